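"""End-to-end survey convenience: search, filter, profile, classify."""

from __future__ import annotations

from dataclasses import dataclass

from . import classify, modules, search
from .classify import CategoryCall, CooccurrenceReport
from .modules import GenomeProfile, ModuleDefinition
from .search import Hit, SearchConfig


@dataclass
class SurveyResult:
    hits: list[Hit]
    filtered: list[Hit]
    profiles: list[GenomeProfile]
    calls: list[CategoryCall]
    cooccurrence: CooccurrenceReport


def run_survey(
    proteomes,
    hmms,
    config: SearchConfig | None = None,
    module_defs: list[ModuleDefinition] | None = None,
) -> SurveyResult:
    """Search all proteomes, apply the survey filters, and classify genomes."""
    config = config or SearchConfig()
    if not isinstance(proteomes, dict):
        proteomes = search.group_by_genome(proteomes)
    hits = search.run_search(proteomes, hmms, config)
    filtered = search.filter_hits(hits, hmms, config)
    filtered = search.best_hit_per_protein(filtered)
    profiles = modules.profile_genomes(
        filtered, sorted(proteomes), module_defs
    )
    calls = [classify.assign_category(p) for p in profiles]
    report = classify.check_cooccurrence(profiles)
    return SurveyResult(
        hits=hits,
        filtered=filtered,
        profiles=profiles,
        calls=calls,
        cooccurrence=report,
    )
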