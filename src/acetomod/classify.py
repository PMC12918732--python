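"""Acetoclastic category assignment, co-occurrence checks, and prevalence.

Categories describe the co-occurrence of an acetate-activation module with
an energy-conservation module:

* **I** — Acs with Fpo'-only (no FpoF, no Rnf, no Ech); the Methanothrix
  configuration.
* **II** — Ack+Pta with Rnf or Ech; the Methanosarcina configuration.
* **III** — Acs with Rnf; a hybrid, common in e.g. Methanomethylovorans.
* **IV** — Ack+Pta with Fpo'-only (no Rnf, no Ech); a hypothesized
  combination never observed in sequenced genomes.

Rules are evaluated in the order III, II, I, IV (first match wins); a
genome matching none is unclassified. Placing III before I means a genome
with Acs, Rnf and an Fpo'-only complex is called III — III is defined by
the Acs/Rnf co-occurrence and most such genomes also carry Fpo. The order
is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .errors import AcetomodError
from .hmmio import GTDB_RANK_NAMES, TaxonomyRecord
from .modules import GenomeProfile

logger = logging.getLogger(__name__)

DEFAULT_RULE_ORDER = ("III", "II", "I", "IV")

#: Category predicates over the six primitive module flags.
CATEGORY_RULES = {
    "I": lambda f: f["acs"] and f["fpo_prime_only"] and not f["rnf"] and not f["ech"],
    "II": lambda f: f["ack_pta"] and (f["rnf"] or f["ech"]),
    "III": lambda f: f["acs"] and f["rnf"],
    "IV": lambda f: f["ack_pta"]
    and f["fpo_prime_only"]
    and not f["rnf"]
    and not f["ech"],
}


@dataclass
class CategoryCall:
    """A genome's acetoclastic category with its rationale axes."""

    genome_id: str
    category: str  # I, II, III, IV, or unclassified
    activation_axis: str  # ack_pta, acs, none, or both
    energy_axis: tuple[str, ...]  # subset of rnf/ech/fpo_prime_only/fpo_full


@dataclass
class PrevalenceSummary:
    """Fraction of genomes in one taxon where a target flag or category holds."""

    taxon: str
    rank: str
    target: str
    k: int
    n: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.k, self.n)

    @property
    def percent(self) -> int:
        """Nearest-integer percent, the style used in survey reports."""
        return round(100 * self.k / self.n)


@dataclass
class CooccurrenceReport:
    """Genomes violating the survey's two never-observed combinations."""

    dual_activation: list[str]  # Ack+Pta AND Acs in one genome
    putative_category_iv: list[str]  # Ack+Pta with Fpo'-only, no Rnf/Ech


def category_from_flags(
    flags: dict[str, bool], order: tuple[str, ...] = DEFAULT_RULE_ORDER
) -> str:
    """First matching category in rule order, else ``unclassified``.

    ``flags`` must contain ``ack_pta``, ``acs``, ``rnf``, ``ech``,
    ``fpo_prime_only`` (``fpo_full`` is not consulted by the rules).
    """
    for cat in order:
        if CATEGORY_RULES[cat](flags):
            return cat
    return "unclassified"


def assign_category(
    profile: GenomeProfile, order: tuple[str, ...] = DEFAULT_RULE_ORDER
) -> CategoryCall:
    """Deterministic category call with rationale axes always populated.

    A genome with both activation modules gets ``activation_axis='both'``;
    classification still proceeds by rule order and the conflict is
    surfaced by :func:`check_cooccurrence`.
    """
    flags = profile.flags()
    if flags["ack_pta"] and flags["acs"]:
        activation = "both"
    elif flags["ack_pta"]:
        activation = "ack_pta"
    elif flags["acs"]:
        activation = "acs"
    else:
        activation = "none"
    energy = tuple(
        name
        for name in ("rnf", "ech", "fpo_prime_only", "fpo_full")
        if flags[name]
    ) or ("none",)
    return CategoryCall(
        genome_id=profile.genome_id,
        category=category_from_flags(flags, order),
        activation_axis=activation,
        energy_axis=energy,
    )


def check_cooccurrence(profiles: list[GenomeProfile]) -> CooccurrenceReport:
    """List genomes with dual activation modules or the putative category IV.

    Both combinations are reported as never observed in sequenced genomes;
    on conforming data both lists are empty. Pure function of the
    profiles.
    """
    dual = []
    putative_iv = []
    for p in profiles:
        f = p.flags()
        if f["ack_pta"] and f["acs"]:
            dual.append(p.genome_id)
        if (
            f["ack_pta"]
            and f["fpo_prime_only"]
            and not f["rnf"]
            and not f["ech"]
        ):
            putative_iv.append(p.genome_id)
    return CooccurrenceReport(
        dual_activation=sorted(dual), putative_category_iv=sorted(putative_iv)
    )


def _target_predicate(target: str):
    if target in GenomeProfile.FLAG_NAMES:
        return lambda profile, call: profile.flags()[target]
    if target.startswith("category:"):
        wanted = target.split(":", 1)[1]
        if wanted not in ("I", "II", "III", "IV", "unclassified"):
            raise AcetomodError(f"unknown category {wanted!r} in target {target!r}")
        return lambda profile, call: call is not None and call.category == wanted
    raise AcetomodError(f"unknown prevalence target {target!r}")


def prevalence(
    profiles: list[GenomeProfile],
    calls: list[CategoryCall] | None,
    taxonomy: list[TaxonomyRecord],
    rank: str,
    target: str,
) -> list[PrevalenceSummary]:
    """Per-taxon k/n summaries at a rank for a module flag or category.

    ``target`` is a derived-flag name (e.g. ``ack_pta``, ``rnf``,
    ``fpo_prime_only``) or ``category:<I|II|III|IV|unclassified>``.
    Genomes without a taxonomy record are warned about and excluded;
    genomes with an empty label at the rank are likewise excluded. The
    exact fraction k/n is retained; percent is the rounded presentation.
    """
    if rank not in GTDB_RANK_NAMES:
        raise AcetomodError(f"unknown rank {rank!r}")
    predicate = _target_predicate(target)
    tax_by_genome = {t.genome_id: t for t in taxonomy}
    call_by_genome = {c.genome_id: c for c in calls} if calls else {}
    counts: dict[str, list[int]] = {}
    for profile in profiles:
        record = tax_by_genome.get(profile.genome_id)
        if record is None:
            logger.warning(
                "genome %s has no taxonomy record; excluded from %s summaries",
                profile.genome_id,
                rank,
            )
            continue
        label = record.rank(rank)
        if not label:
            continue
        call = call_by_genome.get(profile.genome_id)
        k_n = counts.setdefault(label, [0, 0])
        k_n[1] += 1
        if predicate(profile, call):
            k_n[0] += 1
    return [
        PrevalenceSummary(taxon=taxon, rank=rank, target=target, k=k, n=n)
        for taxon, (k, n) in sorted(counts.items())
    ]


def calls_to_frame(calls: list[CategoryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": [c.genome_id for c in calls],
            "category": [c.category for c in calls],
            "activation_axis": [c.activation_axis for c in calls],
            "energy_axis": ["+".join(c.energy_axis) for c in calls],
        }
    )


def prevalence_to_frame(summaries: list[PrevalenceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [s.rank for s in summaries],
            "taxon": [s.taxon for s in summaries],
            "target": [s.target for s in summaries],
            "k": [s.k for s in summaries],
            "n": [s.n for s in summaries],
            "fraction": [float(s.fraction) for s in summaries],
            "percent": [s.percent for s in summaries],
        }
    )
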