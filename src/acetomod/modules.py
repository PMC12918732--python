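"""Per-genome module presence calls from filtered hits.

A module is "present" when hits cover at least a threshold number of its
DISTINCT member models: >= 4 of six Rnf subunits, >= 4 of six Ech subunits,
>= 5 of seven Fpo' subunits; the single-gene modules (Ack, Pta, Acs, FpoF)
require their one model. Fpo' is the F420:methanophenazine oxidoreductase
complex without the F420-interacting FpoF head subunit; a genome with Fpo'
and FpoF carries the full Fpo complex, while Fpo' without FpoF is the
configuration hypothesized to re-oxidize ferredoxin in obligate
acetoclastic methanogens.

Member model names are configuration: the defaults below are placeholder
names that the synthetic generator also uses, and a YAML file can override
them with real accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigurationError
from .search import Hit

logger = logging.getLogger(__name__)

#: Module ids with special meaning for the derived genome flags.
ACK, PTA, ACS, RNF, ECH, FPO_PRIME, FPOF = (
    "ack",
    "pta",
    "acs",
    "rnf",
    "ech",
    "fpo_prime",
    "fpoF",
)


@dataclass
class ModuleDefinition:
    """One module: member model names and the subunit-completeness threshold."""

    module_id: str
    member_hmms: list[str]
    min_subunits: int
    require_all: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_subunits <= len(self.member_hmms)):
            raise ConfigurationError(
                f"module {self.module_id!r}: min_subunits {self.min_subunits} "
                f"outside 1..{len(self.member_hmms)}"
            )
        if self.require_all and self.min_subunits != len(self.member_hmms):
            raise ConfigurationError(
                f"module {self.module_id!r}: require_all implies "
                "min_subunits == number of members"
            )
        if len(set(self.member_hmms)) != len(self.member_hmms):
            raise ConfigurationError(
                f"module {self.module_id!r}: duplicate member model names"
            )


@dataclass
class ModuleCall:
    """Presence record for one module in one genome."""

    module_id: str
    present: bool
    subunits_found: int
    supporting: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class GenomeProfile:
    """Per-genome module presence/absence with derived flags."""

    genome_id: str
    modules: dict[str, ModuleCall]

    def _present(self, module_id: str) -> bool:
        call = self.modules.get(module_id)
        return bool(call and call.present)

    @property
    def ack_pta(self) -> bool:
        """Two-enzyme acetate activation: acetate kinase AND phosphotransacetylase."""
        return self._present(ACK) and self._present(PTA)

    @property
    def acs(self) -> bool:
        """One-enzyme acetate activation: AMP-forming acetyl-CoA synthetase."""
        return self._present(ACS)

    @property
    def rnf(self) -> bool:
        return self._present(RNF)

    @property
    def ech(self) -> bool:
        return self._present(ECH)

    @property
    def fpo_prime(self) -> bool:
        return self._present(FPO_PRIME)

    @property
    def fpoF(self) -> bool:
        return self._present(FPOF)

    @property
    def fpo_full(self) -> bool:
        """Complete Fpo: the Fpo' body plus the FpoF head subunit."""
        return self.fpo_prime and self.fpoF

    @property
    def fpo_prime_only(self) -> bool:
        """Fpo' body without FpoF anywhere in the genome."""
        return self.fpo_prime and not self.fpoF

    FLAG_NAMES = (
        "ack_pta",
        "acs",
        "rnf",
        "ech",
        "fpo_prime",
        "fpoF",
        "fpo_full",
        "fpo_prime_only",
    )

    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in self.FLAG_NAMES}


def default_module_set() -> list[ModuleDefinition]:
    """The survey's seven modules with their completeness thresholds.

    Single-gene modules require their gene; the membrane complexes use
    >=4/6 (Rnf), >=4/6 (Ech) and >=5/7 (Fpo') distinct subunits. Member
    names are placeholders, overridable via :func:`load_module_set`.
    """
    return [
        ModuleDefinition(ACK, ["ack"], 1, require_all=True),
        ModuleDefinition(PTA, ["pta"], 1, require_all=True),
        ModuleDefinition(ACS, ["acs"], 1, require_all=True),
        ModuleDefinition(
            RNF, ["rnfA", "rnfB", "rnfC", "rnfD", "rnfE", "rnfG"], 4
        ),
        ModuleDefinition(
            ECH, ["echA", "echB", "echC", "echD", "echE", "echF"], 4
        ),
        ModuleDefinition(
            FPO_PRIME,
            ["fpoA", "fpoB", "fpoC", "fpoD", "fpoH", "fpoL", "fpoN"],
            5,
        ),
        ModuleDefinition(FPOF, ["fpoF"], 1, require_all=True),
    ]


def load_module_set(path) -> list[ModuleDefinition]:
    """Read module definitions from YAML.

    Layout: a list of mappings with keys ``module_id``, ``member_hmms``
    (list of model names) and ``min_subunits`` (optional
    ``require_all``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError(f"{path}: expected a YAML list of modules")
    defs = [
        ModuleDefinition(
            module_id=item["module_id"],
            member_hmms=list(item["member_hmms"]),
            min_subunits=int(item["min_subunits"]),
            require_all=bool(item.get("require_all", False)),
        )
        for item in raw
    ]
    return defs


def call_module(hits: list[Hit], definition: ModuleDefinition) -> ModuleCall:
    """Count distinct member models with >= 1 passing hit in one genome.

    ``hits`` must already be filtered. Presence means
    ``subunits_found >= min_subunits``; multiple hits to the same member
    model count once.
    """
    members = set(definition.member_hmms)
    supporting: dict[str, list[str]] = {}
    for hit in hits:
        if hit.hmm_name in members:
            supporting.setdefault(hit.hmm_name, []).append(hit.protein_id)
    subunits_found = len(supporting)
    return ModuleCall(
        module_id=definition.module_id,
        present=subunits_found >= definition.min_subunits,
        subunits_found=subunits_found,
        supporting={k: sorted(v) for k, v in sorted(supporting.items())},
    )


def profile_genome(
    genome_id: str,
    hits: list[Hit],
    module_defs: list[ModuleDefinition] | None = None,
) -> GenomeProfile:
    """All module calls for one genome, from its filtered hits.

    Warns (never blocks) on a partial Ack+Pta activation module and on
    proteins supporting several subunits of the same complex — complex
    subunits are homologous, so cross-hits are plausible and are counted
    toward each distinct subunit.
    """
    module_defs = module_defs if module_defs is not None else default_module_set()
    ids = [d.module_id for d in module_defs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate module_id in module definitions")
    genome_hits = [h for h in hits if h.genome_id == genome_id]
    calls = {d.module_id: call_module(genome_hits, d) for d in module_defs}
    profile = GenomeProfile(genome_id=genome_id, modules=calls)
    ack, pta = calls.get(ACK), calls.get(PTA)
    if ack and pta and (ack.present != pta.present):
        have = ACK if ack.present else PTA
        logger.warning(
            "genome %s: partial Ack+Pta activation module (only %s found)",
            genome_id,
            have,
        )
    for call in calls.values():
        seen: dict[str, list[str]] = {}
        for hmm_name, protein_ids in call.supporting.items():
            for pid in protein_ids:
                seen.setdefault(pid, []).append(hmm_name)
        for pid, hmm_names in seen.items():
            if len(hmm_names) > 1:
                logger.warning(
                    "genome %s: protein %s hits %d member models of module "
                    "%s (%s); counted toward each distinct subunit",
                    genome_id,
                    pid,
                    len(hmm_names),
                    call.module_id,
                    ",".join(hmm_names),
                )
    return profile


def profile_genomes(
    hits: list[Hit],
    genome_ids: list[str],
    module_defs: list[ModuleDefinition] | None = None,
) -> list[GenomeProfile]:
    """Profiles for a genome list (genomes with zero hits included)."""
    by_genome: dict[str, list[Hit]] = {g: [] for g in genome_ids}
    for hit in hits:
        if hit.genome_id in by_genome:
            by_genome[hit.genome_id].append(hit)
    return [
        profile_genome(g, by_genome[g], module_defs) for g in genome_ids
    ]


def profiles_to_frame(profiles: list[GenomeProfile]) -> pd.DataFrame:
    """One row per genome: subunit counts per module plus derived flags."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"genome_id": p.genome_id}
        for module_id, call in p.modules.items():
            row[f"{module_id}_present"] = call.present
            row[f"{module_id}_subunits"] = call.subunits_found
        row.update(p.flags())
        rows.append(row)
    return pd.DataFrame(rows)
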