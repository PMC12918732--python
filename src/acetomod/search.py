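"""Run proteomes against profile HMMs and apply the survey's hit filters.

The filtering rule follows the survey protocol: keep a hit when its
full-sequence E-value is below the ceiling (default 1e-3, strict ``<``)
AND its bit score reaches the selected bit-score cutoff annotated on the
model (default the noise cutoff, NC). Both filters are applied jointly.

Two engines are available: the hermetic internal single-hit Viterbi scorer
(:mod:`acetomod.hmmscore`) and an external ``hmmsearch`` subprocess whose
``--tblout`` output is parsed by :mod:`acetomod.hmmio`.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, replace

from . import hmmio, hmmscore
from .errors import AcetomodError, ConfigurationError, EngineUnavailableError
from .hmmio import ProfileHMM, ProteinSequence

logger = logging.getLogger(__name__)

#: Fallback order when the requested cutoff key is missing on a model.
CUTOFF_FALLBACK = ("NC", "GA", "TC")


@dataclass
class Hit:
    """One protein scored against one profile HMM."""

    genome_id: str
    protein_id: str
    hmm_name: str
    bit_score: float
    e_value: float
    engine: str = "internal"
    passed: bool | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise AcetomodError("E-value must be non-negative")


@dataclass
class SearchConfig:
    """Search and filtering parameters.

    ``evalue_strict`` selects strict ``<`` comparison against
    ``evalue_max`` (the default) versus ``<=``. ``n_targets`` is the
    search-space size for internal-engine E-values; when None it is fixed
    at search start to the number of proteins searched.
    """

    evalue_max: float = 1e-3
    cutoff_key: str = "NC"
    n_targets: int | None = None
    engine: str = "internal"
    evalue_strict: bool = True

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ConfigurationError("evalue_max must be positive")
        if self.cutoff_key not in ("NC", "TC", "GA", "none"):
            raise ConfigurationError(f"unknown cutoff key {self.cutoff_key!r}")
        if self.engine not in ("internal", "hmmsearch"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")


def group_by_genome(proteins) -> dict[str, list[ProteinSequence]]:
    """Group a flat protein list by genome_id, preserving order."""
    grouped: dict[str, list[ProteinSequence]] = defaultdict(list)
    for p in proteins:
        grouped[p.genome_id].append(p)
    return dict(grouped)


def run_search(
    proteomes: dict[str, list[ProteinSequence]],
    hmms: list[ProfileHMM],
    config: SearchConfig | None = None,
) -> list[Hit]:
    """Score every protein against every model; hits are unfiltered.

    ``proteomes`` maps genome_id to its protein list (a flat list of
    :class:`~acetomod.hmmio.ProteinSequence` is also accepted and grouped
    by genome). The internal engine scores all pairs; the hmmsearch
    engine shells out and parses tblout (hits below HMMER's own reporting
    floor are absent from its output).
    """
    config = config or SearchConfig()
    if not isinstance(proteomes, dict):
        proteomes = group_by_genome(proteomes)
    if not proteomes or not hmms:
        raise AcetomodError("run_search requires non-empty proteomes and hmms")
    if config.engine == "hmmsearch":
        return _run_hmmsearch(proteomes, hmms)
    n_targets = config.n_targets
    if n_targets is None:
        n_targets = sum(len(v) for v in proteomes.values())
    hits: list[Hit] = []
    warned: set[str] = set()
    for hmm in hmms:
        have_stats = "viterbi_mu" in hmm.gumbel and "viterbi_lambda" in hmm.gumbel
        if not have_stats and hmm.name not in warned:
            warned.add(hmm.name)
            logger.warning(
                "model %s has no VITERBI STATS line; E-values set to +inf "
                "and only score cutoffs apply",
                hmm.name,
            )
        for genome_id, proteins in proteomes.items():
            for protein in proteins:
                aln = hmmscore.viterbi_bitscore(hmm, protein)
                if have_stats:
                    e_value = hmmscore.evalue(
                        aln.bit_score,
                        hmm.gumbel["viterbi_mu"],
                        hmm.gumbel["viterbi_lambda"],
                        n_targets,
                    )
                else:
                    e_value = float("inf")
                hits.append(
                    Hit(
                        genome_id=genome_id,
                        protein_id=protein.protein_id,
                        hmm_name=hmm.name,
                        bit_score=aln.bit_score,
                        e_value=e_value,
                        engine="internal",
                    )
                )
    return hits


def _run_hmmsearch(
    proteomes: dict[str, list[ProteinSequence]], hmms: list[ProfileHMM]
) -> list[Hit]:
    binary = shutil.which("hmmsearch")
    if binary is None:
        raise EngineUnavailableError(
            "hmmsearch not found on PATH; install HMMER or re-run with "
            "engine='internal'"
        )
    # Protein ids are only unique within a genome; tag them for the combined
    # target file and split the tag back out of the tblout.
    sep = "@@"
    tagged = [
        hmmio.ProteinSequence(
            protein_id=f"{gid}{sep}{p.protein_id}",
            genome_id=gid,
            residues=p.residues,
        )
        for gid, prots in proteomes.items()
        for p in prots
    ]
    hits: list[Hit] = []
    with tempfile.TemporaryDirectory(prefix="acetomod_hmmsearch_") as tmp:
        faa = os.path.join(tmp, "targets.faa")
        hmmio.write_fasta(tagged, faa)
        hmmfile = os.path.join(tmp, "query.hmm")
        hmmio.write_hmmer3_many(hmms, hmmfile)
        tbl = os.path.join(tmp, "hits.tbl")
        cmd = [binary, "--noali", "--tblout", tbl, "-E", "1e6", hmmfile, faa]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AcetomodError(
                f"hmmsearch failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        for hit in hmmio.parse_tblout(tbl, engine="hmmsearch"):
            genome_id, _, protein_id = hit.protein_id.partition(sep)
            hits.append(replace(hit, genome_id=genome_id, protein_id=protein_id))
    return hits


def resolve_cutoff(hmm: ProfileHMM, cutoff_key: str) -> tuple[str | None, float | None]:
    """Sequence-bits cutoff for a model, walking the NC -> GA -> TC chain.

    Returns (key actually used, sequence bits), or (None, None) when no
    cutoff annotation exists (or ``cutoff_key='none'``), in which case
    only the E-value ceiling applies. A fallback step is logged, never
    silent.
    """
    if cutoff_key == "none":
        return None, None
    if cutoff_key in hmm.cutoffs:
        return cutoff_key, hmm.cutoffs[cutoff_key][0]
    chain = [k for k in CUTOFF_FALLBACK if k != cutoff_key]
    for key in chain:
        if key in hmm.cutoffs:
            logger.warning(
                "model %s lacks a %s cutoff; falling back to %s",
                hmm.name,
                cutoff_key,
                key,
            )
            return key, hmm.cutoffs[key][0]
    logger.warning(
        "model %s has no GA/TC/NC cutoffs; applying the E-value ceiling only",
        hmm.name,
    )
    return None, None


def filter_hits(
    hits: list[Hit],
    hmms: list[ProfileHMM],
    config: SearchConfig | None = None,
) -> list[Hit]:
    """Apply the joint E-value ceiling and bit-score cutoff; idempotent.

    Retains hits with ``e_value < evalue_max`` (strict by default) and
    ``bit_score >=`` the selected cutoff's sequence-bits value when the
    model carries one. Output is a subset of the input; retained hits get
    ``passed=True``.
    """
    config = config or SearchConfig()
    by_name = {h.name: h for h in hmms}
    cutoff_cache: dict[str, float | None] = {}
    retained: list[Hit] = []
    for hit in hits:
        if hit.hmm_name not in by_name:
            raise ConfigurationError(
                f"hit references unknown model {hit.hmm_name!r}"
            )
        if hit.hmm_name not in cutoff_cache:
            _, bits = resolve_cutoff(by_name[hit.hmm_name], config.cutoff_key)
            cutoff_cache[hit.hmm_name] = bits
        if config.evalue_strict:
            ok_e = hit.e_value < config.evalue_max
        else:
            ok_e = hit.e_value <= config.evalue_max
        bits = cutoff_cache[hit.hmm_name]
        ok_score = True if bits is None else hit.bit_score >= bits
        if ok_e and ok_score:
            hit.passed = True
            retained.append(hit)
    return retained


def best_hit_per_protein(hits: list[Hit]) -> list[Hit]:
    """Keep the single best hit per (genome, protein, model).

    Ordering: higher bit score, then lower E-value, then lexicographic
    protein id; deterministic on re-runs.
    """
    best: dict[tuple[str, str, str], Hit] = {}
    for hit in sorted(
        hits, key=lambda h: (-h.bit_score, h.e_value, h.protein_id)
    ):
        key = (hit.genome_id, hit.protein_id, hit.hmm_name)
        best.setdefault(key, hit)
    return sorted(
        best.values(), key=lambda h: (h.genome_id, h.hmm_name, h.protein_id)
    )
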