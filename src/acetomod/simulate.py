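"""Seeded synthetic fixtures with recorded ground truth.

Generates everything the pipeline consumes: peaked profile HMMs with
calibrated NC/GA/TC cutoffs and Gumbel statistics, proteomes with module
genes planted according to a chosen category composition plus shuffled
decoys, a taxonomy table and tree whose genera group the categories, and
OD600 growth curves with lag, exponential, and stationary phases plus
multiplicative lognormal noise.

All generators are pure functions of (spec, seed): the same seed yields
byte-identical fixture files. Ground truth is serialized alongside the
fixtures and is sufficient to score any pipeline stage without re-reading
fixture internals.

Cutoff construction makes the threshold logic sharp by design: NC is the
midpoint between the lowest of 50 emission-sampled positive scores and the
highest of 50 shuffled-decoy scores, so noise-free planted genes always
clear NC and composition-preserving decoys never do. TC is the minimum
positive score (most stringent), GA the NC/TC midpoint.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import dataclass, field

import numpy as np

from . import hmmio, hmmscore
from .errors import AcetomodError, ConfigurationError
from .growth import GrowthCurve
from .hmmio import AMINO_ALPHABET, ProfileHMM, ProteinSequence, TaxonomyRecord

#: CLI default seed; library callers must pass seeds explicitly.
DEFAULT_SEED = 1701

#: Subunit gene length: short enough for fast scoring, long enough that
#: positive and decoy score distributions are far apart.
GENE_LENGTH = 120

EULER_GAMMA = 0.5772156649015329

#: Category patterns: which module genes each genome carries (Fig-style
#: co-occurrence patterns). "II-rnf" genomes also carry the full Fpo
#: complex, as most natural Ack+Pta/Rnf genomes do.
RNF_GENES = ["rnfA", "rnfB", "rnfC", "rnfD", "rnfE", "rnfG"]
ECH_GENES = ["echA", "echB", "echC", "echD", "echE", "echF"]
FPO_PRIME_GENES = ["fpoA", "fpoB", "fpoC", "fpoD", "fpoH", "fpoL", "fpoN"]

CATEGORY_PATTERNS: dict[str, list[str]] = {
    "I": ["acs"] + FPO_PRIME_GENES,
    "II-rnf": ["ack", "pta"] + RNF_GENES + FPO_PRIME_GENES + ["fpoF"],
    "II-ech": ["ack", "pta"] + ECH_GENES,
    "III": ["acs"] + RNF_GENES + FPO_PRIME_GENES + ["fpoF"],
    "IV": ["ack", "pta"] + FPO_PRIME_GENES,
    "unclassified": [],
}

PATTERN_CATEGORY = {
    "I": "I",
    "II-rnf": "II",
    "II-ech": "II",
    "III": "III",
    "IV": "IV",
    "unclassified": "unclassified",
}

#: Genus label per pattern; taxonomy and tree group genomes by genus.
PATTERN_GENUS = {
    "I": ("o__Methanotrichales", "f__Methanotrichaceae", "g__Methanothrix"),
    "II-rnf": ("o__Methanosarcinales", "f__Methanosarcinaceae", "g__Methanosarcina"),
    "II-ech": ("o__Methanosarcinales", "f__Methanosarcinaceae", "g__Methanosarcina_B"),
    "III": (
        "o__Methanosarcinales",
        "f__Methanosarcinaceae",
        "g__Methanomethylovorans",
    ),
    "IV": ("o__Methanosarcinales", "f__Methanosarcinaceae", "g__Methanoficta"),
    "unclassified": (
        "o__Methanosarcinales",
        "f__Methanosarcinaceae",
        "g__Methanolobus",
    ),
}

ALL_GENE_NAMES = (
    ["ack", "pta", "acs"] + RNF_GENES + ECH_GENES + FPO_PRIME_GENES + ["fpoF"]
)


@dataclass
class CommunitySpec:
    """Composition and noise parameters of a synthetic community."""

    n_genomes_per_category: dict[str, int] = field(
        default_factory=lambda: {k: 2 for k in CATEGORY_PATTERNS}
    )
    decoys_per_genome: int = 10
    divergence: float = 0.05  # per-residue substitution probability
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        unknown = set(self.n_genomes_per_category) - set(CATEGORY_PATTERNS)
        if unknown:
            raise ConfigurationError(f"unknown category pattern(s) {sorted(unknown)}")
        if not (0.0 <= self.divergence < 0.5):
            raise ConfigurationError("divergence must be in [0, 0.5)")
        if self.decoys_per_genome < 0 or any(
            n < 0 for n in self.n_genomes_per_category.values()
        ):
            raise ConfigurationError("counts must be >= 0")


@dataclass
class SyntheticCommunity:
    """In-memory community plus the ground truth that generated it."""

    proteomes: dict[str, list[ProteinSequence]]
    hmms: list[ProfileHMM]
    taxonomy: list[TaxonomyRecord]
    tree_newick: str
    truth: dict


def _random_consensus(rng: np.random.Generator, length: int = GENE_LENGTH) -> str:
    return "".join(rng.choice(list(AMINO_ALPHABET), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0.0:
        return seq
    out = []
    for a in seq:
        if rng.random() < divergence:
            choices = [b for b in AMINO_ALPHABET if b != a]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(a)
    return "".join(out)


def _shuffle(seq: str, rng: np.random.Generator) -> str:
    letters = list(seq)
    rng.shuffle(letters)
    return "".join(letters)


def _sample_from_emissions(hmm: ProfileHMM, rng: np.random.Generator) -> str:
    letters = []
    for k in range(hmm.M):
        j = rng.choice(20, p=hmm.match_emissions[k])
        letters.append(AMINO_ALPHABET[j])
    return "".join(letters)


def make_hmm(
    consensus: str | ProteinSequence,
    peak: float = 0.9,
    seed: int = 0,
    name: str | None = None,
) -> ProfileHMM:
    """Peaked profile HMM around a consensus, with calibrated cutoffs.

    Match emission at node i puts ``peak`` on the consensus letter and
    spreads the rest uniformly; insert emissions and the background are
    uniform. NC separates emission-sampled positives from
    composition-preserving shuffled decoys by construction; Gumbel
    VITERBI parameters are moment-matched to 200 decoy scores.
    """
    if isinstance(consensus, ProteinSequence):
        name = name or f"{consensus.protein_id}_hmm"
        consensus = consensus.residues
    if len(consensus) == 0:
        raise AcetomodError("degenerate consensus (length 0)")
    if not (1.0 / 20.0 < peak <= 1.0):
        raise AcetomodError(f"peak must be in (1/20, 1], got {peak}")
    name = name or "synthetic"
    M = len(consensus)
    match = np.full((M, 20), (1.0 - peak) / 19.0)
    for k, a in enumerate(consensus):
        match[k, hmmio.AMINO_INDEX[a]] = peak
    insert = np.full((M, 20), 1.0 / 20.0)
    background = np.full(20, 1.0 / 20.0)
    trans = np.zeros((M + 1, 7))
    trans[:, :] = [0.90, 0.05, 0.05, 0.90, 0.10, 0.90, 0.10]
    trans[0] = [0.90, 0.05, 0.05, 0.90, 0.10, 1.00, 0.00]
    trans[M] = [0.95, 0.05, 0.00, 0.90, 0.10, 1.00, 0.00]
    hmm = ProfileHMM(
        name=name,
        M=M,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=background,
    )
    hmm.validate()
    rng = np.random.default_rng(seed)
    positives = [
        hmmscore.viterbi_bitscore(hmm, _sample_from_emissions(hmm, rng)).bit_score
        for _ in range(50)
    ]
    decoys = [
        hmmscore.viterbi_bitscore(hmm, _shuffle(consensus, rng)).bit_score
        for _ in range(50)
    ]
    lo_pos = min(positives)
    hi_dec = max(decoys)
    nc = 0.5 * (lo_pos + hi_dec)
    tc = lo_pos
    ga = 0.5 * (nc + tc)
    hmm.cutoffs = {"NC": (nc, nc), "GA": (ga, ga), "TC": (tc, tc)}
    calib = [
        hmmscore.viterbi_bitscore(hmm, _shuffle(consensus, rng)).bit_score
        for _ in range(200)
    ]
    mean = float(np.mean(calib))
    sd = float(np.std(calib, ddof=1))
    if sd > 0:
        lam = math.pi / (sd * math.sqrt(6.0))
    else:
        # degenerate decoy distribution (very short consensus: few distinct
        # permutations); fall back to the canonical bit-score slope
        lam = math.log(2.0)
    mu = mean - EULER_GAMMA / lam
    # HMMER insists on all three STATS lines when any is present, so the
    # MSV and FORWARD slots reuse the Viterbi fit (only VITERBI is consumed
    # by the internal engine).
    hmm.gumbel = {
        "viterbi_mu": mu,
        "viterbi_lambda": lam,
        "msv_mu": mu,
        "msv_lambda": lam,
        "forward_tau": mu,
        "forward_lambda": lam,
    }
    return hmm


def _genus_caterpillar(tips: list[str], rng: random.Random) -> str:
    """Newick caterpillar over tips in a seeded random order."""
    order = tips[:]
    rng.shuffle(order)
    sub = order[0]
    for tip in order[1:]:
        sub = f"({sub}:{rng.uniform(0.05, 0.5):.4f},{tip}:{rng.uniform(0.05, 0.5):.4f})"
    return sub


def make_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate proteomes, models, taxonomy, tree and ground truth.

    Each genome carries mutated copies (per ``spec.divergence``) of the
    genes its category pattern requires, plus ``decoys_per_genome``
    composition-preserving shuffles of randomly chosen planted genes.
    Genus labels group the category patterns, and the tree groups the
    genera.
    """
    total = sum(spec.n_genomes_per_category.values())
    if total == 0:
        raise AcetomodError("community must contain at least one genome")
    root = np.random.SeedSequence(spec.seed)
    ss_genes, ss_hmms, ss_genomes, ss_tree = root.spawn(4)
    gene_rng = np.random.default_rng(ss_genes)
    consensus = {gene: _random_consensus(gene_rng) for gene in ALL_GENE_NAMES}
    hmm_seeds = ss_hmms.generate_state(len(ALL_GENE_NAMES))
    hmms = [
        make_hmm(consensus[gene], peak=0.9, seed=int(s) % (2**31), name=gene)
        for gene, s in zip(ALL_GENE_NAMES, hmm_seeds)
    ]
    proteomes: dict[str, list[ProteinSequence]] = {}
    taxonomy: list[TaxonomyRecord] = []
    truth_genomes: dict[str, dict] = {}
    genome_rng = np.random.default_rng(ss_genomes)
    index = 0
    genomes_by_genus: dict[str, list[str]] = {}
    for pattern in CATEGORY_PATTERNS:  # fixed iteration order: deterministic
        count = spec.n_genomes_per_category.get(pattern, 0)
        order, family, genus = PATTERN_GENUS[pattern]
        for _ in range(count):
            index += 1
            gid = f"SYN{index:04d}"
            genes = CATEGORY_PATTERNS[pattern]
            proteins: list[ProteinSequence] = []
            planted_proteins: dict[str, str] = {}
            for gene in genes:
                pid = f"{gid}_{gene}"
                proteins.append(
                    ProteinSequence(
                        protein_id=pid,
                        genome_id=gid,
                        residues=_mutate(consensus[gene], spec.divergence, genome_rng),
                    )
                )
                planted_proteins[gene] = pid
            for d in range(spec.decoys_per_genome):
                source = ALL_GENE_NAMES[genome_rng.integers(len(ALL_GENE_NAMES))]
                proteins.append(
                    ProteinSequence(
                        protein_id=f"{gid}_decoy{d:03d}",
                        genome_id=gid,
                        residues=_shuffle(
                            _mutate(consensus[source], spec.divergence, genome_rng),
                            genome_rng,
                        ),
                    )
                )
            proteomes[gid] = proteins
            species = f"s__{genus[3:]} synthetica{index}"
            taxonomy.append(
                TaxonomyRecord(
                    genome_id=gid,
                    ranks={
                        "domain": "d__Archaea",
                        "phylum": "p__Halobacteriota",
                        "class": "c__Methanosarcinia",
                        "order": order,
                        "family": family,
                        "genus": genus,
                        "species": species,
                    },
                )
            )
            genomes_by_genus.setdefault(genus, []).append(gid)
            truth_genomes[gid] = {
                "pattern": pattern,
                "category": PATTERN_CATEGORY[pattern],
                "genus": genus,
                "planted_genes": list(genes),
                "planted_proteins": planted_proteins,
            }
    tree_rng = random.Random(int(ss_tree.generate_state(1)[0]) % (2**31))
    subtrees = [
        _genus_caterpillar(tips, tree_rng)
        for genus, tips in sorted(genomes_by_genus.items())
    ]
    if len(subtrees) == 1:
        newick = f"{subtrees[0]};"
    else:
        joined = subtrees[0]
        for sub in subtrees[1:]:
            joined = f"({joined}:{tree_rng.uniform(0.1, 1.0):.4f},{sub}:{tree_rng.uniform(0.1, 1.0):.4f})"
        newick = f"{joined};"
    truth = {
        "seed": spec.seed,
        "divergence": spec.divergence,
        "decoys_per_genome": spec.decoys_per_genome,
        "gene_names": list(ALL_GENE_NAMES),
        "genomes": truth_genomes,
    }
    return SyntheticCommunity(
        proteomes=proteomes,
        hmms=hmms,
        taxonomy=taxonomy,
        tree_newick=newick,
        truth=truth,
    )


def write_community(community: SyntheticCommunity, outdir) -> None:
    """Write proteomes/*.faa, hmms/*.hmm, taxonomy.tsv, tree.nwk, truth.json."""
    os.makedirs(os.path.join(outdir, "proteomes"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "hmms"), exist_ok=True)
    for gid, proteins in community.proteomes.items():
        hmmio.write_fasta(proteins, os.path.join(outdir, "proteomes", f"{gid}.faa"))
    for hmm in community.hmms:
        hmmio.write_hmmer3(hmm, os.path.join(outdir, "hmms", f"{hmm.name}.hmm"))
    hmmio.write_gtdb_taxonomy(
        community.taxonomy, os.path.join(outdir, "taxonomy.tsv")
    )
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(community.tree_newick + "\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(community.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_community(outdir) -> SyntheticCommunity:
    """Load a community previously written by :func:`write_community`."""
    proteome_dir = os.path.join(outdir, "proteomes")
    proteomes = {}
    for fname in sorted(os.listdir(proteome_dir)):
        gid = os.path.splitext(fname)[0]
        proteomes[gid] = hmmio.read_fasta(os.path.join(proteome_dir, fname), gid)
    hmm_dir = os.path.join(outdir, "hmms")
    hmms = []
    for fname in sorted(os.listdir(hmm_dir)):
        hmms.extend(hmmio.parse_hmmer3(os.path.join(hmm_dir, fname)))
    taxonomy = hmmio.parse_gtdb_taxonomy(os.path.join(outdir, "taxonomy.tsv"))
    with open(os.path.join(outdir, "tree.nwk")) as fh:
        newick = fh.read().strip()
    with open(os.path.join(outdir, "truth.json")) as fh:
        truth = json.load(fh)
    return SyntheticCommunity(
        proteomes=proteomes,
        hmms=hmms,
        taxonomy=taxonomy,
        tree_newick=newick,
        truth=truth,
    )


def make_growth_curve(
    od0: float,
    t_lag: float,
    t_d: float,
    od_max: float,
    noise_sd: float,
    seed: int,
    times,
) -> tuple[GrowthCurve, dict]:
    """Lag/exponential/stationary OD600 curve with lognormal noise.

    ``od(t) = od0`` for ``t < t_lag``, then ``od0 * 2^((t - t_lag)/t_d)``
    capped at ``od_max``, multiplied by ``exp(noise_sd * N(0, 1))``.
    Returns the curve and its ground truth.
    """
    if od0 > od_max:
        # equality is allowed: a ceiling at od0 yields a flat (no-growth) curve
        raise AcetomodError("od0 must not exceed od_max")
    if t_d <= 0:
        raise AcetomodError("doubling time must be positive")
    times = np.asarray(times, dtype=float)
    clean = np.where(
        times < t_lag,
        od0,
        np.minimum(od0 * np.power(2.0, (times - t_lag) / t_d), od_max),
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        od = clean * np.exp(noise_sd * rng.standard_normal(len(times)))
    else:
        od = clean.copy()
    curve = GrowthCurve(strain="sim", replicate=str(seed), times=times, od=od)
    truth = {
        "od0": od0,
        "t_lag": t_lag,
        "t_d": t_d,
        "od_max": od_max,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return curve, truth


def write_curves_csv(curves: list[GrowthCurve], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain,replicate,time_h,od600\n")
        for curve in curves:
            for t, od in zip(curve.times, curve.od):
                fh.write(f"{curve.strain},{curve.replicate},{t:.6g},{od:.8g}\n")
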