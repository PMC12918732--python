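"""Shared fixtures: tiny profiles and seeded synthetic communities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from acetomod import simulate
from acetomod.hmmio import AMINO_INDEX, ProfileHMM

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def random_tiny_hmm(rng: np.random.Generator, M: int) -> ProfileHMM:
    """A random, fully normalized model with strictly positive emissions."""

    def simplex(n: int) -> np.ndarray:
        x = rng.random(n) + 0.05
        return x / x.sum()

    match = np.vstack([simplex(20) for _ in range(M)])
    insert = np.vstack([simplex(20) for _ in range(M)])
    trans = np.zeros((M + 1, 7))
    for k in range(M + 1):
        trans[k, 0:3] = simplex(3)
        trans[k, 3:5] = simplex(2)
        trans[k, 5:7] = simplex(2)
    # file-format conventions at the boundary nodes
    trans[0, 5:7] = [1.0, 0.0]
    trans[M, 2] = 0.0
    trans[M, 0:2] = trans[M, 0:2] / trans[M, 0:2].sum()
    trans[M, 5:7] = [1.0, 0.0]
    hmm = ProfileHMM(
        name=f"rand{M}",
        M=M,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=simplex(20),
    )
    hmm.validate()
    return hmm


def brute_force_bitscore(hmm: ProfileHMM, seq: str) -> float:
    """Independent oracle: exhaustive enumeration of all legal local paths.

    A path enters any match node at any residue (uniform 1/M entry),
    walks match/insert/delete states, and may exit (free) from any match
    state. Scores are log2-odds versus the model background. Feasible
    only for tiny models and sequences.
    """
    M, L = hmm.M, len(seq)
    bg = hmm.background

    def lo(p: float, q: float) -> float:
        return -math.inf if p == 0.0 else math.log2(p / q)

    def lt(k: int, col: int) -> float:
        p = hmm.transitions[k][col]
        return -math.inf if p == 0.0 else math.log2(p)

    def em(k: int, i: int) -> float:  # match node k emits residue i (1-based)
        a = seq[i - 1]
        if a == "X":
            return 0.0
        j = AMINO_INDEX[a]
        return lo(hmm.match_emissions[k - 1][j], bg[j])

    def ins(k: int, i: int) -> float:
        a = seq[i - 1]
        if a == "X":
            return 0.0
        j = AMINO_INDEX[a]
        return lo(hmm.insert_emissions[k - 1][j], bg[j])

    best = [-math.inf]

    def walk(state: str, k: int, i: int, score: float) -> None:
        if score == -math.inf:
            return
        if state == "M":
            best[0] = max(best[0], score)  # free exit from any match state
            if k < M and i < L:
                walk("M", k + 1, i + 1, score + lt(k, 0) + em(k + 1, i + 1))
            if i < L:
                walk("I", k, i + 1, score + lt(k, 1) + ins(k, i + 1))
            if k < M:
                walk("D", k + 1, i, score + lt(k, 2))
        elif state == "I":
            if k < M and i < L:
                walk("M", k + 1, i + 1, score + lt(k, 3) + em(k + 1, i + 1))
            if i < L:
                walk("I", k, i + 1, score + lt(k, 4) + ins(k, i + 1))
        else:  # D
            if k < M and i < L:
                walk("M", k + 1, i + 1, score + lt(k, 5) + em(k + 1, i + 1))
            if k < M:
                walk("D", k + 1, i, score + lt(k, 6))

    entry = -math.log2(M)
    for k0 in range(1, M + 1):
        for i0 in range(1, L + 1):
            walk("M", k0, i0, entry + em(k0, i0))
    return best[0]


@pytest.fixture(scope="session")
def toy_hmm() -> ProfileHMM:
    return simulate.make_hmm("ACDEFGHIK", peak=0.9, seed=42, name="toy")


@pytest.fixture(scope="session")
def community():
    """Default 12-genome community (two genomes per category pattern)."""
    return simulate.make_community(simulate.CommunitySpec(seed=1701))


@pytest.fixture(scope="session")
def observed_community():
    """12 genomes drawn only from patterns seen in sequenced genomes.

    No category-IV and no dual-activation genomes: the co-occurrence
    violation lists must come out empty on this community.
    """
    spec = simulate.CommunitySpec(
        n_genomes_per_category={
            "I": 3,
            "II-rnf": 3,
            "II-ech": 2,
            "III": 2,
            "IV": 0,
            "unclassified": 2,
        },
        divergence=0.0,
        seed=90210,
    )
    return simulate.make_community(spec)
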