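"""Minimal profile-HMM scoring engine.

Single-hit local Viterbi bit scores against an i.i.d. background null, with
Gumbel E-values from the model's VITERBI calibration. The local alignment
model enters uniformly (probability ``1/M``) into any match node and exits
freely from any match node; delete states are silent; flanking residues
score zero (background versus background cancels). This engine is exact and
deterministic, and serves as the hermetic default backend for synthetic
searches; bit-for-bit HMMER fidelity on real models goes through the
``hmmsearch`` engine in :mod:`acetomod.search`.

Scores are kept in bits (log2) at every step, which keeps the dynamic
program transparent against the brute-force path-enumeration oracle used in
the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AcetomodError, SequenceAlphabetError
from .hmmio import AMINO_INDEX, ProfileHMM, ProteinSequence

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@dataclass
class ScoredAlignment:
    """Best single-hit local alignment of one sequence to one profile.

    Node and residue coordinates are 1-based and inclusive.
    """

    bit_score: float
    start_node: int
    end_node: int
    start_res: int
    end_res: int
    path: list[str] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score):
            raise AcetomodError("bit score must be finite")
        if self.start_node > self.end_node or self.start_res > self.end_res:
            raise AcetomodError("alignment start must not exceed end")


def encode_sequence(seq: ProteinSequence | str) -> np.ndarray:
    """Map residues to alphabet indices; ambiguous X maps to index 20."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    out = np.empty(len(residues), dtype=np.int64)
    for i, a in enumerate(residues):
        if a == "X":
            out[i] = 20
        elif a in AMINO_INDEX:
            out[i] = AMINO_INDEX[a]
        else:
            raise SequenceAlphabetError(f"illegal residue {a!r}")
    return out


def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


def score_tables(hmm: ProfileHMM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node log2-odds emission tables and log2 transition table.

    Emission tables have 21 columns: the 20 residues plus ambiguous X,
    which scores as the background (log-odds 0). Row ``k-1`` is match
    node ``k``. The transition table keeps the file's row layout: row
    index is the source node, columns follow
    :data:`acetomod.hmmio.TRANSITION_ORDER`.
    """
    bg = _log2(hmm.background)
    match_lo = np.zeros((hmm.M, 21))
    ins_lo = np.zeros((hmm.M, 21))
    match_lo[:, :20] = _log2(hmm.match_emissions) - bg[None, :]
    ins_lo[:, :20] = _log2(hmm.insert_emissions) - bg[None, :]
    log_trans = _log2(hmm.transitions)
    return match_lo, ins_lo, log_trans


@njit(cache=False)
def _viterbi_kernel(match_lo, ins_lo, lt, enc, log_entry):
    """Single-hit local Viterbi in bits.

    Cell (i, k): best score of a local alignment that has consumed the
    first i residues and currently sits in the given state of match node
    k. Delete states consume no residue, so the delete chain propagates
    along k within a residue row. Returns (bits, end_node, end_res,
    start_node, start_res), coordinates 1-based.
    """
    M = match_lo.shape[0]
    L = enc.shape[0]
    neg = -1.0e30
    vm_p = np.full(M + 1, neg)
    vi_p = np.full(M + 1, neg)
    vd_p = np.full(M + 1, neg)
    smk_p = np.zeros(M + 1, dtype=np.int64)
    smi_p = np.zeros(M + 1, dtype=np.int64)
    sik_p = np.zeros(M + 1, dtype=np.int64)
    sii_p = np.zeros(M + 1, dtype=np.int64)
    sdk_p = np.zeros(M + 1, dtype=np.int64)
    sdi_p = np.zeros(M + 1, dtype=np.int64)
    best = neg
    b_ek = 1
    b_ei = 1
    b_sk = 1
    b_si = 1
    for i in range(1, L + 1):
        x = enc[i - 1]
        vm = np.full(M + 1, neg)
        vi = np.full(M + 1, neg)
        vd = np.full(M + 1, neg)
        smk = np.zeros(M + 1, dtype=np.int64)
        smi = np.zeros(M + 1, dtype=np.int64)
        sik = np.zeros(M + 1, dtype=np.int64)
        sii = np.zeros(M + 1, dtype=np.int64)
        sdk = np.zeros(M + 1, dtype=np.int64)
        sdi = np.zeros(M + 1, dtype=np.int64)
        for k in range(1, M + 1):
            # match state: fresh local entry, or continue from node k-1
            s = log_entry
            sk = k
            si = i
            if k > 1:
                c = vm_p[k - 1] + lt[k - 1, 0]  # M -> M
                if c > s:
                    s = c
                    sk = smk_p[k - 1]
                    si = smi_p[k - 1]
                c = vi_p[k - 1] + lt[k - 1, 3]  # I -> M
                if c > s:
                    s = c
                    sk = sik_p[k - 1]
                    si = sii_p[k - 1]
                c = vd_p[k - 1] + lt[k - 1, 5]  # D -> M
                if c > s:
                    s = c
                    sk = sdk_p[k - 1]
                    si = sdi_p[k - 1]
            vm[k] = s + match_lo[k - 1, x]
            smk[k] = sk
            smi[k] = si
        for k in range(2, M + 1):
            # delete chain, same residue row
            a = vm[k - 1] + lt[k - 1, 2]  # M -> D
            ak = smk[k - 1]
            ai = smi[k - 1]
            b = vd[k - 1] + lt[k - 1, 6]  # D -> D
            if b > a:
                a = b
                ak = sdk[k - 1]
                ai = sdi[k - 1]
            vd[k] = a
            sdk[k] = ak
            sdi[k] = ai
        for k in range(1, M + 1):
            a = vm_p[k] + lt[k, 1]  # M -> I
            ak = smk_p[k]
            ai = smi_p[k]
            b = vi_p[k] + lt[k, 4]  # I -> I
            if b > a:
                a = b
                ak = sik_p[k]
                ai = sii_p[k]
            vi[k] = a + ins_lo[k - 1, x]
            sik[k] = ak
            sii[k] = ai
            if vm[k] > best:
                best = vm[k]
                b_ek = k
                b_ei = i
                b_sk = smk[k]
                b_si = smi[k]
        vm_p, vi_p, vd_p = vm, vi, vd
        smk_p, smi_p = smk, smi
        sik_p, sii_p = sik, sii
        sdk_p, sdi_p = sdk, sdi
    return best, b_ek, b_ei, b_sk, b_si


def viterbi_bitscore(hmm: ProfileHMM, seq: ProteinSequence | str) -> ScoredAlignment:
    """Best single-hit local-alignment bit score of ``seq`` against ``hmm``.

    The maximum is over all contiguous local alignments entering any match
    node (uniform ``1/M`` entry) and exiting from any match node (free
    exit), of the log2-odds score versus the model's i.i.d. background.
    Deterministic; raises on alphabet mismatch.
    """
    if isinstance(seq, str):
        seq = ProteinSequence(protein_id="seq", genome_id="", residues=seq)
    if len(seq) < 1:
        raise AcetomodError("sequence must have length >= 1")
    enc = encode_sequence(seq)
    match_lo, ins_lo, log_trans = score_tables(hmm)
    log_entry = -math.log2(hmm.M)
    bits, ek, ei, sk, si = _viterbi_kernel(match_lo, ins_lo, log_trans, enc, log_entry)
    if bits <= -1.0e29:
        raise AcetomodError(
            f"{hmm.name}: no scorable alignment (zero-probability emissions "
            "for every residue)"
        )
    return ScoredAlignment(
        bit_score=float(bits),
        start_node=int(sk),
        end_node=int(ek),
        start_res=int(si),
        end_res=int(ei),
    )


def evalue(bits: float, mu: float, lam: float, n_targets: int) -> float:
    """Gumbel-tail E-value for a bit score.

    ``E = n_targets * (1 - exp(-exp(-lam * (bits - mu))))``; monotone
    non-increasing in ``bits`` and linear in ``n_targets``.
    """
    if lam <= 0:
        raise AcetomodError(f"Gumbel lambda must be positive, got {lam}")
    if n_targets < 1:
        raise AcetomodError(f"n_targets must be >= 1, got {n_targets}")
    u = math.exp(-lam * (bits - mu))
    return n_targets * (-math.expm1(-u))


def consensus(hmm: ProfileHMM) -> ProteinSequence:
    """Length-M sequence of per-node argmax match emissions.

    Ties break toward the alphabetically first residue.
    """
    from .hmmio import AMINO_ALPHABET

    idx = np.argmax(hmm.match_emissions, axis=1)  # argmax takes first on ties
    residues = "".join(AMINO_ALPHABET[j] for j in idx)
    return ProteinSequence(
        protein_id=f"{hmm.name}_consensus", genome_id="", residues=residues
    )
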