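"""Readers and writers for the on-disk formats the survey touches.

Covers HMMER3 profile text (``HMMER3/f`` and ``HMMER3/b`` dialects), protein
FASTA, HMMER ``--tblout`` tables, GTDB taxonomy tables, and Newick trees.
Profile probabilities are stored in linear space; the HMMER3 body encodes
them as negative natural logs with ``*`` for probability zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import (
    DuplicateIdError,
    HmmFormatError,
    ModelValidationError,
    SequenceAlphabetError,
    TaxonomyFormatError,
    TbloutFormatError,
)

#: HMMER's canonical amino-acid ordering (alphabetical one-letter codes).
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AMINO_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

#: Seven per-node transitions, in HMMER3 column order.
TRANSITION_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")

GTDB_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
GTDB_RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")

_NORM_TOL = 1e-4


@dataclass
class ProteinSequence:
    """One protein: identifier, source genome, and residues.

    Residues are uppercase letters from the 20-letter amino alphabet;
    ``X`` is permitted and treated as ambiguous (scores as background).
    """

    protein_id: str
    genome_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceAlphabetError(
                f"protein {self.protein_id!r}: empty sequence"
            )
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(AMINO_ALPHABET) - {"X"}
        if bad:
            raise SequenceAlphabetError(
                f"protein {self.protein_id!r}: illegal residue letter(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProfileHMM:
    """A profile HMM over the amino alphabet, probabilities in linear space.

    ``transitions`` has ``M + 1`` rows: row 0 is the begin node, rows
    ``1..M`` the match nodes, each a 7-tuple in :data:`TRANSITION_ORDER`.
    ``cutoffs`` maps ``GA``/``TC``/``NC`` to (sequence-bits, domain-bits)
    pairs when annotated on the model. ``gumbel`` holds the STATS LOCAL
    calibration (``viterbi_mu``, ``viterbi_lambda``, ``msv_mu``,
    ``msv_lambda``, ``forward_tau``, ``forward_lambda``) when present.
    """

    name: str
    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    accession: str | None = None
    cutoffs: dict[str, tuple[float, float]] = field(default_factory=dict)
    gumbel: dict[str, float] = field(default_factory=dict)
    insert0_emissions: np.ndarray | None = None

    def validate(self) -> None:
        """Check shapes and normalization; raise ModelValidationError."""
        if self.M < 1:
            raise ModelValidationError(f"{self.name}: model length must be >= 1")
        if self.match_emissions.shape != (self.M, 20):
            raise ModelValidationError(f"{self.name}: match emissions not {self.M}x20")
        if self.insert_emissions.shape != (self.M, 20):
            raise ModelValidationError(f"{self.name}: insert emissions not {self.M}x20")
        if self.transitions.shape != (self.M + 1, 7):
            raise ModelValidationError(f"{self.name}: transitions not {self.M + 1}x7")
        for arr, label in (
            (self.match_emissions, "match emission"),
            (self.insert_emissions, "insert emission"),
        ):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ModelValidationError(f"{self.name}: {label} outside [0, 1]")
            rows = arr.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > _NORM_TOL):
                bad = int(np.argmax(np.abs(rows - 1.0)))
                raise ModelValidationError(
                    f"{self.name}: {label} row {bad + 1} sums to {rows[bad]:.6f}"
                )
        if np.any(self.transitions < 0) or np.any(self.transitions > 1):
            raise ModelValidationError(f"{self.name}: transition outside [0, 1]")
        t = self.transitions
        for sums, label in (
            (t[:, 0:3].sum(axis=1), "match-state"),
            (t[:, 3:5].sum(axis=1), "insert-state"),
            (t[:, 5:7].sum(axis=1), "delete-state"),
        ):
            if np.any(np.abs(sums - 1.0) > _NORM_TOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ModelValidationError(
                    f"{self.name}: {label} transitions at node {bad} "
                    f"sum to {sums[bad]:.6f}"
                )
        if self.background.shape != (20,) or abs(self.background.sum() - 1.0) > _NORM_TOL:
            raise ModelValidationError(f"{self.name}: background not a 20-distribution")


@dataclass
class TaxonomyRecord:
    """GTDB 7-rank taxonomy for one genome accession."""

    genome_id: str
    ranks: dict[str, str]

    def rank(self, name: str) -> str:
        """Bare label at ``name`` (e.g. ``genus``), without the prefix."""
        return self.ranks[name][3:]


# ---------------------------------------------------------------------------
# HMMER3 profile text


def _logprob(token: str, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError as exc:
        raise HmmFormatError(f"non-numeric probability field {token!r}", lineno) from exc


def parse_hmmer3(path) -> list[ProfileHMM]:
    """Parse a HMMER3 text file, possibly containing several models.

    Log-space body values are converted to probabilities (``*`` becomes 0).
    GA/TC/NC cutoff pairs and STATS LOCAL Gumbel parameters are captured
    when present. Every returned model satisfies its normalization
    invariants; denormalized input fails loudly.
    """
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("HMMER3/"):
            raise HmmFormatError(
                f"expected HMMER3 format line, got {line[:40]!r}", i + 1
            )
        if not (line.startswith("HMMER3/f") or line.startswith("HMMER3/b")):
            raise HmmFormatError(
                "unsupported HMMER3 dialect (only HMMER3/f and HMMER3/b "
                f"text are accepted): {line[:40]!r}",
                i + 1,
            )
        model, i = _parse_one_model(lines, i + 1)
        model.validate()
        models.append(model)
    return models


def _parse_one_model(lines: list[str], i: int) -> tuple[ProfileHMM, int]:
    name = None
    accession = None
    length = None
    alph = None
    cutoffs: dict[str, tuple[float, float]] = {}
    gumbel: dict[str, float] = {}
    n = len(lines)
    while i < n:
        tokens = lines[i].split()
        if not tokens:
            i += 1
            continue
        key = tokens[0]
        if key == "HMM":
            break
        if key == "NAME":
            name = tokens[1] if len(tokens) > 1 else None
        elif key == "ACC":
            accession = tokens[1] if len(tokens) > 1 else None
        elif key == "LENG":
            try:
                length = int(tokens[1])
            except (IndexError, ValueError) as exc:
                raise HmmFormatError("malformed LENG line", i + 1) from exc
        elif key == "ALPH":
            alph = tokens[1].lower() if len(tokens) > 1 else None
        elif key in ("GA", "TC", "NC"):
            try:
                seq_bits = float(tokens[1].rstrip(";"))
                dom_bits = float(tokens[2].rstrip(";")) if len(tokens) > 2 else seq_bits
            except (IndexError, ValueError) as exc:
                raise HmmFormatError(f"malformed {key} cutoff line", i + 1) from exc
            cutoffs[key] = (seq_bits, dom_bits)
        elif key == "STATS":
            # STATS LOCAL <MSV|VITERBI|FORWARD> <mu/tau> <lambda>
            try:
                kind = tokens[2].upper()
                loc, lam = float(tokens[3]), float(tokens[4])
            except (IndexError, ValueError) as exc:
                raise HmmFormatError("malformed STATS line", i + 1) from exc
            if kind == "MSV":
                gumbel["msv_mu"], gumbel["msv_lambda"] = loc, lam
            elif kind == "VITERBI":
                gumbel["viterbi_mu"], gumbel["viterbi_lambda"] = loc, lam
            elif kind == "FORWARD":
                gumbel["forward_tau"], gumbel["forward_lambda"] = loc, lam
        # other header keys (DESC, DATE, NSEQ, EFFN, CKSUM, MAP, ...) ignored
        i += 1
    if i >= n:
        raise HmmFormatError("unexpected end of file before HMM body", n)
    if name is None:
        raise HmmFormatError("model missing NAME header", i + 1)
    if length is None:
        raise HmmFormatError(f"model {name!r} missing LENG header", i + 1)
    if alph != "amino":
        raise HmmFormatError(
            f"model {name!r}: non-amino alphabet {alph!r} not supported", i + 1
        )
    hmm_cols = lines[i].split()[1:]
    if hmm_cols != list(AMINO_ALPHABET):
        raise HmmFormatError(
            f"model {name!r}: HMM symbol line does not list the 20 amino "
            "letters in canonical order",
            i + 1,
        )
    i += 1  # skip transition-header line (m->m ...)
    i += 1

    def emission_row(lineno: int, tokens: list[str], what: str) -> np.ndarray:
        if len(tokens) != 20:
            raise HmmFormatError(
                f"model {name!r}: {what} row has {len(tokens)} values, expected 20",
                lineno + 1,
            )
        return np.array([_logprob(t, lineno + 1) for t in tokens])

    # Optional COMPO line: average match composition, used as background.
    background = np.full(20, 1.0 / 20.0)
    tokens = lines[i].split()
    if tokens and tokens[0] == "COMPO":
        background = emission_row(i, tokens[1:], "COMPO")
        background = background / background.sum()
        i += 1
    # Node 0: insert-state emissions, then begin-node transitions.
    insert0 = emission_row(i, lines[i].split(), "insert-0 emission")
    i += 1
    trans = np.zeros((length + 1, 7))
    tokens = lines[i].split()
    if len(tokens) != 7:
        raise HmmFormatError(
            f"model {name!r}: begin-node transition row has {len(tokens)} values",
            i + 1,
        )
    trans[0] = [_logprob(t, i + 1) for t in tokens]
    i += 1

    match = np.zeros((length, 20))
    insert = np.zeros((length, 20))
    for k in range(1, length + 1):
        tokens = lines[i].split()
        if not tokens or tokens[0] == "//":
            raise HmmFormatError(
                f"model {name!r}: body ended at node {k - 1} of {length}", i + 1
            )
        try:
            node = int(tokens[0])
        except ValueError as exc:
            raise HmmFormatError(
                f"model {name!r}: expected node index, got {tokens[0]!r}", i + 1
            ) from exc
        if node != k:
            raise HmmFormatError(
                f"model {name!r}: node index {node} out of order (expected {k})",
                i + 1,
            )
        match[k - 1] = emission_row(i, tokens[1:21], "match emission")
        i += 1
        insert[k - 1] = emission_row(i, lines[i].split(), "insert emission")
        i += 1
        tokens = lines[i].split()
        if len(tokens) != 7:
            raise HmmFormatError(
                f"model {name!r}: transition row has {len(tokens)} values", i + 1
            )
        trans[k] = [_logprob(t, i + 1) for t in tokens]
        i += 1
    if i >= n or lines[i].split() != ["//"]:
        raise HmmFormatError(f"model {name!r}: missing closing '//'", i + 1)
    i += 1
    model = ProfileHMM(
        name=name,
        accession=accession,
        M=length,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=background,
        cutoffs=cutoffs,
        gumbel=gumbel,
        insert0_emissions=insert0,
    )
    return model, i


def _fmt(p: float) -> str:
    # 7 decimals keeps the write->parse round trip within 1e-6 on probabilities
    return "*" if p <= 0.0 else f"{-math.log(p):.7f}"


def write_hmmer3(hmm: ProfileHMM, path) -> None:
    """Write one profile in HMMER3/f text, parseable by :func:`parse_hmmer3`.

    Zero probabilities are written as ``*``. Cutoff and STATS lines are
    emitted only for fields present on the model.
    """
    hmm.validate()
    out = []
    out.append("HMMER3/f [acetomod 0.1]")
    out.append(f"NAME  {hmm.name}")
    if hmm.accession:
        out.append(f"ACC   {hmm.accession}")
    out.append(f"LENG  {hmm.M}")
    out.append("ALPH  amino")
    # annotation flags HMMER expects; consensus column is required by
    # hmmsearch's profile configuration
    out.append("RF    no")
    out.append("MM    no")
    out.append("CONS  yes")
    out.append("CS    no")
    out.append("MAP   yes")
    for key in ("GA", "TC", "NC"):
        if key in hmm.cutoffs:
            seq_bits, dom_bits = hmm.cutoffs[key]
            out.append(f"{key}    {seq_bits:.2f} {dom_bits:.2f};")
    stats = hmm.gumbel
    if "msv_mu" in stats:
        out.append(
            f"STATS LOCAL MSV      {stats['msv_mu']:9.5f} {stats['msv_lambda']:9.5f}"
        )
    if "viterbi_mu" in stats:
        out.append(
            "STATS LOCAL VITERBI  "
            f"{stats['viterbi_mu']:9.5f} {stats['viterbi_lambda']:9.5f}"
        )
    if "forward_tau" in stats:
        out.append(
            "STATS LOCAL FORWARD  "
            f"{stats['forward_tau']:9.5f} {stats['forward_lambda']:9.5f}"
        )
    out.append("HMM          " + "        ".join(AMINO_ALPHABET))
    out.append(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
    )
    out.append("  COMPO   " + "  ".join(f"{_fmt(p):>7s}" for p in hmm.background))
    insert0 = (
        hmm.insert0_emissions if hmm.insert0_emissions is not None else hmm.background
    )
    out.append("          " + "  ".join(f"{_fmt(p):>7s}" for p in insert0))
    out.append("          " + "  ".join(f"{_fmt(p):>7s}" for p in hmm.transitions[0]))
    for k in range(1, hmm.M + 1):
        cons_letter = AMINO_ALPHABET[int(np.argmax(hmm.match_emissions[k - 1]))]
        out.append(
            f"{k:7d}   "
            + "  ".join(f"{_fmt(p):>7s}" for p in hmm.match_emissions[k - 1])
            + f"{k:7d} {cons_letter} - - -"
        )
        out.append(
            "          " + "  ".join(f"{_fmt(p):>7s}" for p in hmm.insert_emissions[k - 1])
        )
        out.append("          " + "  ".join(f"{_fmt(p):>7s}" for p in hmm.transitions[k]))
    out.append("//")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def write_hmmer3_many(hmms, path) -> None:
    """Concatenate several models into one HMMER3 text file."""
    import io as _io
    import os
    import tempfile

    chunks = []
    for hmm in hmms:
        fd, tmp = tempfile.mkstemp(suffix=".hmm")
        os.close(fd)
        try:
            write_hmmer3(hmm, tmp)
            with open(tmp) as fh:
                chunks.append(fh.read())
        finally:
            os.unlink(tmp)
    with open(path, "w") as fh:
        fh.write("".join(chunks))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, genome_id: str) -> list[ProteinSequence]:
    """Read a protein FASTA for one genome.

    The first whitespace-delimited token of each header is the protein id;
    residues are uppercased. Duplicate ids and illegal residues raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceAlphabetError(f"{path}: empty FASTA (no records)")
    seen: set[str] = set()
    out: list[ProteinSequence] = []
    for rec in records:
        pid = rec.id
        if pid in seen:
            raise DuplicateIdError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        out.append(ProteinSequence(protein_id=pid, genome_id=genome_id, residues=str(rec.seq)))
    return out


def write_fasta(proteins, path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for j in range(0, len(p.residues), 60):
                fh.write(p.residues[j : j + 60] + "\n")


# ---------------------------------------------------------------------------
# HMMER --tblout


def parse_tblout(path, genome_id: str = "", engine: str = "hmmsearch") -> list:
    """Parse HMMER per-sequence tabular output into :class:`~acetomod.search.Hit`.

    Comment lines (``#``) are skipped. Columns used: target name (1),
    query name (3), full-sequence E-value (5) and bit score (6).
    """
    from .search import Hit  # local import to avoid a cycle

    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 6:
                raise TbloutFormatError(
                    f"row has {len(tokens)} fields, expected >= 6", lineno
                )
            try:
                e_value = float(tokens[4])
                bit_score = float(tokens[5])
            except ValueError as exc:
                raise TbloutFormatError(
                    f"non-numeric score field in {tokens[4]!r}/{tokens[5]!r}", lineno
                ) from exc
            hits.append(
                Hit(
                    genome_id=genome_id,
                    protein_id=tokens[0],
                    hmm_name=tokens[2],
                    bit_score=bit_score,
                    e_value=e_value,
                    engine=engine,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# GTDB taxonomy

_ACCESSION_PREFIX = re.compile(r"^(RS_|GB_)")


def strip_accession_prefix(accession: str) -> str:
    """Drop GTDB's ``RS_``/``GB_`` database prefixes for joining."""
    return _ACCESSION_PREFIX.sub("", accession)


def parse_gtdb_taxonomy(path) -> list[TaxonomyRecord]:
    """Parse a two-column GTDB taxonomy table (accession, 7-rank string)."""
    out: list[TaxonomyRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split(None, 1)
            if len(parts) != 2:
                raise TaxonomyFormatError(
                    f"line {lineno}: expected two columns, got {len(parts)}"
                )
            accession, taxstring = parts[0].strip(), parts[1].strip()
            labels = [t.strip() for t in taxstring.split(";")]
            if len(labels) != 7:
                raise TaxonomyFormatError(
                    f"line {lineno}: taxonomy string has {len(labels)} ranks, "
                    "expected 7"
                )
            ranks: dict[str, str] = {}
            for name, prefix, label in zip(GTDB_RANK_NAMES, GTDB_RANK_PREFIXES, labels):
                if not label.startswith(prefix):
                    raise TaxonomyFormatError(
                        f"line {lineno}: rank {name} label {label!r} does not "
                        f"start with {prefix!r}"
                    )
                ranks[name] = label
            genome_id = strip_accession_prefix(accession)
            if genome_id in seen:
                raise DuplicateIdError(
                    f"line {lineno}: duplicate genome accession {genome_id!r}"
                )
            seen.add(genome_id)
            out.append(TaxonomyRecord(genome_id=genome_id, ranks=ranks))
    return out


def write_gtdb_taxonomy(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            taxstring = ";".join(rec.ranks[name] for name in GTDB_RANK_NAMES)
            fh.write(f"{rec.genome_id}\t{taxstring}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree; leaf labels are genome accessions."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
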