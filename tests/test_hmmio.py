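"""Format round trips and loud failure on malformed input."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest

from acetomod import hmmio, simulate
from acetomod.errors import (
    DuplicateIdError,
    HmmFormatError,
    ModelValidationError,
    SequenceAlphabetError,
    TaxonomyFormatError,
    TbloutFormatError,
)

MINIMAL_HMM = """\
HMMER3/f [toy]
NAME  mini
LENG  2
ALPH  amino
NC    25.00 25.00;
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.10536  2.99573  2.99573  0.10536  2.30259  0.00000        *
      1   0.10536  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.10536  2.99573  2.99573  0.10536  2.30259  0.69315  0.69315
      2   5.24702  0.10536  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702  5.24702
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.05129  2.99573        *  0.10536  2.30259  0.00000        *
//
"""


class TestParseHmmer3:
    def test_minimal_two_node_model(self, tmp_path):
        path = tmp_path / "mini.hmm"
        path.write_text(MINIMAL_HMM)
        (hmm,) = hmmio.parse_hmmer3(path)
        assert hmm.name == "mini" and hmm.M == 2
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-4)
        assert np.allclose(hmm.insert_emissions.sum(axis=1), 1.0, atol=1e-4)

    def test_nc_cutoff_line_captured(self, tmp_path):
        path = tmp_path / "mini.hmm"
        path.write_text(MINIMAL_HMM)
        (hmm,) = hmmio.parse_hmmer3(path)
        assert hmm.cutoffs["NC"] == (25.0, 25.0)
        assert "GA" not in hmm.cutoffs and "TC" not in hmm.cutoffs

    def test_star_means_probability_zero(self, tmp_path):
        path = tmp_path / "mini.hmm"
        path.write_text(MINIMAL_HMM)
        (hmm,) = hmmio.parse_hmmer3(path)
        assert hmm.transitions[0, 6] == 0.0  # begin-node d->d written as *
        assert hmm.transitions[2, 2] == 0.0  # last node has no delete exit

    def test_parses_real_hmmbuild_output(self, tmp_path):
        """A model emitted by HMMER's own hmmbuild parses and validates."""
        msa = tmp_path / "aln.sto"
        msa.write_text(
            "# STOCKHOLM 1.0\n"
            "s1  ACDEFGHIKLMNPQRSTVWY\n"
            "s2  ACDEFGHIKLMNPQRSTVWY\n"
            "s3  ACDEFGHIKLMNPQRSAVWY\n"
            "//\n"
        )
        out = tmp_path / "ref.hmm"
        proc = subprocess.run(
            ["hmmbuild", "--amino", str(out), str(msa)], capture_output=True
        )
        assert proc.returncode == 0, proc.stderr.decode()
        (hmm,) = hmmio.parse_hmmer3(out)
        hmm.validate()
        assert hmm.M == 20
        assert {"msv_mu", "viterbi_mu", "forward_tau"} <= set(hmm.gumbel)

    @pytest.mark.parametrize(
        "mangle, message",
        [
            (lambda t: t.replace("HMMER3/f", "HMMER2.0"), "dialect"),
            (lambda t: t.replace("ALPH  amino", "ALPH  DNA"), "alphabet"),
            (lambda t: t.replace("LENG  2", "LENG  two"), "LENG"),
            (
                lambda t: t.replace("      1   0.10536  5.24702", "      1   0.10536"),
                "row",
            ),
        ],
    )
    def test_malformed_input_raises_with_line_number(self, tmp_path, mangle, message):
        path = tmp_path / "bad.hmm"
        path.write_text(mangle(MINIMAL_HMM))
        with pytest.raises(HmmFormatError, match="line"):
            hmmio.parse_hmmer3(path)

    def test_denormalized_model_fails_loudly(self, tmp_path):
        bad = MINIMAL_HMM.replace(
            "      2   5.24702  0.10536", "      2   5.24702  5.24702"
        )
        path = tmp_path / "denorm.hmm"
        path.write_text(bad)
        with pytest.raises(ModelValidationError):
            hmmio.parse_hmmer3(path)


class TestWriteHmmer3:
    def test_round_trip_probabilities_within_1e6(self, tmp_path, toy_hmm):
        path = tmp_path / "rt.hmm"
        hmmio.write_hmmer3(toy_hmm, path)
        (back,) = hmmio.parse_hmmer3(path)
        assert np.allclose(back.match_emissions, toy_hmm.match_emissions, atol=1e-6)
        assert np.allclose(back.insert_emissions, toy_hmm.insert_emissions, atol=1e-6)
        assert np.allclose(back.transitions, toy_hmm.transitions, atol=1e-6)
        assert np.allclose(back.background, toy_hmm.background, atol=1e-6)
        assert back.name == toy_hmm.name
        assert back.cutoffs.keys() == toy_hmm.cutoffs.keys()
        for key in toy_hmm.cutoffs:
            assert back.cutoffs[key] == pytest.approx(toy_hmm.cutoffs[key], abs=0.005)

    def test_cutoff_absence_preserved(self, tmp_path, toy_hmm):
        import copy

        bare = copy.deepcopy(toy_hmm)
        bare.cutoffs = {}
        bare.gumbel = {}
        path = tmp_path / "bare.hmm"
        hmmio.write_hmmer3(bare, path)
        text = path.read_text()
        assert "GA " not in text and "TC " not in text and "NC " not in text
        (back,) = hmmio.parse_hmmer3(path)
        assert back.cutoffs == {} and back.gumbel == {}

    def test_single_cutoff_yields_single_line(self, tmp_path, toy_hmm):
        import copy

        one = copy.deepcopy(toy_hmm)
        one.cutoffs = {"NC": (30.0, 30.0)}
        path = tmp_path / "one.hmm"
        hmmio.write_hmmer3(one, path)
        lines = [
            ln for ln in path.read_text().splitlines() if ln[:3] in ("GA ", "TC ", "NC ")
        ]
        assert lines == ["NC    30.00 30.00;"]

    def test_zero_probabilities_written_as_star(self, tmp_path, toy_hmm):
        path = tmp_path / "star.hmm"
        hmmio.write_hmmer3(toy_hmm, path)
        body = path.read_text().splitlines()
        # begin-node row: d->d is probability zero
        begin_row = body[[i for i, ln in enumerate(body) if "m->m" in ln][0] + 3]
        assert begin_row.split()[-1] == "*"

    def test_unnormalized_model_rejected(self, toy_hmm, tmp_path):
        import copy

        broken = copy.deepcopy(toy_hmm)
        broken.match_emissions[0, 0] += 0.5
        with pytest.raises(ModelValidationError):
            hmmio.write_hmmer3(broken, tmp_path / "x.hmm")


class TestFasta:
    def test_read_two_records(self, tmp_path):
        path = tmp_path / "g.faa"
        path.write_text(">p1 desc\nACDEF\n>p2\nGHIKL\nMNPQR\n")
        seqs = hmmio.read_fasta(path, "g1")
        assert [s.protein_id for s in seqs] == ["p1", "p2"]
        assert seqs[1].residues == "GHIKLMNPQR"
        assert all(s.genome_id == "g1" for s in seqs)

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "g.faa"
        path.write_text(">p1\nacdef\n")
        assert hmmio.read_fasta(path, "g")[0].residues == "ACDEF"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "g.faa"
        path.write_text(">p1\nACDEF\n>p1\nGHIKL\n")
        with pytest.raises(DuplicateIdError):
            hmmio.read_fasta(path, "g")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.faa"
        path.write_text("")
        with pytest.raises(SequenceAlphabetError):
            hmmio.read_fasta(path, "g")

    def test_illegal_residue_rejected(self, tmp_path):
        path = tmp_path / "g.faa"
        path.write_text(">p1\nACDEFB\n")
        with pytest.raises(SequenceAlphabetError):
            hmmio.read_fasta(path, "g")


class TestTblout:
    HEADER = "#                    --- full sequence ---- \n# target name     accession  query name accession   E-value  score  bias\n"

    def test_data_rows_parsed_comments_skipped(self, tmp_path):
        path = tmp_path / "hits.tbl"
        rows = [
            "p1 - modA - 1.2e-45 310.5 0.1 0 0 0 0 0 0 0 0 0 0 0 -",
            "p2 - modA - 3.1e-02 12.0 0.0 0 0 0 0 0 0 0 0 0 0 0 -",
            "p3 - modB - 5e-10 88.8 0.2 0 0 0 0 0 0 0 0 0 0 0 -",
        ]
        path.write_text(self.HEADER * 3 + "\n".join(rows) + "\n# done\n")
        hits = hmmio.parse_tblout(path, genome_id="gX")
        assert len(hits) == 3
        assert hits[0].e_value == pytest.approx(1.2e-45)
        assert hits[0].bit_score == pytest.approx(310.5)
        assert hits[0].hmm_name == "modA" and hits[0].protein_id == "p1"
        assert all(h.genome_id == "gX" for h in hits)

    def test_comments_only_is_empty_not_error(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(self.HEADER)
        assert hmmio.parse_tblout(path) == []

    def test_non_numeric_score_reports_line(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text("p1 - modA - notanumber 310.5 0.1\n")
        with pytest.raises(TbloutFormatError, match="line 1"):
            hmmio.parse_tblout(path)


class TestTaxonomy:
    GOOD = (
        "G1\td__Archaea;p__Halobacteriota;c__Methanosarcinia;o__X;f__Y;"
        "g__Methanosarcina;s__Z\n"
    )

    def test_ranks_split_and_validated(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(self.GOOD)
        (rec,) = hmmio.parse_gtdb_taxonomy(path)
        assert rec.genome_id == "G1"
        assert rec.rank("genus") == "Methanosarcina"
        assert rec.ranks["domain"] == "d__Archaea"

    def test_gtdb_accession_prefixes_stripped(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(self.GOOD.replace("G1", "RS_GCF_000001.1"))
        (rec,) = hmmio.parse_gtdb_taxonomy(path)
        assert rec.genome_id == "GCF_000001.1"

    def test_empty_species_allowed(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(self.GOOD.replace("s__Z", "s__"))
        (rec,) = hmmio.parse_gtdb_taxonomy(path)
        assert rec.rank("species") == ""

    def test_six_ranks_rejected(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("G1\td__Archaea;p__H;c__M;o__X;f__Y;g__Z\n")
        with pytest.raises(TaxonomyFormatError):
            hmmio.parse_gtdb_taxonomy(path)

    def test_misplaced_prefix_rejected(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(self.GOOD.replace("p__Halobacteriota", "c__Halobacteriota"))
        with pytest.raises(TaxonomyFormatError):
            hmmio.parse_gtdb_taxonomy(path)


class TestNewick:
    def test_three_leaf_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A,(B,C));\n")
        tree = hmmio.read_newick(path)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == {"A", "B", "C"}

    def test_round_trip_preserves_leaf_set(self, tmp_path, community):
        path = tmp_path / "t.nwk"
        path.write_text(community.tree_newick + "\n")
        tree = hmmio.read_newick(path)
        out = tmp_path / "out.nwk"
        hmmio.write_newick(tree, out)
        again = hmmio.read_newick(out)
        labels = lambda t: sorted(
            leaf.taxon.label for leaf in t.leaf_node_iter()
        )
        assert labels(tree) == labels(again) == sorted(community.proteomes)
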