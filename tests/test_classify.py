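"""Category rules, rule-order audit, co-occurrence checks, prevalence."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from acetomod import classify
from acetomod.classify import (
    CATEGORY_RULES,
    DEFAULT_RULE_ORDER,
    assign_category,
    category_from_flags,
    check_cooccurrence,
    prevalence,
)
from acetomod.errors import AcetomodError
from acetomod.hmmio import TaxonomyRecord
from acetomod.modules import ACK, ACS, ECH, FPO_PRIME, FPOF, PTA, RNF, GenomeProfile, ModuleCall

PRIMITIVES = ("ack_pta", "acs", "rnf", "ech", "fpo_prime", "fpoF")


def make_profile(genome_id="g1", **flags) -> GenomeProfile:
    """Profile whose module calls realise the requested primitive flags."""
    calls = {}
    present = {
        ACK: flags.get("ack_pta", False),
        PTA: flags.get("ack_pta", False),
        ACS: flags.get("acs", False),
        RNF: flags.get("rnf", False),
        ECH: flags.get("ech", False),
        FPO_PRIME: flags.get("fpo_prime", False),
        FPOF: flags.get("fpoF", False),
    }
    for module_id, ok in present.items():
        calls[module_id] = ModuleCall(module_id, ok, 1 if ok else 0)
    return GenomeProfile(genome_id=genome_id, modules=calls)


def all_boolean_profiles():
    for bits in itertools.product([False, True], repeat=6):
        flags = dict(zip(PRIMITIVES, bits))
        flags["fpo_prime_only"] = flags["fpo_prime"] and not flags["fpoF"]
        flags["fpo_full"] = flags["fpo_prime"] and flags["fpoF"]
        yield flags


class TestAssignCategory:
    def test_category_i_exemplar(self):
        """Acs + Fpo'-only, no Rnf/Ech: the Methanothrix configuration."""
        call = assign_category(make_profile(acs=True, fpo_prime=True))
        assert call.category == "I"
        assert call.activation_axis == "acs"
        assert call.energy_axis == ("fpo_prime_only",)

    def test_category_ii_exemplar(self):
        """Ack+Pta with Rnf: the Methanosarcina configuration."""
        call = assign_category(make_profile(ack_pta=True, rnf=True))
        assert call.category == "II" and call.activation_axis == "ack_pta"

    def test_category_ii_via_ech(self):
        assert (
            assign_category(make_profile(ack_pta=True, ech=True)).category == "II"
        )

    def test_category_iii_exemplar(self):
        """Acs + Rnf + full Fpo: the Methanomethylovorans configuration."""
        call = assign_category(
            make_profile(acs=True, rnf=True, fpo_prime=True, fpoF=True)
        )
        assert call.category == "III"
        assert "fpo_full" in call.energy_axis

    def test_category_iv_putative(self):
        call = assign_category(make_profile(ack_pta=True, fpo_prime=True))
        assert call.category == "IV"

    def test_empty_profile_unclassified(self):
        call = assign_category(make_profile())
        assert call.category == "unclassified"
        assert call.activation_axis == "none" and call.energy_axis == ("none",)

    def test_iii_takes_precedence_over_i_shape(self):
        """Acs + Rnf + Fpo'-only is III: defined by the Acs/Rnf co-occurrence."""
        call = assign_category(make_profile(acs=True, rnf=True, fpo_prime=True))
        assert call.category == "III"

    def test_dual_activation_surfaced_but_classified(self):
        call = assign_category(make_profile(ack_pta=True, acs=True, rnf=True))
        assert call.activation_axis == "both"
        assert call.category == "III"  # rule order III before II


class TestRuleSpaceAudit:
    def test_every_profile_gets_exactly_one_category(self):
        for flags in all_boolean_profiles():
            cat = category_from_flags(flags)
            assert cat in ("I", "II", "III", "IV", "unclassified")

    def test_order_independence_outside_multifire_cell(self):
        """Rule order only matters where >1 rule fires simultaneously.

        With the Rnf/Ech exclusions in categories I and IV, every
        multi-fire profile carries both activation modules (the
        dual-activation cell the co-occurrence report surfaces): with Rnf
        both III and II fire, and with Fpo'-only (no Rnf/Ech) both I and
        IV fire. All single-activation profiles classify identically
        under every rule order.
        """
        multifire = set()
        for idx, flags in enumerate(all_boolean_profiles()):
            firing = [c for c in CATEGORY_RULES if CATEGORY_RULES[c](flags)]
            results = {
                category_from_flags(flags, order)
                for order in itertools.permutations(DEFAULT_RULE_ORDER)
            }
            if len(firing) > 1:
                multifire.add(idx)
                assert results == set(firing)
            else:
                assert len(results) == 1
        expected = {
            idx
            for idx, flags in enumerate(all_boolean_profiles())
            if flags["ack_pta"]
            and flags["acs"]
            and (
                flags["rnf"]
                or (flags["fpo_prime_only"] and not flags["ech"])
            )
        }
        assert multifire == expected


class TestCooccurrence:
    def test_conforming_community_has_empty_lists(self):
        profiles = [
            make_profile("g1", acs=True, fpo_prime=True),
            make_profile("g2", ack_pta=True, rnf=True, fpo_prime=True, fpoF=True),
            make_profile("g3", acs=True, rnf=True),
        ]
        report = check_cooccurrence(profiles)
        assert report.dual_activation == []
        assert report.putative_category_iv == []

    def test_dual_activation_genome_listed(self):
        profiles = [make_profile("gX", ack_pta=True, acs=True)]
        assert check_cooccurrence(profiles).dual_activation == ["gX"]

    def test_pure_function_of_profiles(self):
        profiles = [make_profile("g1", ack_pta=True, fpo_prime=True)]
        assert check_cooccurrence(profiles) == check_cooccurrence(profiles)


TAX_TEMPLATE = dict(
    zip(
        ("domain", "phylum", "class", "order", "family", "genus", "species"),
        (
            "d__Archaea",
            "p__Halobacteriota",
            "c__Methanosarcinia",
            "o__Methanosarcinales",
            "f__Methanosarcinaceae",
            "g__Methanosarcina",
            "s__",
        ),
    )
)


def tax(genome_id, genus):
    ranks = dict(TAX_TEMPLATE)
    ranks["genus"] = f"g__{genus}"
    return TaxonomyRecord(genome_id=genome_id, ranks=ranks)


class TestPrevalence:
    def test_toy_genus_fraction(self):
        profiles = [
            make_profile("g1", rnf=True),
            make_profile("g2", rnf=True),
            make_profile("g3"),
        ]
        taxonomy = [tax(g, "Methanosarcina") for g in ("g1", "g2", "g3")]
        (s,) = prevalence(profiles, None, taxonomy, "genus", "rnf")
        assert (s.k, s.n) == (2, 3)
        assert s.fraction == Fraction(2, 3)
        assert s.percent == 67

    def test_genus_counts_partition_class_counts(self):
        profiles = [make_profile(f"g{i}", acs=(i % 2 == 0)) for i in range(10)]
        taxonomy = [
            tax(f"g{i}", "Methanothrix" if i < 4 else "Methanolobus")
            for i in range(10)
        ]
        by_genus = prevalence(profiles, None, taxonomy, "genus", "acs")
        by_class = prevalence(profiles, None, taxonomy, "class", "acs")
        assert sum(s.k for s in by_genus) == by_class[0].k
        assert sum(s.n for s in by_genus) == by_class[0].n

    def test_category_target(self):
        profiles = [make_profile("g1", acs=True, fpo_prime=True), make_profile("g2")]
        calls = [assign_category(p) for p in profiles]
        taxonomy = [tax("g1", "Methanothrix"), tax("g2", "Methanothrix")]
        (s,) = prevalence(profiles, calls, taxonomy, "genus", "category:I")
        assert (s.k, s.n) == (1, 2)

    def test_unjoined_genome_warned_and_excluded(self, caplog):
        profiles = [make_profile("g1", rnf=True), make_profile("orphan", rnf=True)]
        taxonomy = [tax("g1", "Methanosarcina")]
        with caplog.at_level("WARNING"):
            (s,) = prevalence(profiles, None, taxonomy, "genus", "rnf")
        assert s.n == 1
        assert any("no taxonomy record" in r.message for r in caplog.records)

    def test_unknown_target_rejected(self):
        with pytest.raises(AcetomodError):
            prevalence([], None, [], "genus", "flux_capacitor")

    def test_generator_truth_matches_fractions(self, community):
        """On the synthetic community every genus fraction equals the
        generator's planted composition exactly."""
        from acetomod.pipeline import run_survey

        result = run_survey(community.proteomes, community.hmms)
        truth = community.truth["genomes"]
        for target, flag in (("ack_pta", "ack"), ("acs", "acs")):
            summaries = prevalence(
                result.profiles, result.calls, community.taxonomy, "genus", target
            )
            for s in summaries:
                in_genus = [
                    info
                    for info in truth.values()
                    if info["genus"] == "g__" + s.taxon
                ]
                expected_k = sum(1 for info in in_genus if flag in info["planted_genes"])
                expected_n = len(in_genus)
                assert s.n == expected_n
                assert s.k == expected_k
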