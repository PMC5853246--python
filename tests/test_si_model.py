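"""Sporophytic expression, analytic cross distributions, and the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cacaosi.si_model import (
    ConfigurationError,
    CrossSpec,
    DiploidGenotype,
    FullyIncompatibleCrossError,
    GameticFusionRule,
    SAllele,
    SIModel,
    ZygoticEliminationRule,
    classical_alleles,
    classify_offspring_parentage,
    expected_genotype_distribution,
    expected_unfused_fraction,
    expressed_specificities,
    simulate_mixed_pollination,
    simulate_progeny,
)


class TestExpressedSpecificities:
    def test_amorphous_homozygote_expresses_nothing(self, sf):
        assert expressed_specificities(DiploidGenotype("CH4", (sf, sf))) == frozenset()

    def test_active_allele_dominant_over_amorphous(self, sf, s_sca):
        expr = expressed_specificities(DiploidGenotype("CH4", (sf, s_sca)))
        assert {a.id for a in expr} == {"S_sca"}

    def test_codominant_pair_expressed_together(self):
        al = classical_alleles()
        expr = expressed_specificities(DiploidGenotype("S", (al["S2"], al["S3"])))
        assert {a.id for a in expr} == {"S2", "S3"}

    def test_dominant_silences_recessive(self):
        al = classical_alleles()
        expr = expressed_specificities(DiploidGenotype("S", (al["S1"], al["S4"])))
        assert {a.id for a in expr} == {"S1"}

    def test_recessive_alleles_silenced_by_dominant_amorphous(self):
        # S4/S5 are recessive to the amorphous Sf: Sf/S4 expresses nothing
        al = classical_alleles()
        expr = expressed_specificities(DiploidGenotype("S", (al["Sf"], al["S4"])))
        assert expr == frozenset()

    def test_unranked_allele_is_a_configuration_error(self):
        a = SAllele("S_x")  # no dominance rank
        with pytest.raises(ConfigurationError):
            expressed_specificities(DiploidGenotype("S", (a, a)))


class TestExpectedDistribution:
    def test_mendelian_selfing_without_rules(self, sf, s_sca):
        cross = CrossSpec.selfing({"L": DiploidGenotype("L", (sf, s_sca))})
        d = expected_genotype_distribution(cross, SIModel.none())
        assert d.as_tuple("L") == (0.25, 0.5, 0.25)

    def test_gametic_rule_selfing_gives_one_to_two(self, tsh516_selfing):
        # survivors of the fusion-failure rule segregate a:h = 1:2, no b
        cross, model = tsh516_selfing
        d = expected_genotype_distribution(cross, model)
        assert d.as_tuple("CH4") == pytest.approx((1 / 3, 2 / 3, 0.0))

    def test_zygotic_elimination_selfing(self, br59_selfing):
        cross, model = br59_selfing
        d = expected_genotype_distribution(cross, model)
        assert d.as_tuple("CH1") == pytest.approx((0.0, 2 / 3, 1 / 3))

    def test_non_activating_allele_keeps_mendelian_ratios(self):
        # Amelonado/Criollo heterozygotes crossed: the Criollo allele does
        # not activate elimination, all three genotypes appear 1:2:1
        a223, a228 = SAllele("A223"), SAllele("A228")
        geno = DiploidGenotype("CH1", (a223, a228))
        cross = CrossSpec(mother={"CH1": geno}, father={"CH1": geno})
        model = SIModel(
            zygotic_rules={
                "CH1": ZygoticEliminationRule(frozenset({("A225", "A223")}))
            }
        )
        d = expected_genotype_distribution(cross, model)
        assert d.as_tuple("CH1") == (0.25, 0.5, 0.25)

    def test_fully_incompatible_cross_is_signalled(self):
        al = classical_alleles()
        g = DiploidGenotype("CH4", (al["S1"], al["S1"]))
        cross = CrossSpec.selfing({"CH4": g})
        model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
        with pytest.raises(FullyIncompatibleCrossError):
            expected_genotype_distribution(cross, model)

    @given(
        m0=st.integers(0, 1), m1=st.integers(0, 1),
        f0=st.integers(0, 1), f1=st.integers(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_no_rules_reduce_to_mendelian(self, m0, m1, f0, f1):
        """Rule-free distributions equal direct gamete-pair enumeration."""
        pool = (SAllele("A"), SAllele("B"))
        mother = DiploidGenotype("L", (pool[m0], pool[m1]))
        father = DiploidGenotype("L", (pool[f0], pool[f1]))
        cross = CrossSpec(
            mother={"L": mother}, father={"L": father},
            class_alleles={"L": ("A", "B")},
        )
        d = expected_genotype_distribution(cross, SIModel.none())
        # independent oracle: enumerate the four equiprobable gamete pairs
        expected = {"a": 0.0, "h": 0.0, "b": 0.0}
        for f in mother.alleles:
            for m in father.alleles:
                ids = sorted((f.id, m.id))
                cls = {("A", "A"): "a", ("A", "B"): "h", ("B", "B"): "b"}[tuple(ids)]
                expected[cls] += 0.25
        assert d.as_tuple("L") == pytest.approx(
            (expected["a"], expected["h"], expected["b"])
        )
        assert sum(d["L"].values()) == pytest.approx(1.0)


class TestUnfusedFraction:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("Sf", "Sf"), 0.0),
            (("Sf", "S1"), 0.25),
            (("S2", "S3"), 0.50),
            (("S1", "S1"), 1.00),
        ],
    )
    def test_cytology_classes(self, pair, expected):
        """Selfing yields the classical 0 / 25 / 50 / 100 % unfused classes."""
        al = classical_alleles()
        g = DiploidGenotype("CH4", (al[pair[0]], al[pair[1]]))
        cross = CrossSpec.selfing({"CH4": g})
        model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
        assert expected_unfused_fraction(cross, model) == pytest.approx(expected)


class TestSimulateProgeny:
    def test_eliminated_class_never_appears(self, br59_selfing):
        cross, model = br59_selfing
        sim = simulate_progeny(cross, model, seed=11)
        counts = sim.class_counts("CH1")
        assert counts["a"] == 0
        n, p = 109, 2 / 3
        assert abs(counts["h"] - n * p) <= 3 * np.sqrt(n * p * (1 - p))
        assert sim.ovule_fates["unfused"] == 0  # pre-fusion contract

    def test_fates_partition_all_ovules(self, tsh516_selfing):
        cross, model = tsh516_selfing
        cross.baseline_abortion = 0.10
        sim = simulate_progeny(cross, model, seed=7)
        assert sum(sim.ovule_fates.values()) == cross.n_offspring

    def test_rule_free_selfing_is_one_two_one(self, sf, s_sca):
        cross = CrossSpec.selfing(
            {"L": DiploidGenotype("L", (sf, s_sca))},
            n_offspring=10_000,
            baseline_abortion=0.0,
        )
        sim = simulate_progeny(cross, SIModel.none(), seed=3)
        c = sim.class_counts("L")
        obs = [c["a"], c["h"], c["b"]]
        stat, p = stats.chisquare(obs, f_exp=[2500, 5000, 2500])
        assert p > 0.001

    def test_unfused_fraction_converges(self, tsh516_selfing):
        cross, model = tsh516_selfing
        cross.n_offspring = 10_000
        sim = simulate_progeny(cross, model, seed=4)
        frac = sim.ovule_fates["unfused"] / cross.n_offspring
        assert abs(frac - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_zygotic_rule_leaves_abortion_at_baseline(self, br59_selfing):
        """Pre-fusion elimination adds no ovule abortion, selfing or not."""
        cross, model = br59_selfing
        cross.n_offspring = 20_000
        cross.baseline_abortion = 0.10
        sim = simulate_progeny(cross, model, seed=5)
        frac = sim.ovule_fates["baseline_aborted"] / cross.n_offspring
        assert abs(frac - 0.10) <= 3 * np.sqrt(0.1 * 0.9 / 20_000)
        assert sim.ovule_fates["unfused"] == 0

    def test_impossible_redraw_raises(self):
        a = SAllele("A")
        g = DiploidGenotype("CH1", (a, a))
        cross = CrossSpec.selfing({"CH1": g}, baseline_abortion=0.0)
        model = SIModel(
            zygotic_rules={"CH1": ZygoticEliminationRule(frozenset({("A", "A")}))}
        )
        with pytest.raises(FullyIncompatibleCrossError):
            simulate_progeny(cross, model, seed=0)


class TestMixedPollination:
    def _si_selfing(self, n=2000, mentor=0.5):
        al = classical_alleles()
        g = DiploidGenotype("CH4", (al["Sf"], al["S1"]))
        cross = CrossSpec.selfing(
            {"CH4": g}, n_offspring=n, mentor_fraction=mentor, baseline_abortion=0.0
        )
        model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
        return cross, model

    def test_no_mentor_on_si_tree_drops_all_fruit(self):
        al = classical_alleles()
        g = DiploidGenotype("CH4", (al["S1"], al["S1"]))
        cross = CrossSpec.selfing(
            {"CH4": g}, n_offspring=400, mentor_fraction=0.0, baseline_abortion=0.0
        )
        model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
        sim = simulate_mixed_pollination(
            cross, model, ovules_per_fruit=40, retention_threshold=0.2, seed=1
        )
        assert not sim.fruit_retained.any()
        assert len(sim.viable_offspring) == 0

    def test_pure_mentor_pollination_yields_no_viable_selfs(self):
        cross, model = self._si_selfing(n=400, mentor=1.0)
        sim = simulate_mixed_pollination(cross, model, ovules_per_fruit=40, seed=2)
        assert (sim.offspring["parentage"] == "mentor").all()
        assert len(sim.viable_offspring) == 0

    def test_viable_selfs_follow_analytic_distribution(self):
        cross, model = self._si_selfing(n=5000, mentor=0.5)
        sim = simulate_mixed_pollination(cross, model, ovules_per_fruit=40, seed=3)
        viable = sim.viable_offspring
        assert (viable["parentage"] == "self").all()
        c = viable[f"CH4_class"].value_counts()
        n = len(viable)
        for cls, p in (("a", 1 / 3), ("h", 2 / 3)):
            assert abs(c.get(cls, 0) - n * p) <= 3 * np.sqrt(n * p * (1 - p))
        assert c.get("b", 0) == 0
        # mentor rescue: every fruit retains at threshold 0
        assert sim.fruit_retained.all()


class TestParentageClassification:
    def test_foreign_allele_from_pollen_parent_is_outcross(self):
        assert (
            classify_offspring_parentage(
                {"m1": (133, 999)}, {"m1": (133, 145)}, {"m1": (999, 999)}
            )
            == "outcross"
        )

    def test_excluded_pollen_parent_is_self(self):
        assert (
            classify_offspring_parentage(
                {"m1": (133, 145)}, {"m1": (133, 145)}, {"m1": (200, 200)}
            )
            == "self"
        )

    def test_compatible_with_both_parents_is_ambiguous(self):
        assert (
            classify_offspring_parentage(
                {"m1": (133, 145)}, {"m1": (133, 145)}, {"m1": (133, 145)}
            )
            == "ambiguous"
        )

    def test_all_markers_missing_is_an_error(self):
        with pytest.raises(ValueError):
            classify_offspring_parentage({"m1": None}, {"m1": (1, 2)}, {"m1": (3, 4)})
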