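"""Exact test, FDR control, combination screen, and allele dose fits."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cacaosi.diagnostic_screen import (
    PhenotypeTable,
    SSRGenotypeTable,
    allele_dose_fit,
    allele_presence_screen,
    bh_qvalues,
    combo_screen,
    enumerate_combos,
    fisher_exact,
)
from cacaosi._logistic import fit_logistic
from cacaosi.synthetic_data import default_assoc_config, gen_association_population


def _fisher_oracle(table):
    """Brute-force two-sided Fisher p by enumerating margin-fixed tables."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    return sum(
        point(x)
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        if point(x) <= p_obs * (1 + 1e-7)
    )


class TestFisherExact:
    def test_balanced_table_is_null(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_perfect_association(self):
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_moderate_association(self):
        assert fisher_exact([[2, 8], [8, 2]]) == pytest.approx(0.023, abs=5e-4)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[5, 0], [7, 0]]) == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                _fisher_oracle(t.tolist()), rel=1e-7
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                sps.fisher_exact(t)[1], rel=1e-6
            )


class TestBHQvalues:
    def test_hand_computed_step_up(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_passes_through(self):
        assert bh_qvalues([0.3]) == pytest.approx([0.3])

    def test_equal_ps_unchanged(self):
        assert bh_qvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_against_statsmodels_and_dominance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        assert np.all(q >= p)
        sm_q = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(sm_q)
        # rejection sets agree with classical BH at several alphas
        for alpha in (0.01, 0.05, 0.2):
            assert set(np.flatnonzero(q <= alpha)) == set(
                np.flatnonzero(multipletests(p, alpha=alpha, method="fdr_bh")[0])
            )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.2])


class TestEnumerateCombos:
    def test_hand_countable_two_marker_table(self):
        data = pd.DataFrame(
            {
                "M1": [(1, 1), (1, 2), (1, 1), (1, 2)],
                "M2": [(3, 3), (3, 3), (3, 4), (3, 4)],
            },
            index=list("wxyz"),
        )
        combos = enumerate_combos(SSRGenotypeTable(data), max_order=2, min_support=1)
        assert len(combos) == 4 + 4  # 4 singletons + 4 observed pairs

    def test_min_support_above_n_empty(self, toy_ssr_population):
        ssr, _ = toy_ssr_population
        assert enumerate_combos(ssr, max_order=2, min_support=11) == []

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        genos = [(1, 1), (1, 2), (2, 2)]
        data = pd.DataFrame(
            {
                m: [genos[rng.integers(3)] for _ in range(30)]
                for m in ("A", "B", "C", "D")
            },
            index=[f"i{k}" for k in range(30)],
        )
        table = SSRGenotypeTable(data)
        for min_support in (1, 3):
            combos = enumerate_combos(table, max_order=3, min_support=min_support)
            # oracle: count observed joint genotypes per subset directly
            expected = 0
            for k in (1, 2, 3):
                for subset in itertools.combinations(sorted(data.columns), k):
                    seen: dict[tuple, int] = {}
                    for _, row in data.iterrows():
                        key = tuple(row[m] for m in subset)
                        seen[key] = seen.get(key, 0) + 1
                    expected += sum(v >= min_support for v in seen.values())
            assert len(combos) == expected

    def test_invalid_order_rejected(self, toy_ssr_population):
        ssr, _ = toy_ssr_population
        with pytest.raises(ValueError):
            enumerate_combos(ssr, max_order=4)


class TestComboScreen:
    def test_probabilities_are_empirical_proportions(self):
        rng = np.random.default_rng(21)
        n = 120
        geno = [(1, 1) if rng.random() < 0.4 else (1, 2) for _ in range(n)]
        sc = rng.integers(0, 2, n)
        data = pd.DataFrame({"M": geno}, index=[f"i{k}" for k in range(n)])
        phen = PhenotypeTable(pd.DataFrame({"sc_status": sc}, index=data.index))
        res = combo_screen(SSRGenotypeTable(data), phen, max_order=1, min_support=1)
        for r in res:
            carrier = np.array([g == r.combo.terms[0][1] for g in geno])
            assert r.prob_sc_has == pytest.approx(sc[carrier].mean())
            assert r.prob_sc_not == pytest.approx(sc[~carrier].mean())

    def test_logistic_mle_equals_empirical_proportions(self):
        """Single-indicator logistic MLE reproduces the group proportions."""
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 300)
        y = (rng.random(300) < np.where(x == 1, 0.7, 0.3)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(300), x]), y)
        probs = fit.predict(np.array([[1, 0], [1, 1]]))
        assert probs[0] == pytest.approx(y[x == 0].mean(), abs=1e-6)
        assert probs[1] == pytest.approx(y[x == 1].mean(), abs=1e-6)

    def test_pure_carrier_group_flags_separation(self, toy_ssr_population):
        ssr, phen = toy_ssr_population
        res = combo_screen(ssr, phen, max_order=1, min_support=1)
        top = res[0]
        assert top.combo.terms == (("M1", (161, 161)),)
        assert top.prob_sc_has == 1.0 and top.prob_sc_not == 0.0
        assert top.separation

    def test_planted_predictive_genotype_ranks_first(self):
        ssr, phen, _, truth = gen_association_population(
            default_assoc_config(n=400, r2=1.0, seed=5)
        )
        res = combo_screen(ssr, phen, max_order=1, min_support=3)
        top = res[0]
        marker, geno = top.combo.terms[0]
        assert marker == truth["planted_marker"]
        assert geno == (truth["planted_allele"], truth["planted_allele"])

    def test_single_class_phenotype_rejected(self, toy_ssr_population):
        ssr, _ = toy_ssr_population
        phen = PhenotypeTable(
            pd.DataFrame({"sc_status": [1] * 10}, index=ssr.individuals)
        )
        with pytest.raises(ValueError):
            combo_screen(ssr, phen)

    def test_invariant_to_input_order(self, toy_ssr_population):
        ssr, phen = toy_ssr_population
        shuffled = SSRGenotypeTable(
            ssr.data.sample(frac=1.0, random_state=4)[["M2", "M1"]]
        )
        a = combo_screen(ssr, phen, max_order=2, min_support=1)
        b = combo_screen(shuffled, phen, max_order=2, min_support=1)
        assert [(str(r.combo), r.p, r.q) for r in a] == [
            (str(r.combo), r.p, r.q) for r in b
        ]


class TestAllelePresenceScreen:
    def test_planted_allele_attains_minimum_q(self):
        ssr, phen, _, truth = gen_association_population(
            default_assoc_config(n=700, r2=0.9, seed=8)
        )
        res = allele_presence_screen(ssr, phen)
        assert (res[0].marker, res[0].allele) == (
            truth["planted_marker"],
            truth["planted_allele"],
        )

    def test_consistency_with_hand_built_table(self, toy_ssr_population):
        ssr, phen = toy_ssr_population
        res = allele_presence_screen(ssr, phen)
        r161 = next(r for r in res if (r.marker, r.allele) == ("M1", 161))
        # carriers of 161: trees 0-5 and 8 (6 SC... 4 SC, 3 SI); check table
        carriers = [g for g in ssr.data["M1"] if 161 in g]
        assert r161.n_carriers == len(carriers)
        assert r161.p == pytest.approx(fisher_exact(r161.contingency))

    def test_ubiquitous_allele_warns_zero_margin(self):
        data = pd.DataFrame(
            {"M": [(1, 1), (1, 2), (1, 1), (1, 2), (1, 1), (1, 2)]},
            index=[f"i{k}" for k in range(6)],
        )
        phen = PhenotypeTable(
            pd.DataFrame({"sc_status": [0, 1, 0, 1, 0, 1]}, index=data.index)
        )
        with pytest.warns(UserWarning):
            res = allele_presence_screen(SSRGenotypeTable(data), phen)
        r1 = next(r for r in res if r.allele == 1)
        assert r1.p == 1.0


class TestAlleleDoseFit:
    @staticmethod
    def _dose_population(n, intercept, slope, seed):
        rng = np.random.default_rng(seed)
        dose = rng.integers(0, 3, n)
        logit = intercept + slope * dose
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        cells = [
            {0: (1, 1), 1: (1, 9), 2: (9, 9)}[d] for d in dose
        ]  # allele 9 carried d times
        data = pd.DataFrame({"M": cells}, index=[f"i{k}" for k in range(n)])
        phen = PhenotypeTable(pd.DataFrame({"sc_status": y}, index=data.index))
        return SSRGenotypeTable(data), phen

    def test_parameter_recovery(self):
        ssr, phen = self._dose_population(2000, 0.5, -1.0, seed=14)
        r = allele_dose_fit(ssr, phen, "M", 9)
        assert abs(r.intercept - 0.5) <= 0.15
        assert abs(r.slope + 1.0) <= 0.15
        assert not r.separation

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        ssr, phen = self._dose_population(500, 0.2, -0.8, seed=15)
        r = allele_dose_fit(ssr, phen, "M", 9)
        d = ssr.dose("M", 9).to_numpy()
        y = phen.sc_status.to_numpy()
        X = sm.add_constant(d)
        sm_fit = sm.Logit(y, X).fit(disp=0)
        assert r.intercept == pytest.approx(sm_fit.params[0], abs=1e-5)
        assert r.slope == pytest.approx(sm_fit.params[1], abs=1e-5)

    def test_flat_dose_response(self):
        ssr, phen = self._dose_population(3000, 0.4, 0.0, seed=16)
        r = allele_dose_fit(ssr, phen, "M", 9)
        p0, p1, p2 = r.prob_sc
        assert abs(p0 - p1) < 0.08 and abs(p1 - p2) < 0.08

    def test_separation_falls_back_to_penalized_fit(self):
        # every two-copy carrier is SI: quasi-separation, Firth fallback
        rng = np.random.default_rng(17)
        dose = np.repeat([0, 1, 2], [60, 60, 40])
        y = np.concatenate(
            [
                (rng.random(60) < 0.8).astype(int),
                (rng.random(60) < 0.3).astype(int),
                np.zeros(40, dtype=int),
            ]
        )
        cells = [{0: (1, 1), 1: (1, 9), 2: (9, 9)}[d] for d in dose]
        data = pd.DataFrame({"M": cells}, index=[f"i{k}" for k in range(160)])
        phen = PhenotypeTable(pd.DataFrame({"sc_status": y}, index=data.index))
        r = allele_dose_fit(SSRGenotypeTable(data), phen, "M", 9)
        assert r.separation and r.fit.firth
        assert r.prob_sc[2] < 0.1
        assert np.isfinite([r.intercept, r.slope]).all()

    def test_single_dose_is_an_error(self):
        data = pd.DataFrame(
            {"M": [(1, 1)] * 10}, index=[f"i{k}" for k in range(10)]
        )
        phen = PhenotypeTable(
            pd.DataFrame({"sc_status": [0, 1] * 5}, index=data.index)
        )
        with pytest.raises(ValueError):
            allele_dose_fit(SSRGenotypeTable(data), phen, "M", 1)
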