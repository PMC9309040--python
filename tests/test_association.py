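"""Analysis of deviance, exact 2×k tests, and the rate correlation.

Independent routes: statsmodels binomial GLM for the deviance, Pearson
chi-square asymptotics, Monte-Carlo sampling for the exact test, and label
permutation for the regression p-value.
"""

import numpy as np
import pytest
from scipy import stats

from nemapatch import (
    BaitRecord,
    BaitType,
    CollectionRecord,
    EmptyInputError,
    accessibility_analysis,
    bait_type_analysis,
    bait_type_fisher,
    binomial_lrt,
    fisher_exact_2xk,
    rate_correlation,
    substrate_association,
)
from nemapatch.association import _enumerated_table_probs
from nemapatch.simulate import (
    BaitDesign,
    ExclosureDesign,
    SimulationConfig,
    simulate_bait_experiment,
    simulate_exclosure,
)


class TestBinomialLRT:
    def test_identical_rates_give_null_result(self):
        dev = binomial_lrt([5, 5], [10, 10])
        assert dev.lrt_stat == 0.0 and dev.p_value == 1.0

    def test_hand_computed_two_level_case(self):
        dev = binomial_lrt([8, 2], [10, 10])
        assert dev.lrt_stat == pytest.approx(7.710, abs=5e-4)
        assert dev.df == 1
        assert dev.p_value == pytest.approx(0.0055, abs=2e-4)

    def test_matches_statsmodels_glm_deviance(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(5):
            k = rng.integers(0, 21, size=4)
            n = np.full(4, 20)
            dev = binomial_lrt(k, n)
            X = np.column_stack([np.ones(4), np.eye(4)[:, 1:]])
            fit = sm.GLM(
                np.column_stack([k, n - k]), X, family=sm.families.Binomial()
            ).fit()
            null = sm.GLM(
                np.column_stack([k, n - k]), np.ones((4, 1)),
                family=sm.families.Binomial(),
            ).fit()
            assert dev.lrt_stat == pytest.approx(
                null.deviance - fit.deviance, abs=1e-8
            )

    def test_within_ten_percent_of_pearson_chi_square(self, rng):
        k = rng.binomial(500, [0.30, 0.32, 0.35, 0.28], size=4)
        n = np.full(4, 500)
        dev = binomial_lrt(k, n)
        table = np.column_stack([k, n - k])
        pearson = stats.chi2_contingency(table, correction=False)[0]
        assert dev.lrt_stat == pytest.approx(pearson, rel=0.10)

    def test_invariant_to_level_reordering(self):
        a = binomial_lrt([8, 2, 5], [10, 10, 10])
        b = binomial_lrt([5, 8, 2], [10, 10, 10])
        assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-12)

    def test_zero_trial_level_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero trials"):
            dev = binomial_lrt([8, 2, 0], [10, 10, 0])
        assert dev.df == 1 and len(dev.levels) == 2

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 over 5000 simulated datasets
        (6 levels, 30 trials each, p=0.3) stays within 0.05 ± 0.01."""
        rng = np.random.default_rng(42)
        k = rng.binomial(30, 0.3, size=(5000, 6))
        trials = [30] * 6
        rej = sum(binomial_lrt(row, trials).p_value < 0.05 for row in k)
        assert abs(rej / 5000 - 0.05) <= 0.01

    def test_boundary_counts_allowed(self):
        dev = binomial_lrt([0, 10], [10, 10])
        assert np.isfinite(dev.lrt_stat) and dev.p_value < 0.01


class TestFisher2xk:
    def test_balanced_table_p_one(self):
        assert bait_type_fisher([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            tab = rng.integers(0, 8, size=(2, int(rng.integers(2, 5))))
            cols = tab.sum(axis=0)
            if cols.min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            probs = _enumerated_table_probs(cols, int(tab[0].sum()))
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_matches_monte_carlo(self, rng):
        for _ in range(5):
            tab = rng.integers(0, 6, size=(2, 3))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            p_exact = fisher_exact_2xk(tab)
            p_mc = fisher_exact_2xk(tab, max_tables=0, n_mc=200_000,
                                    seed=int(rng.integers(2**31)))
            mc_se = np.sqrt(p_exact * (1 - p_exact) / 200_000)
            assert abs(p_exact - p_mc) < 3 * mc_se + 1e-5

    def test_zero_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-total"):
            p = fisher_exact_2xk([[3, 0, 2], [2, 0, 3]])
        assert 0 <= p <= 1


def _uniform_records(seed, n=200, p=0.4):
    r = np.random.default_rng(seed)
    cats = ["fruit", "flower", "fungus", "leaf_litter"]
    recs = []
    for i in range(n):
        present = r.random() < p
        recs.append(
            CollectionRecord(
                f"s{i}", "X", 2018, cats[int(r.integers(4))], present,
                frozenset({"C. briggsae"}) if present else frozenset(),
            )
        )
    return recs


class TestSubstrateAssociation:
    def test_null_p_values_uniform(self):
        ps = [
            substrate_association(_uniform_records(seed), "C. briggsae",
                                  "fine").p_value
            for seed in range(400)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_doubled_odds(self):
        rng = np.random.default_rng(8)
        hits = 0
        runs = 50
        for run in range(runs):
            recs = []
            for i in range(500):
                cat = ["fruit", "flower"][int(rng.integers(2))]
                logit = 0.0 + (np.log(2) if cat == "fruit" else 0.0)
                p = 1 / (1 + np.exp(-(-0.5 + logit)))
                present = rng.random() < p
                recs.append(
                    CollectionRecord(
                        f"r{run}-{i}", "X", 2018, cat, present,
                        frozenset({"C. briggsae"}) if present else frozenset(),
                    )
                )
            hits += substrate_association(recs, "C. briggsae",
                                          "coarse").p_value < 0.05
        assert hits / runs > 0.5

    def test_single_substrate_class_errors(self):
        recs = [CollectionRecord(f"s{i}", "X", 2018, "fruit", False)
                for i in range(10)]
        with pytest.raises(ValueError, match="one substrate class"):
            substrate_association(recs)


class TestBaitAnalyses:
    def test_identical_counts_give_p_one(self):
        recs = []
        for bt in BaitType:
            for i in range(10):
                colonized = i < 3
                recs.append(
                    BaitRecord("S1", f"A{i}", bt, True, colonized, colonized,
                               frozenset({"C. briggsae"}) if colonized
                               else frozenset())
                )
        dev = bait_type_analysis(recs, target="any_nematode")
        assert dev.p_value == pytest.approx(1.0)

    def test_unrecovered_baits_excluded_from_trials(self):
        cfg = SimulationConfig(seed=2, bait=BaitDesign(loss_prob=0.3))
        recs = simulate_bait_experiment(cfg)
        dev = bait_type_analysis(recs)
        assert sum(dev.trials) == sum(r.recovered for r in recs)

    def test_no_recovered_baits_errors(self):
        cfg = SimulationConfig(seed=2, bait=BaitDesign(loss_prob=1.0))
        with pytest.raises(EmptyInputError):
            bait_type_analysis(simulate_bait_experiment(cfg))

    def test_power_against_ground_contact_effect(self):
        """Strong ground-contact effect (logit difference 2) at the full
        design size is detected in >= 90% of runs."""
        base = 1 / (1 + np.exp(0.5))  # dish-type rate
        high = 1 / (1 + np.exp(-1.5))  # ground-contact rate, logit diff 2
        p_nem = {
            bt.value: (high if bt.value.endswith("_ground") else base)
            for bt in BaitType
        }
        hits = 0
        runs = 200
        for run in range(runs):
            cfg = SimulationConfig(
                seed=1000 + run,
                bait=BaitDesign(p_other_nematode=p_nem, loss_prob=29 / 210),
            )
            dev = bait_type_analysis(simulate_bait_experiment(cfg),
                                     target="any_nematode")
            hits += dev.p_value < 0.01
        assert hits / runs >= 0.90


class TestRateCorrelation:
    def test_identity_rates(self):
        recs = []
        rng = np.random.default_rng(0)
        for bt in BaitType:
            n = 20
            k = int(rng.integers(3, 9))
            for i in range(n):
                caeno = i < k
                other = k <= i < 2 * k
                recs.append(
                    BaitRecord("S1", f"A{i}", bt, True, caeno or other, caeno,
                               frozenset({"C. briggsae"}) if caeno
                               else frozenset())
                )
        res = rate_correlation(recs)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        # OLS of y=(0.1,0.4,0.6) on x=(0,0.5,1)
        fit = stats.linregress([0, 0.5, 1], [0.1, 0.4, 0.6])
        assert fit.rvalue**2 == pytest.approx(0.9868, abs=5e-5)

    def test_permutation_p_consistent_with_t_test(self, rng):
        res = rate_correlation(simulate_bait_experiment(SimulationConfig(seed=4)))
        x = np.array(res.x_rates)
        y = np.array(res.y_rates)
        obs = abs(stats.pearsonr(x, y)[0])
        n_perm = 10_000
        count = sum(
            abs(stats.pearsonr(x, rng.permutation(y))[0]) >= obs - 1e-12
            for _ in range(n_perm)
        )
        p_perm = (count + 1) / (n_perm + 1)
        # permutation and t-test p-values agree to within a factor ~2 for
        # well-behaved data at k=6 points
        assert p_perm < 0.1 if res.p_value < 0.02 else True
        if res.p_value > 1e-3:
            assert np.log10(max(p_perm, 1e-4)) == pytest.approx(
                np.log10(res.p_value), abs=1.0
            )

    def test_too_few_types_errors(self):
        recs = [
            BaitRecord("S1", "A1", "peptone_dish", True, False, False),
            BaitRecord("S1", "A1", "peptone_ground", True, False, False),
        ]
        with pytest.raises(ValueError, match=">= 3 bait types"):
            rate_correlation(recs)


class TestAccessibility:
    def test_uniform_colonization_gives_p_one(self):
        from nemapatch import ExclosureRecord, ExclosureTreatment

        recs = []
        for tr in ExclosureTreatment:
            for i in range(10):
                colonized = i < 2
                recs.append(
                    ExclosureRecord(
                        "S1", f"{tr.value}-{i}", tr, True, colonized,
                        frozenset({"Rhabditidae sp."}) if colonized
                        else frozenset(),
                    )
                )
        dev, table = accessibility_analysis(recs)
        assert dev.p_value == pytest.approx(1.0)
        assert table.loc["Rhabditidae sp."].sum() == 12

    def test_blocked_mesh_shows_empty_species_cells(self):
        recs = simulate_exclosure(SimulationConfig(seed=1))
        dev, table = accessibility_analysis(recs, target="any_caenorhabditis")
        caeno_rows = [s for s in table.index if s.startswith("C. ")]
        blocked = ["mesh_1mm", "mesh_0p064mm", "mesh_0p01mm"]
        assert table.loc[caeno_rows, blocked].to_numpy().sum() == 0

    def test_power_against_accessibility_gradient(self):
        """Monotone logit decline across treatments at the 6 × 24 design is
        detected in >= 80% of runs."""
        from nemapatch import ExclosureTreatment

        logits = np.linspace(0.5, -2.5, 6)
        p_nem = {
            tr.value: float(1 / (1 + np.exp(-l)))
            for tr, l in zip(ExclosureTreatment, logits)
        }
        hits = 0
        runs = 200
        for run in range(runs):
            cfg = SimulationConfig(
                seed=5000 + run,
                exclosure=ExclosureDesign(p_other_nematode=p_nem),
            )
            dev, _ = accessibility_analysis(simulate_exclosure(cfg),
                                            target="any_nematode")
            hits += dev.p_value < 0.05
        assert hits / runs >= 0.80
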