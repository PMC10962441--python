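"""Statistical battery: parameter recovery, brute-force oracles, contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvsalps.cohort import CohortSpec, generate_cohort
from pvsalps.stats import (
    ModelSpec,
    best_cutpoint,
    fdr_adjust,
    fit_cox,
    fit_linear,
    fit_lmm,
    fit_logistic,
    km_logrank,
    variable_importance,
)


class TestLinear:
    def test_perfect_correlation_standardized_beta_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"y": 2 * x, "x": x})
        res = fit_linear(df, ModelSpec(outcome="y", predictor="x"))
        assert res.estimate == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-12

    def test_null_beta_bounded(self):
        rng = np.random.default_rng(1)
        n = 1000
        df = pd.DataFrame(
            {"y": rng.standard_normal(n), "x": rng.standard_normal(n)}
        )
        res = fit_linear(df, ModelSpec(outcome="y", predictor="x"))
        assert abs(res.estimate) < 3 / np.sqrt(n)

    def test_planted_partial_coefficient_recovered(self):
        rng = np.random.default_rng(2)
        n = 1000
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        beta = 0.30
        y = beta * x + 0.4 * z + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        res = fit_linear(
            df,
            ModelSpec(outcome="y", predictor="x", covariates=("z",),
                      standardize=False),
        )
        se = (res.ci_high - res.ci_low) / 3.92
        assert abs(res.estimate - beta) < 2 * se

    def test_rank_deficient_names_collinear_column(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        df = pd.DataFrame({"y": rng.standard_normal(40), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            fit_linear(
                df,
                ModelSpec(outcome="y", predictor="x", covariates=("x2",),
                          standardize=False),
            )

    def test_too_few_cases(self):
        df = pd.DataFrame({"y": np.arange(5.0), "x": np.arange(5.0) ** 2})
        with pytest.raises(ValueError, match="complete cases"):
            fit_linear(df, ModelSpec(outcome="y", predictor="x"))


class TestLmm:
    def test_recovery_within_two_se(self, cohort_200):
        table, truth = cohort_200
        res, slopes = fit_lmm(
            table.dropna(subset=["alps"]),
            ModelSpec(outcome="alps", covariates=(), family="lmm",
                      standardize=False),
        )
        se = (res.ci_high - res.ci_low) / 3.92
        assert abs(res.estimate - truth["alps_slope"]) < 2 * se
        assert len(slopes.table) == 200
        assert slopes.method == "blup"

    def test_noiseless_exact(self):
        table, _ = generate_cohort(
            CohortSpec(n=40, seed=12, alps_slope_sd=0.0, alps_resid_sd=0.0)
        )
        res, slopes = fit_lmm(
            table.dropna(subset=["alps"]),
            ModelSpec(outcome="alps", covariates=(), family="lmm",
                      standardize=False),
        )
        assert res.estimate == pytest.approx(-0.010, abs=1e-5)
        assert res.diagnostics["random_slope_var"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(slopes.table["slope"], -0.010, atol=1e-5)

    def test_predictor_time_interaction_recovered(self, cohort_200):
        table, truth = cohort_200
        base = table[table.visit_year == 0].set_index("subject_id")["alps"]
        longit = table.dropna(subset=["cog_exec"]).copy()
        longit["alps0"] = longit["subject_id"].map(base)
        res, _ = fit_lmm(
            longit,
            ModelSpec(outcome="cog_exec", predictor="alps0", covariates=(),
                      family="lmm", standardize=False),
        )
        # generator links slope to standardized baseline ALPS; convert the
        # per-unit interaction back to per-SD of the true baseline scale
        per_sd = res.estimate * truth["alps0_sd"]
        se = (res.ci_high - res.ci_low) / 3.92 * truth["alps0_sd"]
        assert abs(per_sd - truth["cog_slope_per_sd_alps"]["exec"]) < 2 * se

    def test_single_visit_errors(self):
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0],
                "visit_year": [0.0, 0.0, 0.0],
                "subject_id": ["a", "b", "c"],
            }
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_lmm(df, ModelSpec(outcome="y", covariates=(), family="lmm"))


class TestLogistic:
    def _simulate(self, log_or, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-0.5 + log_or * x)))
        return pd.DataFrame({"y": rng.binomial(1, p), "x": x})

    def test_null_log_or_bounded(self):
        df = self._simulate(0.0, 2000, 4)
        res = fit_logistic(df, ModelSpec(outcome="y", predictor="x",
                                         family="logistic", standardize=False))
        log_or = res.diagnostics["log_or"]
        se = (np.log(res.ci_high) - np.log(res.ci_low)) / 3.92
        assert abs(log_or) < 3 * se

    def test_planted_log_or_recovered(self):
        df = self._simulate(1.0, 2000, 5)
        res = fit_logistic(df, ModelSpec(outcome="y", predictor="x",
                                         family="logistic", standardize=False))
        se = (np.log(res.ci_high) - np.log(res.ci_low)) / 3.92
        assert abs(res.diagnostics["log_or"] - 1.0) < 2 * se

    def test_single_class_outcome_errors(self):
        df = pd.DataFrame({"y": np.zeros(50), "x": np.arange(50.0)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, ModelSpec(outcome="y", predictor="x",
                                       family="logistic"))

    def test_complete_separation_reported_not_estimated(self):
        x = np.linspace(-2, 2, 60)
        df = pd.DataFrame({"y": (x > 0).astype(int), "x": x})
        res = fit_logistic(df, ModelSpec(outcome="y", predictor="x",
                                         family="logistic", standardize=False))
        assert not res.converged
        assert np.isnan(res.estimate)


class TestCox:
    def test_null_log_hr_ci_covers_one(self):
        table, _ = generate_cohort(CohortSpec(n=500, seed=13, log_hr_alps=0.0))
        base = table[table.visit_year == 0]
        res = fit_cox(base, ModelSpec(outcome="dementia_event",
                                      predictor="alps", covariates=(),
                                      family="cox"))
        assert res.ci_low < 1.0 < res.ci_high

    def test_planted_hr_recovered(self, cohort_200):
        table, truth = cohort_200
        base = table[table.visit_year == 0]
        res = fit_cox(base, ModelSpec(outcome="dementia_event",
                                      predictor="alps", covariates=(),
                                      family="cox"))
        log_hr = res.diagnostics["log_hr"]
        se = (np.log(res.ci_high) - np.log(res.ci_low)) / 3.92
        assert abs(log_hr - truth["log_hr_alps"]) < 2 * se

    def test_zero_events_errors(self):
        df = pd.DataFrame(
            {
                "dementia_time": np.linspace(1, 5, 30),
                "dementia_event": np.zeros(30, dtype=int),
                "alps": np.random.default_rng(0).standard_normal(30),
            }
        )
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, ModelSpec(outcome="dementia_event", predictor="alps",
                                  covariates=(), family="cox"))


def _bh_oracle(pvals):
    """Brute-force BH: step-up over sorted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFdr:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(fdr_adjust([0.25]), [0.25])
        np.testing.assert_allclose(fdr_adjust([0.5, 1.0]), [1.0, 1.0])

    def test_exhaustive_subsets_match_oracle(self):
        pool = [0.001, 0.01, 0.02, 0.04, 0.049, 0.2, 0.5, 0.94]
        for r in range(1, len(pool) + 1):
            for subset in itertools.combinations(pool, r):
                np.testing.assert_allclose(
                    fdr_adjust(subset), _bh_oracle(subset), atol=1e-12
                )

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_property_matches_oracle_and_is_monotone(self, pvals):
        adj = fdr_adjust(pvals)
        np.testing.assert_allclose(adj, _bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


def _cutpoint_oracle(scores, events, direction):
    """Independent enumeration via confusion-matrix recount."""
    uniq = np.unique(scores)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2.0:
        flagged = scores <= c if direction == "<=" else scores >= c
        sens = np.mean(flagged[events == 1])
        spec = np.mean(~flagged[events == 0])
        j = sens + spec - 1
        bal = abs(flagged.sum() - (~flagged).sum())
        key = (-j, bal, c)
        if best is None or key < best:
            best = key
    return best[2], -best[0]


class TestCutpoint:
    def test_worked_example(self):
        res = best_cutpoint([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.direction == "<="
        assert res.cutpoint == pytest.approx(2.5)
        assert res.youden == pytest.approx(1.0)

    def test_null_scores_no_crash(self):
        rng = np.random.default_rng(6)
        res = best_cutpoint(rng.standard_normal(300), rng.binomial(1, 0.3, 300))
        assert -1.0 <= res.youden <= 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=1000)
        events = rng.binomial(1, 1 / (1 + np.exp(2 * scores)))
        res = best_cutpoint(scores, events)
        c, j = _cutpoint_oracle(scores, events, res.direction)
        assert res.cutpoint == pytest.approx(c)
        assert res.youden == pytest.approx(j)

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="constant"):
            best_cutpoint([1.0, 1.0, 1.0], [0, 1, 0])

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="class"):
            best_cutpoint([1.0, 2.0], [1, 1])


class TestKmLogrank:
    def test_identical_groups_null(self):
        dur = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        ev = np.array([1, 0, 1, 1, 0, 1])
        g = np.array(["a"] * 3 + ["b"] * 3)
        out = km_logrank(dur, ev, g)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_no_events_flat_curves(self):
        dur = np.array([1.0, 2.0, 3.0, 4.0])
        ev = np.zeros(4, dtype=int)
        g = np.array(["a", "a", "b", "b"])
        out = km_logrank(dur, ev, g)
        for curve in out["curves"].values():
            assert np.allclose(curve.to_numpy(), 1.0)
        assert out["p"] == 1.0

    def test_hand_worked_six_subjects(self):
        # A: (1,+), (2,+), (3,-); B: (1,-), (2,+), (4,+)
        # t=1: N=6, d=1, O_A=1, E_A=0.5, V=3*3*1*5/(36*5)=0.25
        # t=2: N=4, d=2, O_A=1, E_A=1.0, V=2*2*2*2/(16*3)=1/3
        # t=4: N=1 (B only), V=0 -> chi2 = 0.5^2/(7/12) = 3/7
        dur = np.array([1, 2, 3, 1, 2, 4], dtype=float)
        ev = np.array([1, 1, 0, 0, 1, 1])
        g = np.array(["A"] * 3 + ["B"] * 3)
        out = km_logrank(dur, ev, g)
        assert out["statistic"] == pytest.approx(3 / 7, abs=1e-12)
        assert out["p"] == pytest.approx(0.5126907602619235, abs=1e-12)
        km_a = out["curves"]["A"].iloc[:, 0]
        assert km_a.loc[1.0] == pytest.approx(2 / 3)
        assert km_a.loc[2.0] == pytest.approx(1 / 3)
        assert km_a.loc[3.0] == pytest.approx(1 / 3)  # censoring: no step
        km_b = out["curves"]["B"].iloc[:, 0]
        assert km_b.loc[1.0] == pytest.approx(1.0)
        assert km_b.loc[2.0] == pytest.approx(1 / 2)
        assert km_b.loc[4.0] == pytest.approx(0.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            km_logrank([1.0, 2.0], [1, 0], ["a", "a"])


class TestImportance:
    def _panel(self, n, seed, duplicate=False):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 5))
        y = X[:, 0] + 0.3 * rng.standard_normal(n)
        cols = {f"p{i}": X[:, i] for i in range(5)}
        if duplicate:
            cols["p0_copy"] = X[:, 0]
        cols["y"] = y
        return pd.DataFrame(cols)

    def test_informative_predictor_ranked_first(self):
        df = self._panel(500, 8)
        imp = variable_importance(df, "y", tuple(f"p{i}" for i in range(5)),
                                  seed=8, n_estimators=100, n_repeats=3)
        assert imp["predictor"].iloc[0] == "p0"
        assert imp["importance"].iloc[0] > 5 * imp["importance"].iloc[1]

    def test_pure_noise_importances_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((400, 5)),
                          columns=[f"p{i}" for i in range(4)] + ["y"])
        imp = variable_importance(df, "y", tuple(f"p{i}" for i in range(4)),
                                  seed=9, n_estimators=100, n_repeats=5)
        # no predictor explains held-in variance beyond overfit wiggle
        informative = self._panel(400, 9)
        ref = variable_importance(informative, "y",
                                  tuple(f"p{i}" for i in range(5)),
                                  seed=9, n_estimators=100, n_repeats=5)
        assert imp["importance"].max() < 0.1 * ref["importance"].max()

    def test_duplicated_predictor_shares_importance(self):
        df = self._panel(500, 10, duplicate=True)
        solo = variable_importance(df, "y", tuple(f"p{i}" for i in range(5)),
                                   seed=10, n_estimators=100, n_repeats=3)
        dup = variable_importance(
            df, "y", ("p0", "p0_copy", "p1", "p2", "p3", "p4"),
            seed=10, n_estimators=100, n_repeats=3,
        )
        solo_top = solo.set_index("predictor")["importance"]["p0"]
        shared = dup.set_index("predictor")["importance"][["p0", "p0_copy"]]
        # each copy individually matters less, but the signal is detected
        assert shared.max() < solo_top
        assert shared.sum() > 0.25 * solo_top
        assert set(dup["predictor"].iloc[:2]) <= {"p0", "p0_copy", "p1", "p2",
                                                  "p3", "p4"}

    def test_seeded_determinism(self):
        df = self._panel(200, 11)
        a = variable_importance(df, "y", tuple(f"p{i}" for i in range(5)),
                                seed=11, n_estimators=50, n_repeats=3)
        b = variable_importance(df, "y", tuple(f"p{i}" for i in range(5)),
                                seed=11, n_estimators=50, n_repeats=3)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_outcome_errors(self):
        df = self._panel(50, 12)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            variable_importance(df, "y", ("p0", "p1"), seed=0)
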