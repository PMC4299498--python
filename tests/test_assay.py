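"""Measurement processing and inference: normalisation, regression, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from rnapalloc import (
    AllocatorSystem,
    CoreSpec,
    InductionModel,
    MeasurementTable,
    PromoterSpec,
    SigmaSpec,
    compensate_alpha_expression,
    core_ratio_regression,
    fit_relative_expression,
    fold_induction,
    fraction_core_utilized,
    orthogonality_matrix,
    promoter_activity,
    saturated_shares,
    sum_constancy,
)
from rnapalloc.errors import (
    DegenerateFitError,
    InfeasibleTargetError,
    InsufficientDataError,
    UndefinedFoldError,
    ValidationError,
)


def make_table(records, white=40.0, reporter_only=None):
    df = pd.DataFrame(
        records, columns=["condition", "iptg_uM", "promoter", "replicate", "fluorescence_au"]
    )
    return MeasurementTable(
        data=df, white_cell={"default": white}, reporter_only=reporter_only or {}
    )


class TestPromoterActivity:
    def test_geometric_mean_minus_white(self):
        table = make_table(
            [("c", 0.0, "p", r, 100.0) for r in (1, 2, 3)], white=40.0
        )
        acts = promoter_activity(table)
        assert acts.loc[0, "activity_au"] == pytest.approx(60.0)

    def test_geometric_not_arithmetic_mean(self):
        table = make_table([("c", 0.0, "p", 1, 10.0), ("c", 0.0, "p", 2, 1000.0)], white=0.0)
        assert promoter_activity(table).loc[0, "activity_au"] == pytest.approx(100.0)

    def test_negative_activities_are_retained(self):
        reps = (50.0, 80.0, 120.0)
        table = make_table([("c", 0.0, "p", i, v) for i, v in enumerate(reps)], white=70.0)
        expect = gmean(reps) - 70.0
        got = promoter_activity(table).loc[0, "activity_au"]
        assert got == pytest.approx(expect)
        assert got < 10.0  # ~78.3 - 70, may be small or negative

    def test_missing_white_cell_value_is_an_error(self):
        df = pd.DataFrame(
            [("c", 0.0, "p", 1, 10.0, "b2")],
            columns=["condition", "iptg_uM", "promoter", "replicate", "fluorescence_au", "batch"],
        )
        with pytest.raises(ValidationError, match="white-cell"):
            MeasurementTable(data=df, white_cell={"b1": 40.0})

    def test_missing_column_is_named(self):
        df = pd.DataFrame({"condition": ["c"], "fluorescence_au": [1.0]})
        with pytest.raises(ValidationError, match="iptg_uM"):
            MeasurementTable(data=df, white_cell={"default": 0.0})


class TestFoldInduction:
    def test_anchored_ratio(self):
        assert fold_induction(400_000.0, 100.0) == pytest.approx(4000.0)

    def test_equal_activities_give_one(self):
        assert fold_induction(123.0, 123.0) == 1.0

    def test_nonpositive_reporter_only_rejected(self):
        with pytest.raises(UndefinedFoldError):
            fold_induction(10.0, 0.0)

    def test_invariant_to_shared_white_offset(self):
        # applying the same background to both raw values before
        # correction leaves the fold unchanged
        white = 55.0
        raw_test, raw_ref = 4000.0 + white, 40.0 + white
        assert fold_induction(raw_test - white, raw_ref - white) == pytest.approx(100.0)


class TestFractionCoreUtilized:
    def test_reference_equals_one_zero_stays_zero(self):
        acts = pd.DataFrame(
            {"condition": ["c"] * 2, "iptg_uM": [0.0, 1.0], "promoter": ["p", "p"],
             "activity_au": [100.0, 0.0]}
        )
        frac = fraction_core_utilized(acts, {"p": 100.0})
        assert list(frac["fraction"]) == [1.0, 0.0]

    def test_missing_reference_is_an_error(self):
        acts = pd.DataFrame(
            {"condition": ["c"], "iptg_uM": [0.0], "promoter": ["p"], "activity_au": [1.0]}
        )
        with pytest.raises(ValidationError, match="saturation"):
            fraction_core_utilized(acts, {"other": 1.0})

    def test_noiseless_saturated_model_recovers_shares(self):
        # forward model at deep saturation: fractions == saturated shares
        totals = {"a": 0.3, "b": 0.7}
        shares = saturated_shares(totals)
        sat = {"pa": 2.0 * 1.0, "pb": 3.0 * 1.0}  # efficiency * core
        acts = pd.DataFrame(
            {
                "condition": ["c"] * 2,
                "iptg_uM": [0.0] * 2,
                "promoter": ["pa", "pb"],
                "activity_au": [2.0 * shares["a"], 3.0 * shares["b"]],
            }
        )
        frac = fraction_core_utilized(acts, sat)
        got = dict(zip(frac["promoter"], frac["fraction"]))
        assert got["pa"] == pytest.approx(0.3)
        assert got["pb"] == pytest.approx(0.7)
        assert sum(got.values()) == pytest.approx(1.0)


class TestSumConstancy:
    def test_conserved_budget_has_zero_cv(self):
        rows = []
        for iptg, share in [(0.0, 0.1), (1.0, 0.5), (2.0, 0.9)]:
            rows.append(("c", iptg, "pa", share))
            rows.append(("c", iptg, "pb", 1.0 - share))
        acts = pd.DataFrame(rows, columns=["condition", "iptg_uM", "promoter", "activity_au"])
        mean, cv = sum_constancy(acts)
        assert mean == pytest.approx(1.0)
        assert cv == pytest.approx(0.0, abs=1e-15)

    def test_single_promoter_constant_activity(self):
        acts = pd.DataFrame(
            {"condition": ["c"] * 3, "iptg_uM": [0.0, 1.0, 2.0], "promoter": ["p"] * 3,
             "activity_au": [5.0, 5.0, 5.0]}
        )
        assert sum_constancy(acts) == (5.0, 0.0)

    def test_cv_tracks_replicate_noise(self, rng):
        # lognormal noise with cv sigma on geometric means of triplicates:
        # the cv of sums is close to sigma/sqrt(3), here checked against a
        # direct resampling estimate
        cv_true = 0.1
        n_pts, n_rep = 200, 3
        sigma2 = np.log1p(cv_true**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=(n_pts, 2, n_rep))
        gm = gmean(noise, axis=2)  # per-point per-promoter geometric means
        sums = gm.sum(axis=1) * 50.0  # two promoters at activity 50 each
        acts = pd.DataFrame(
            {
                "condition": "c",
                "iptg_uM": np.repeat(np.arange(n_pts), 2),
                "promoter": ["pa", "pb"] * n_pts,
                "activity_au": (gm * 50.0).ravel(),
            }
        )
        _, cv = sum_constancy(acts)
        resample = np.std(sums, ddof=1) / np.mean(sums)
        assert cv == pytest.approx(resample, rel=1e-9)
        assert cv == pytest.approx(cv_true / np.sqrt(3) / np.sqrt(2), rel=0.25)


class TestCoreRatioRegression:
    def test_exact_ratio_recovered(self):
        high = np.array([10.0, 50.0, 200.0, 1000.0])
        res = core_ratio_regression(0.36 * high, high, n_boot=50, seed=0)
        assert res.parameters["slope"] == pytest.approx(0.36, rel=1e-12)

    def test_identity_when_equal(self):
        high = np.array([1.0, 2.0, 3.0])
        assert core_ratio_regression(high, high, n_boot=10, seed=0).parameters[
            "slope"
        ] == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        high = rng.uniform(1, 100, 20)
        low = 0.4 * high * rng.lognormal(0, 0.05, 20)
        s0 = core_ratio_regression(low, high, n_boot=10, seed=1).parameters["slope"]
        s_both = core_ratio_regression(3.7 * low, 3.7 * high, n_boot=10, seed=1).parameters["slope"]
        s_low = core_ratio_regression(3.7 * low, high, n_boot=10, seed=1).parameters["slope"]
        assert s_both == pytest.approx(s0, rel=1e-12)
        assert s_low == pytest.approx(3.7 * s0, rel=1e-12)

    def test_noisy_recovery_with_ci(self, rng):
        # both allocator levels measured as triplicate geometric means with
        # 10% lognormal replicate noise; the true ratio should sit inside
        # the bootstrap CI in >= 90% of runs
        covered = 0
        n_runs = 20
        s2 = np.log1p(0.01)
        for _ in range(n_runs):
            base = rng.uniform(10, 100, 24)
            high = gmean(base[:, None] * rng.lognormal(-s2 / 2, np.sqrt(s2), (24, 3)), axis=1)
            low = gmean(
                0.36 * base[:, None] * rng.lognormal(-s2 / 2, np.sqrt(s2), (24, 3)), axis=1
            )
            res = core_ratio_regression(low, high, n_boot=999, seed=int(rng.integers(2**31)))
            lo, hi = res.bootstrap_ci["slope"]
            covered += lo <= 0.36 <= hi
            assert res.parameters["slope"] == pytest.approx(0.36, rel=0.1)
        assert covered >= 0.9 * n_runs

    def test_all_zero_reference_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            core_ratio_regression(np.array([1.0, 2.0]), np.array([0.0, 0.0]))


class TestFitRelativeExpression:
    x = np.array([0.05, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0])

    @pytest.mark.parametrize("s", [0.2, 1.0, 5.0])
    def test_noiseless_recovery(self, s):
        fi, fc = self.x / (self.x + s), s / (self.x + s)
        res = fit_relative_expression(self.x, fi, fc, n_boot=0)
        assert res.parameters["s"] == pytest.approx(s, rel=1e-6)
        assert res.residual_norm < 1e-8

    def test_noisy_recovery_median_error(self, rng):
        s = 5.0
        errs = []
        for _ in range(20):
            reps = np.repeat(self.x, 3)
            noise = lambda: rng.lognormal(-0.5 * np.log1p(0.01), np.sqrt(np.log1p(0.01)), len(reps))
            fi = reps / (reps + s) * noise()
            fc = s / (reps + s) * noise()
            res = fit_relative_expression(reps, fi, fc, n_boot=0)
            errs.append(abs(res.parameters["s"] - s) / s)
        assert np.median(errs) <= 0.10

    def test_bias_shrinks_with_replicates(self, rng):
        s = 1.0
        biases = {}
        for n_rep in (3, 10, 30):
            est = []
            for _ in range(30):
                reps = np.repeat(self.x, n_rep)
                noise = lambda: rng.lognormal(
                    -0.5 * np.log1p(0.01), np.sqrt(np.log1p(0.01)), len(reps)
                )
                fi = reps / (reps + s) * noise()
                fc = s / (reps + s) * noise()
                est.append(fit_relative_expression(reps, fi, fc, n_boot=0).parameters["s"])
            biases[n_rep] = abs(np.mean(est) - s)
        assert biases[30] < biases[3] + 0.01
        assert biases[30] < 0.02

    def test_ci_contains_estimate(self):
        s = 1.0
        fi, fc = self.x / (self.x + s), s / (self.x + s)
        res = fit_relative_expression(self.x, fi, fc, n_boot=100, seed=3)
        lo, hi = res.bootstrap_ci["s"]
        assert lo <= res.parameters["s"] <= hi

    def test_too_few_points_rejected(self):
        x = np.array([1.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_relative_expression(x, x / (x + 1), 1 / (x + 1))


class TestOrthogonalityMatrix:
    def _long(self, mat):
        rows = []
        for s, row in mat.items():
            for p, v in row.items():
                rows.append({"sigma": s, "promoter": p, "activity_au": v})
        return pd.DataFrame(rows)

    def test_diagonal_dominates_for_orthogonal_system(self):
        df = self._long(
            {"a": {"pa": 100.0, "pb": 0.5}, "b": {"pa": 0.4, "pb": 80.0}}
        )
        mat = orthogonality_matrix(df)
        assert mat.loc["a", "pa"] > 100 * mat.loc["a", "pb"]

    def test_normalized_off_diagonal_reads_crosstalk(self):
        df = self._long({"a": {"pa": 100.0, "pb": 16.0}, "b": {"pa": 1.0, "pb": 80.0}})
        mat = orthogonality_matrix(df, normalize=True, cognate={"pa": "a", "pb": "b"})
        assert mat.loc["a", "pa"] == 1.0
        assert mat.loc["a", "pb"] == pytest.approx(0.2)

    def test_missing_cell_is_an_error(self):
        df = self._long({"a": {"pa": 1.0}, "b": {"pa": 1.0, "pb": 1.0}})
        with pytest.raises(ValidationError, match="missing"):
            orthogonality_matrix(df)


class TestCompensateAlpha:
    def _beta_system(self):
        return AllocatorSystem(
            CoreSpec(1.0, requires_alpha=True, kd_alpha=0.01, alpha_total=0.0),
            (SigmaSpec("T7", 5.0, 0.01, efficiency=2.0),),
            (PromoterSpec("PT7", "T7"),),
        )

    def test_equal_copy_numbers_equal_strengths(self):
        res = compensate_alpha_expression({"p1": 5.0, "p2": 5.0}, 0.5, self._beta_system())
        assert res["p1"] == pytest.approx(res["p2"], rel=1e-9)

    def test_strengths_inverse_to_copy_number(self):
        res = compensate_alpha_expression({"low": 1.0, "high": 10.0}, 0.4, self._beta_system())
        assert res["low"] / res["high"] == pytest.approx(10.0, rel=1e-6)

    def test_target_above_ceiling_is_infeasible(self):
        # beta core ceiling: all core active -> activity 2.0
        with pytest.raises(InfeasibleTargetError, match="ceiling"):
            compensate_alpha_expression({"p1": 1.0}, 5.0, self._beta_system())

    def test_full_core_cannot_be_compensated(self):
        system = AllocatorSystem(
            CoreSpec(1.0),
            (SigmaSpec("T7", 5.0, 0.01, efficiency=2.0),),
            (PromoterSpec("PT7", "T7"),),
        )
        with pytest.raises(InfeasibleTargetError, match="copy number"):
            compensate_alpha_expression({"p1": 1.0, "p2": 10.0}, 0.5, system)


class TestInductionModel:
    def test_basal_at_zero_and_plateau(self):
        m = InductionModel(basal=0.1, vmax=5.0, k_half=10.0, hill_n=2.0)
        assert m.expression(0.0) == pytest.approx(0.1)
        assert m.expression(1e6) == pytest.approx(5.0, rel=1e-6)
        assert m.expression(10.0) == pytest.approx(0.1 + (5.0 - 0.1) / 2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            InductionModel(basal=2.0, vmax=1.0, k_half=1.0, hill_n=1.0)
        with pytest.raises(ValidationError):
            InductionModel(basal=0.0, vmax=1.0, k_half=0.0, hill_n=1.0)
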