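"""Adjusted hazards, log hazard ratios and cumulative incidence."""

import numpy as np
import pytest

from peann.curves import (
    AdjustedCurveSpec,
    adjusted_hazard,
    cumulative_hazard,
    cumulative_incidence,
    log_hazard_ratio,
)
from peann.netmodel import Ensemble, HazardNet
from peann.survdata import Covariate, build_interval_grid, encode_covariates

from conftest import make_cohort


def constant_net(c, p, grid, encoding):
    """Net with only the output bias set: hazard == c everywhere."""
    W2 = np.zeros(2)
    W2[0] = np.log(c)
    return HazardNet(1, np.zeros((p + 2, 1)), W2, 0.0, grid.horizon,
                     encoding=encoding, grid=grid)


def strata_net(coef_by_column, base, grid, encoding):
    """Log-hazard linear in selected dummy columns (steep-sigmoid trick).

    Uses one hidden unit per column with large first-layer weight so the
    sigmoid acts as a 0/1 switch on that dummy.
    """
    p = encoding.p
    H = len(coef_by_column)
    W1 = np.zeros((p + 2, H))
    W2 = np.zeros(H + 1)
    for k, (col, coef) in enumerate(coef_by_column.items()):
        j = encoding.columns.index(col)
        W1[0, k] = -200.0  # bias: sigmoid ~ 0 unless the dummy fires
        W1[1 + j, k] = 400.0
        W2[1 + k] = coef
    W2[0] = np.log(base)
    return HazardNet(H, W1, W2, 0.0, grid.horizon, encoding=encoding, grid=grid)


@pytest.fixture
def treated_cohort():
    treat = ["control"] * 20 + ["active"] * 20
    pn = (["pN0"] * 30 + ["pN2"] * 10)
    return make_cohort(
        np.linspace(5, 70, 40),
        [1] * 40,
        {"treatment": treat, "pN": pn},
        schema=(
            Covariate("treatment", "categorical", ("control", "active")),
            Covariate("pN", "categorical", ("pN0", "pN2")),
        ),
        treatment="treatment",
    )


class TestAdjustedHazard:
    def test_identical_subjects_recover_individual_curve(self):
        cohort = make_cohort(
            [10.0] * 5, [1] * 5, {"treatment": ["a"] * 5},
            schema=(Covariate("treatment", "categorical", ("a", "b")),),
            treatment="treatment",
        )
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(cohort)
        ens = Ensemble([constant_net(0.07, emap.p, grid, emap)])
        curve = adjusted_hazard(ens, cohort, AdjustedCurveSpec("a"))
        np.testing.assert_allclose(curve.estimate, 0.07)

    def test_null_effect_net_gives_identical_arm_curves(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        # hazard depends on pN only; treatment column has zero weight
        ens = Ensemble([strata_net({"pN=pN2": 0.5}, 0.05, grid, emap)])
        c_act = adjusted_hazard(ens, treated_cohort, AdjustedCurveSpec("active"))
        c_ctl = adjusted_hazard(ens, treated_cohort, AdjustedCurveSpec("control"))
        np.testing.assert_allclose(c_act.estimate, c_ctl.estimate)

    def test_weighted_mean_forced_arithmetic(self, treated_cohort):
        """Strata hazards 1 and 3 with 30/10 subjects -> adjusted hazard 1.5."""
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([strata_net({"pN=pN2": np.log(3.0)}, 1.0, grid, emap)])
        curve = adjusted_hazard(ens, treated_cohort, AdjustedCurveSpec("control"))
        np.testing.assert_allclose(curve.estimate, 1.5, rtol=1e-9)

    def test_adjusted_within_individual_range(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, X = encode_covariates(treated_cohort)
        ens = Ensemble([strata_net({"pN=pN2": 0.7, "treatment=active": -0.3},
                                   0.04, grid, emap)])
        curve = adjusted_hazard(ens, treated_cohort, AdjustedCurveSpec(None))
        from peann.fitting import predict_hazard

        for j, t in enumerate(curve.t_grid):
            indiv = predict_hazard(ens, X, t)
            assert indiv.min() - 1e-12 <= curve.estimate[j] <= indiv.max() + 1e-12

    def test_standardization_consistency_over_partition(self, treated_cohort):
        """Whole-cohort curve == size-weighted mean of pN-subgroup curves."""
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([strata_net({"pN=pN2": 0.7, "treatment=active": -0.3},
                                   0.04, grid, emap)])
        whole = adjusted_hazard(ens, treated_cohort, AdjustedCurveSpec("active"))
        parts, sizes = [], []
        for lvl in ("pN0", "pN2"):
            c = adjusted_hazard(
                ens, treated_cohort, AdjustedCurveSpec("active", {"pN": lvl})
            )
            parts.append(c.estimate)
            sizes.append((treated_cohort.data["pN"] == lvl).sum())
        combined = (sizes[0] * parts[0] + sizes[1] * parts[1]) / sum(sizes)
        np.testing.assert_allclose(whole.estimate, combined, rtol=1e-12)

    def test_empty_subgroup_rejected(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([constant_net(0.1, emap.p, grid, emap)])
        with pytest.raises(ValueError, match="empty"):
            adjusted_hazard(
                ens, treated_cohort, AdjustedCurveSpec("active", {"pN": "pN3"})
            )


class TestLogHazardRatio:
    def test_identical_specs_zero_curve(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([strata_net({"pN=pN2": 0.5}, 0.05, grid, emap)])
        curve = log_hazard_ratio(
            ens, treated_cohort, AdjustedCurveSpec("active"), AdjustedCurveSpec("active")
        )
        np.testing.assert_allclose(curve.estimate, 0.0, atol=1e-15)

    def test_null_effect_zero_curve(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([strata_net({"pN=pN2": 0.5}, 0.05, grid, emap)])
        curve = log_hazard_ratio(
            ens, treated_cohort, AdjustedCurveSpec("active"), AdjustedCurveSpec("control")
        )
        np.testing.assert_allclose(curve.estimate, 0.0, atol=1e-12)

    def test_hazard_ratio_two_forced(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble(
            [strata_net({"treatment=active": np.log(2.0)}, 1.0, grid, emap)]
        )
        curve = log_hazard_ratio(
            ens, treated_cohort, AdjustedCurveSpec("active"), AdjustedCurveSpec("control")
        )
        np.testing.assert_allclose(curve.estimate, np.log(2.0), rtol=1e-9)

    def test_mismatched_subgroups_rejected(self, treated_cohort):
        grid = build_interval_grid(9.0, 72.0)
        emap, _ = encode_covariates(treated_cohort)
        ens = Ensemble([constant_net(0.1, emap.p, grid, emap)])
        with pytest.raises(ValueError):
            log_hazard_ratio(
                ens,
                treated_cohort,
                AdjustedCurveSpec("active", {"pN": "pN0"}),
                AdjustedCurveSpec("control"),
            )


class TestCumulativeIncidence:
    def _const_ens(self, c):
        grid = build_interval_grid(3.0, 72.0)
        return Ensemble([constant_net(c, 0, grid, None)])

    def test_constant_hazard_closed_form(self):
        ens = self._const_ens(0.01)
        ci = cumulative_incidence(ens, np.zeros((1, 0)), 72.0)
        assert ci == pytest.approx(1 - np.exp(-0.72), rel=1e-12)

    def test_horizon_zero(self):
        ens = self._const_ens(0.01)
        assert cumulative_incidence(ens, np.zeros((1, 0)), 0.0) == 0.0

    def test_piecewise_rates_closed_form(self):
        grid = build_interval_grid(3.0, 72.0)

        class StepMember:
            H, lam, time_scale = 1, 0.0, 72.0
            encoding, grid_ = None, grid

            def predict_hazard(self, x, t):
                t = np.atleast_1d(np.asarray(t, float))
                return np.where(t <= 36.0, 0.02, 0.005)

        member = StepMember()
        ens = Ensemble([member])
        ens.members[0].grid = grid
        ci = cumulative_incidence(ens, np.zeros((1, 0)), 72.0)
        assert ci == pytest.approx(1 - np.exp(-(0.72 + 0.18)), rel=1e-12)

    def test_monotone_in_horizon_and_inflation(self):
        ens_lo = self._const_ens(0.01)
        ens_hi = self._const_ens(0.02)
        x = np.zeros((1, 0))
        vals = [cumulative_incidence(ens_lo, x, h) for h in (0, 12, 36, 60, 72)]
        assert np.all(np.diff(vals) > 0)
        assert cumulative_incidence(ens_hi, x, 72.0) > vals[-1]

    def test_horizon_beyond_grid_rejected(self):
        ens = self._const_ens(0.01)
        with pytest.raises(ValueError):
            cumulative_incidence(ens, np.zeros((1, 0)), 80.0)
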