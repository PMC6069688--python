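"""Nonparametric bootstrap confidence bands with bias-corrected percentiles.

Subjects are resampled with replacement (the resampling unit is the subject,
before person-period expansion, so within-subject rows stay together).  For
each bootstrap sample, one net is refitted per member of the base ensemble,
warm-started at that member's final coefficients; the replicate statistic is
the ensemble-averaged curve on the resampled data.  Pointwise bounds come
from the bias-corrected (BC) percentile method:

    z0 = Phi^{-1}( #{replicates < point estimate} / B ),
    lower/upper at empirical quantiles Phi(2 z0 + z_{a/2}), Phi(2 z0 + z_{1-a/2}).

BC (not BCa): no acceleration term, hence no jackknife.  Empirical quantiles
use the nearest-rank (type 1) definition for exact cross-platform
reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .curves import Curve
from .fitting import FitConfig, fit_single
from .netmodel import Ensemble
from .survdata import IntervalGrid, SurvivalCohort, expand_person_period

__all__ = ["BootstrapConfig", "bootstrap_curves", "bc_percentile"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap controls: B replicates, level, warm starts, seed.

    ``max_iter`` caps the per-replicate refit length; warm-started refits
    need far fewer iterations than cold fits.
    """

    B: int = 2000
    alpha: float = 0.05
    warm_start: bool = True
    seed: int = 0
    max_iter: int = 200
    init_range: float = 0.5
    grad_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _quantile_type1(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank (type 1) empirical quantile of pre-sorted values."""
    n = sorted_vals.size
    k = int(np.ceil(q * n)) - 1
    return float(sorted_vals[min(max(k, 0), n - 1)])


def bc_percentile(
    replicates: np.ndarray, point_estimate: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected percentile interval from bootstrap replicates.

    The bias-correction constant z0 is the normal quantile of the fraction of
    replicates below the point estimate; that fraction is clamped to
    [1/(B+1), B/(B+1)] so z0 stays finite.  With z0 = 0 (median-unbiased
    replicates) the interval reduces to the plain percentile interval.
    """
    reps = np.asarray(replicates, float)
    if reps.size == 0 or not np.isfinite(reps).all():
        raise ValueError("replicates must be nonempty and finite")
    if np.all(reps == reps[0]):
        return float(reps[0]), float(reps[0])
    B = reps.size
    frac = np.count_nonzero(reps < point_estimate) / B
    frac = min(max(frac, 1.0 / (B + 1)), B / (B + 1))
    z0 = norm.ppf(frac)
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    q_lo = norm.cdf(2 * z0 + z_lo)
    q_hi = norm.cdf(2 * z0 + z_hi)
    s = np.sort(reps)
    lo, hi = _quantile_type1(s, q_lo), _quantile_type1(s, q_hi)
    return (lo, hi) if lo <= hi else (hi, lo)


def bootstrap_curves(
    cohort: SurvivalCohort,
    grid: IntervalGrid,
    base: Ensemble,
    statistic_fn: Callable[[Ensemble, SurvivalCohort], Curve],
    config: BootstrapConfig = BootstrapConfig(),
) -> Curve:
    """Pointwise confidence band for a curve statistic of a fitted ensemble.

    ``statistic_fn(ensemble, cohort)`` must return a :class:`~peann.curves.Curve`
    evaluated on a fixed time grid (e.g. an adjusted hazard or log-HR curve).
    The point estimate uses the base ensemble on the original cohort; each
    replicate refits the ensemble on a subject-level resample, warm-started
    from the base coefficients, and re-evaluates the statistic on the
    resampled cohort.  Replicates whose refit fails are retried once with a
    jittered start, then dropped (the count is recorded on the returned
    curve's ``n_dropped`` attribute).
    """
    point = statistic_fn(base, cohort)
    t_grid = np.asarray(point.t_grid, float)
    rng = np.random.default_rng(config.seed)
    fit_cfg = FitConfig(
        n_starts=1,
        init_range=config.init_range,
        max_iter=config.max_iter,
        grad_tol=config.grad_tol,
        seed=config.seed,
    )
    reps = np.empty((config.B, t_grid.size))
    n_dropped = 0
    kept = []
    for b in range(config.B):
        boot = cohort.resample(rng)
        pp = expand_person_period(boot, grid, encoding=base.encoding)
        members = []
        try:
            for m in base.members:
                if config.warm_start:
                    init = m.pack()
                else:
                    init = int(rng.integers(0, 2**31))
                try:
                    members.append(fit_single(pp, base.H, base.lam, init, fit_cfg))
                except RuntimeError:
                    jitter = m.pack() + rng.normal(0, 0.01, m.n_coef)
                    members.append(fit_single(pp, base.H, base.lam, jitter, fit_cfg))
            rep_curve = statistic_fn(Ensemble(members), boot)
        except (RuntimeError, ValueError):
            # e.g. the resample missed the subgroup entirely
            n_dropped += 1
            continue
        reps[len(kept)] = rep_curve.estimate
        kept.append(b)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} of {config.B} bootstrap replicates")
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 usable bootstrap replicates")
    reps = reps[: len(kept)]
    lower = np.empty(t_grid.size)
    upper = np.empty(t_grid.size)
    for j in range(t_grid.size):
        lower[j], upper[j] = bc_percentile(
            reps[:, j], float(point.estimate[j]), config.alpha
        )
    out = Curve(point.label, t_grid, point.estimate, lower, upper)
    out.n_dropped = n_dropped  # type: ignore[attr-defined]
    return out
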