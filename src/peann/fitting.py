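"""Optimization driver: multi-start BFGS and ensemble-averaged prediction.

The penalized objective is non-convex, so a single fit lands in an arbitrary
local optimum.  The estimation strategy is therefore: draw several random
initializations, minimize each with quasi-Newton BFGS using the analytic
gradient, keep *all* fits, and predict with the arithmetic mean of the member
hazard functions.  No member selection or trimming is applied — averaging over
all restarts is part of the estimator, not a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .netmodel import Ensemble, HazardNet, objective_and_gradient, unpack
from .survdata import PersonPeriodTable

__all__ = ["FitConfig", "fit_single", "fit_ensemble", "predict_hazard"]


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the multi-start optimizer.

    n_starts : number of random initializations kept in the ensemble.
    init_range : coefficients start uniform on (-init_range, init_range).
    max_iter : BFGS iteration cap; hitting it is a recorded warning, not an
        error (standard penalized-likelihood practice).
    grad_tol : gradient infinity-norm convergence tolerance.
    seed : base seed; per-member seeds are derived deterministically.
    """

    n_starts: int = 10
    init_range: float = 0.5
    max_iter: int = 2000
    grad_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.init_range <= 0 or self.max_iter < 1:
            raise ValueError("n_starts, init_range, max_iter must be positive")
        if self.grad_tol <= 0:
            raise ValueError("grad_tol must be positive")


def member_seeds(config: FitConfig) -> np.ndarray:
    """Deterministic per-member seeds derived from the base seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_starts) % (2**31)


def fit_single(
    pp: PersonPeriodTable,
    H: int,
    lam: float,
    init: np.ndarray | int,
    config: FitConfig = FitConfig(),
) -> HazardNet:
    """One BFGS minimization of the penalized objective.

    ``init`` is either an explicit packed coefficient vector (warm start) or
    an integer seed from which a uniform initialization is drawn.  Returns the
    fitted network with diagnostics (final objective, convergence flag,
    iteration count, seed if any) attached.
    """
    if pp.n_rows == 0:
        raise ValueError("person-period table is empty")
    if H < 1 or lam < 0:
        raise ValueError("H must be >= 1 and lambda >= 0")
    p = pp.p
    n_par = (p + 2) * H + H + 1
    seed = None
    if np.isscalar(init):
        seed = int(init)
        rng = np.random.default_rng(seed)
        theta0 = rng.uniform(-config.init_range, config.init_range, n_par)
        # objective is finite for any finite start here (exp is guarded), but
        # keep the re-draw contract for robustness
        for _ in range(5):
            f0, _ = objective_and_gradient(theta0, pp, p, H, lam)
            if np.isfinite(f0):
                break
            theta0 = rng.uniform(-config.init_range, config.init_range, n_par)
        else:
            raise RuntimeError(f"non-finite objective at start (seed {seed})")
    else:
        theta0 = np.asarray(init, float)
        if theta0.size != n_par:
            raise ValueError("warm-start vector has wrong length")
        f0, _ = objective_and_gradient(theta0, pp, p, H, lam)
        if not np.isfinite(f0):
            raise RuntimeError("non-finite objective at warm start")

    res = minimize(
        objective_and_gradient,
        theta0,
        args=(pp, p, H, lam),
        method="BFGS",
        jac=True,
        options={"gtol": config.grad_tol, "maxiter": config.max_iter},
    )
    # BFGS can step into a worse point on pathological line searches; fall
    # back to the start rather than return a degraded fit.
    theta = res.x
    f_final = float(res.fun)
    f_start, _ = objective_and_gradient(theta0, pp, p, H, lam)
    if not np.isfinite(f_final) or f_final > f_start:
        theta, f_final = theta0, float(f_start)
    W1, W2 = unpack(theta, p, H)
    net = HazardNet(
        H,
        W1,
        W2,
        lam,
        time_scale=pp.grid.horizon,
        encoding=pp.encoding,
        grid=pp.grid,
    )
    net.diagnostics = {
        "objective": f_final,
        "converged": bool(res.success),
        "n_iter": int(res.nit),
        "seed": seed,
        "message": str(res.message),
    }
    return net


def fit_ensemble(
    pp: PersonPeriodTable, H: int, lam: float, config: FitConfig = FitConfig()
) -> Ensemble:
    """Fit ``config.n_starts`` nets from independent seeded initializations."""
    seeds = member_seeds(config)
    members, failures = [], []
    for s in seeds:
        try:
            members.append(fit_single(pp, H, lam, int(s), config))
        except RuntimeError:
            failures.append(int(s))
    if failures:
        raise RuntimeError(f"ensemble fit failed for seeds {failures}")
    return Ensemble(members)


def predict_hazard(
    ensemble: Ensemble, x_enc: np.ndarray, t_months
) -> np.ndarray | float:
    """Ensemble hazard: mean of member hazard functions at time in months.

    Times outside [0, horizon] are rejected — the model is not extrapolated
    beyond its grid.
    """
    t = np.asarray(t_months, float)
    horizon = ensemble.members[0].time_scale
    if np.any(t < 0) or np.any(t > horizon + 1e-9):
        raise ValueError(f"time outside [0, {horizon}] months")
    vals = np.stack(
        [np.asarray(m.predict_hazard(x_enc, t_months), float) for m in ensemble.members]
    )
    out = vals.mean(axis=0)
    return float(out) if out.ndim == 0 else out
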