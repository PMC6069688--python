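"""Seeded synthetic cohorts with known ground-truth hazards.

Simulated cohorts mirror the structure of an adjuvant-therapy trial with
categorical prognostic factors: a two-arm treatment, tumor grade (two
categories), pathologic T stage (three) and nodal involvement (three), with
independent censoring and administrative truncation at an analysis horizon.
The hazard is

    h(t | x) = baseline(t) * exp( sum of covariate effects
                                  + interaction terms, possibly time-dependent ),

where interaction terms may switch sign at a change point — the structure
needed to emulate a treatment that is harmful early and protective late, or
protective only in one nodal subgroup.

Event times are drawn by inverting the cumulative hazard: closed form where
the baseline admits one, segment-wise otherwise, bisection (tolerance 1e-9
months) for baselines without an analytic inverse.  Mass beyond the horizon
becomes administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .survdata import Covariate, SurvivalCohort

__all__ = [
    "ConstantBaseline",
    "WeibullBaseline",
    "PiecewiseBaseline",
    "MixtureBaseline",
    "Interaction",
    "HazardSpec",
    "true_hazard",
    "simulate_cohort",
    "scenario",
    "SCENARIOS",
    "default_covariate_dist",
]


# ---------------------------------------------------------------------------
# baselines: hazard, cumulative hazard, and (where available) its inverse


@dataclass(frozen=True)
class ConstantBaseline:
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def hazard(self, t):
        return np.full_like(np.asarray(t, float), self.rate)

    def cum(self, t):
        return self.rate * np.asarray(t, float)

    def inv_cum(self, x):
        return x / self.rate


@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull hazard (shape/scale) * (t/scale)^(shape-1); shape < 1 decreases."""

    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def hazard(self, t):
        t = np.asarray(t, float)
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)

    def cum(self, t):
        return (np.asarray(t, float) / self.scale) ** self.shape

    def inv_cum(self, x):
        return self.scale * np.asarray(x, float) ** (1.0 / self.shape)


@dataclass(frozen=True)
class PiecewiseBaseline:
    """Piecewise-constant hazard: rates[s] on (boundaries[s], boundaries[s+1]].

    ``boundaries`` starts at 0; the last rate extends beyond the last boundary.
    """

    boundaries: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        r = tuple(float(x) for x in self.rates)
        if b[0] != 0 or any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at 0 and increase")
        if len(r) != len(b) or any(x <= 0 for x in r):
            raise ValueError("need one positive rate per boundary segment")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "rates", r)

    def hazard(self, t):
        t = np.asarray(t, float)
        idx = np.searchsorted(self.boundaries, t, side="left") - 1
        return np.asarray(self.rates)[np.clip(idx, 0, len(self.rates) - 1)]

    def cum(self, t):
        t = np.atleast_1d(np.asarray(t, float))
        b = np.asarray(self.boundaries)
        r = np.asarray(self.rates)
        cum_at_b = np.concatenate([[0.0], np.cumsum(r[:-1] * np.diff(b))])
        idx = np.clip(np.searchsorted(b, t, side="left") - 1, 0, len(r) - 1)
        out = cum_at_b[idx] + r[idx] * (t - b[idx])
        return out if out.size > 1 else float(out[0])

    def inv_cum(self, x):
        b = np.asarray(self.boundaries)
        r = np.asarray(self.rates)
        cum_at_b = np.concatenate([[0.0], np.cumsum(r[:-1] * np.diff(b))])
        idx = np.clip(np.searchsorted(cum_at_b, x, side="right") - 1, 0, len(r) - 1)
        return b[idx] + (x - cum_at_b[idx]) / r[idx]


@dataclass(frozen=True)
class MixtureBaseline:
    """Additive mixture of component hazards — multi-peak shapes.

    The hazard (and cumulative hazard) is the weighted sum over components;
    inversion has no closed form and falls back to bisection.
    """

    components: tuple
    weights: tuple[float, ...]

    def hazard(self, t):
        return sum(w * c.hazard(t) for w, c in zip(self.weights, self.components))

    def cum(self, t):
        return sum(w * c.cum(t) for w, c in zip(self.weights, self.components))

    inv_cum = None


@dataclass(frozen=True)
class Interaction:
    """A multiplicative log-hazard term active for matching covariates.

    ``when`` maps covariate names to a level (or tuple of levels) that must
    all match.  With a ``changepoint`` the contribution is ``loghr`` up to and
    including the change point and ``loghr_after`` beyond it (sign-switching
    time-dependent effects); otherwise ``loghr`` applies at all times.
    """

    when: Mapping[str, object]
    loghr: float
    changepoint: float | None = None
    loghr_after: float | None = None

    def matches(self, covariates: Mapping) -> bool:
        for name, want in self.when.items():
            val = str(covariates[name])
            levels = (
                tuple(str(w) for w in want)
                if isinstance(want, (tuple, list, set, frozenset))
                else (str(want),)
            )
            if val not in levels:
                return False
        return True

    def loghr_at(self, t: float) -> float:
        if self.changepoint is None:
            return self.loghr
        return self.loghr if t <= self.changepoint else self.loghr_after


@dataclass(frozen=True)
class HazardSpec:
    """Ground-truth hazard: baseline x exp(effects + interactions).

    ``effects`` maps covariate name -> {level: log-HR} for categorical
    covariates (missing levels contribute 0) or a float coefficient for
    continuous ones.  ``horizon`` is the administrative truncation time in
    months; ``censor_max`` (if set) adds independent uniform(0, censor_max)
    censoring.
    """

    baseline: object
    effects: Mapping[str, object] = field(default_factory=dict)
    interactions: tuple[Interaction, ...] = ()
    horizon: float = 72.0
    censor_max: float | None = None

    def static_loghr(self, covariates: Mapping) -> float:
        total = 0.0
        for name, eff in self.effects.items():
            if isinstance(eff, Mapping):
                total += float(eff.get(str(covariates[name]), 0.0))
            else:
                total += float(eff) * float(covariates[name])
        for inter in self.interactions:
            if inter.changepoint is None and inter.matches(covariates):
                total += inter.loghr
        return total

    def changepoints(self, covariates: Mapping) -> list[float]:
        return sorted(
            {
                i.changepoint
                for i in self.interactions
                if i.changepoint is not None and i.matches(covariates)
            }
        )

    def timevar_loghr(self, covariates: Mapping, t: float) -> float:
        return sum(
            i.loghr_at(t)
            for i in self.interactions
            if i.changepoint is not None and i.matches(covariates)
        )


def true_hazard(spec: HazardSpec, covariates: Mapping, t) -> np.ndarray | float:
    """Ground-truth hazard at time(s) t in (0, horizon] for one subject."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    if np.any(t_arr <= 0) or np.any(t_arr > spec.horizon):
        raise ValueError(f"t must lie in (0, {spec.horizon}]")
    base = np.asarray(spec.baseline.hazard(t_arr), float)
    lhr = spec.static_loghr(covariates) + np.array(
        [spec.timevar_loghr(covariates, ti) for ti in t_arr]
    )
    out = base * np.exp(lhr)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _cum_hazard(spec: HazardSpec, covariates: Mapping, t: float) -> float:
    """Subject-specific cumulative hazard at t (exact, segment-wise)."""
    m0 = np.exp(spec.static_loghr(covariates))
    cps = [c for c in spec.changepoints(covariates) if c < t]
    knots = [0.0] + cps + [t]
    total = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        mid = (lo + hi) / 2.0
        mult = m0 * np.exp(spec.timevar_loghr(covariates, mid))
        total += mult * (float(np.asarray(spec.baseline.cum(hi)).reshape(-1)[0])
                         - float(np.asarray(spec.baseline.cum(lo)).reshape(-1)[0]))
    return total


def _invert_cum_hazard(spec: HazardSpec, covariates: Mapping, target: float) -> float:
    """Smallest t with cumulative hazard >= target, or inf beyond the horizon."""
    if target >= _cum_hazard(spec, covariates, spec.horizon):
        return np.inf
    m0 = np.exp(spec.static_loghr(covariates))
    cps = spec.changepoints(covariates)
    knots = [0.0] + [c for c in cps if c < spec.horizon] + [spec.horizon]
    acc = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        mid = (lo + hi) / 2.0
        mult = m0 * np.exp(spec.timevar_loghr(covariates, mid))
        lam_lo = float(np.asarray(spec.baseline.cum(lo)).reshape(-1)[0])
        lam_hi = float(np.asarray(spec.baseline.cum(hi)).reshape(-1)[0])
        seg = mult * (lam_hi - lam_lo)
        if acc + seg >= target:
            rem = (target - acc) / mult + lam_lo
            if getattr(spec.baseline, "inv_cum", None) is not None:
                return float(np.asarray(spec.baseline.inv_cum(rem)).reshape(-1)[0])
            f = lambda t: float(np.asarray(spec.baseline.cum(t)).reshape(-1)[0]) - rem
            return float(bisect(f, lo, hi, xtol=1e-9))
        acc += seg
    return np.inf  # not reached


def simulate_cohort(
    spec: HazardSpec,
    n: int,
    covariate_dist: Mapping[str, Mapping[str, float]],
    seed: int,
    treatment_name: str | None = None,
) -> SurvivalCohort:
    """Draw a reproducible cohort from the ground-truth hazard.

    ``covariate_dist`` maps each covariate name to {level: probability}
    (categorical).  Event times come from inverse-cumulative-hazard sampling;
    censoring is uniform(0, censor_max) if configured, always truncated
    administratively at the horizon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    schema = []
    draws: dict[str, np.ndarray] = {}
    for name, dist in covariate_dist.items():
        levels = list(dist.keys())
        probs = np.asarray(list(dist.values()), float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"probabilities for {name!r} must sum to 1")
        schema.append(Covariate(name, "categorical", tuple(levels)))
        draws[name] = rng.choice(levels, size=n, p=probs)
    u = rng.uniform(size=n)
    cmax = spec.censor_max
    cens = rng.uniform(0, cmax, size=n) if cmax is not None else np.full(n, np.inf)

    times = np.empty(n)
    events = np.empty(n, int)
    for i in range(n):
        cov_i = {name: draws[name][i] for name in draws}
        T = _invert_cum_hazard(spec, cov_i, -np.log(u[i]))
        limit = min(cens[i], spec.horizon)
        if T <= limit:
            times[i], events[i] = T, 1
        else:
            times[i], events[i] = limit, 0
    times = np.maximum(times, 1e-9)  # guard against a 0-duration draw
    df = pd.DataFrame({"subject_id": np.arange(n), "time": times, "event": events})
    for name in draws:
        df[name] = draws[name]
    return SurvivalCohort(df, tuple(schema), treatment_name)


# ---------------------------------------------------------------------------
# scenario catalogue

#: Default covariate composition for the trial-like cohort.
default_covariate_dist = {
    "treatment": {"control": 0.5, "interferon": 0.5},
    "grade": {"G1-G2": 0.6, "G3-G4": 0.4},
    "pT": {"pT2": 0.3, "pT3a": 0.5, "pT3b": 0.2},
    "pN": {"pN0": 0.5, "pN1": 0.25, "pN2-pN3": 0.25},
}

# Gently decreasing baseline calibrated so a reference subject has roughly a
# 40% event probability by 72 months, with uniform censoring giving a median
# follow-up around five years — the regime of a long-follow-up adjuvant trial.
_BASELINE = WeibullBaseline(shape=0.8, scale=170.0)

_PROG_EFFECTS = {
    "grade": {"G3-G4": 0.4},
    "pT": {"pT3a": 0.2, "pT3b": 0.5},
    "pN": {"pN1": 0.4, "pN2-pN3": 0.8},
}


def scenario(name: str) -> tuple[HazardSpec, Mapping]:
    """Named ground-truth scenarios: null, proportional, interaction, changepoint.

    * ``null`` — no covariate affects the hazard (pure baseline).
    * ``proportional`` — time-constant prognostic effects plus a uniformly
      protective treatment (log HR -0.3).
    * ``interaction`` — qualitative treatment-by-nodes interaction: treatment
      harmful (log HR +0.4) in the node-negative group, protective
      (log HR -0.8) with multiple nodal metastases.
    * ``changepoint`` — sign-switching treatment effect: harmful (log HR
      +0.5) up to 24 months, protective (-0.5) afterwards.

    Returns the hazard spec and the default covariate distribution.
    """
    if name == "null":
        spec = HazardSpec(_BASELINE, censor_max=144.0)
    elif name == "proportional":
        spec = HazardSpec(
            _BASELINE,
            effects={**_PROG_EFFECTS, "treatment": {"interferon": -0.3}},
            censor_max=144.0,
        )
    elif name == "interaction":
        spec = HazardSpec(
            _BASELINE,
            effects=_PROG_EFFECTS,
            interactions=(
                Interaction({"treatment": "interferon", "pN": "pN0"}, 0.4),
                Interaction({"treatment": "interferon", "pN": "pN2-pN3"}, -0.8),
            ),
            censor_max=144.0,
        )
    elif name == "changepoint":
        spec = HazardSpec(
            _BASELINE,
            effects=_PROG_EFFECTS,
            interactions=(
                Interaction(
                    {"treatment": "interferon"},
                    0.5,
                    changepoint=24.0,
                    loghr_after=-0.5,
                ),
            ),
            censor_max=144.0,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return spec, default_covariate_dist


SCENARIOS = ("null", "proportional", "interaction", "changepoint")
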