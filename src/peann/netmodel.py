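"""The PEANN hazard network, its penalized likelihood and analytic gradient.

The hazard is a single-hidden-layer feed-forward network of the covariates and
(scaled) time,

    h(t; x) = exp( b2_0 + sum_k z_k * b2_k ),
    z_k     = logistic( b1_{0k} + sum_l x_l b1_{lk} + t b1_{p+1,k} ),

so the log-hazard is a smooth function of time and covariates and positivity
is automatic.  Coefficients are estimated by minimizing the penalized negative
log-likelihood of the piecewise exponential model on person-period data,

    E = -log L + lambda * (sum of squares of ALL coefficients),

where -log L = -sum_ij [ d_ij log h(t_j; x_i) - h(t_j; x_i) tau_ij ].  This is,
up to the parameter-free constant sum(d log tau), the negative log-likelihood
of independent Poisson counts d_ij with mean h * tau — the classical
person-period trick.  The penalty includes the bias terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .survdata import EncodingMap, IntervalGrid, PersonPeriodTable

__all__ = [
    "HazardNet",
    "Ensemble",
    "hazard_forward",
    "neg_log_lik",
    "objective",
    "gradient",
    "objective_and_gradient",
]

# Overflow guard on the output-layer linear predictor.  exp(50) ~ 5e21 is far
# beyond any plausible per-month hazard; at converged solutions the guard
# never binds (checked in the test suite).
_ETA_CLIP = 50.0


def _logistic(a: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class HazardNet:
    """Fitted (or candidate) hazard network.

    ``W1`` has shape (p + 2, H): row 0 is the hidden bias, rows 1..p the
    covariate weights, row p + 1 the time weight.  ``W2`` has shape (H + 1,):
    entry 0 is the output bias.  ``time_scale`` is the horizon a_J by which
    time inputs are divided; prediction APIs accept months and scale
    internally.
    """

    H: int
    W1: np.ndarray
    W2: np.ndarray
    lam: float
    time_scale: float
    encoding: EncodingMap | None = None
    grid: IntervalGrid | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, float)
        self.W2 = np.asarray(self.W2, float)
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.W1.ndim != 2 or self.W1.shape[1] != self.H:
            raise ValueError(f"W1 must have shape (p+2, {self.H})")
        if self.W2.shape != (self.H + 1,):
            raise ValueError(f"W2 must have shape ({self.H + 1},)")
        if not (np.isfinite(self.W1).all() and np.isfinite(self.W2).all()):
            raise ValueError("coefficients must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def p(self) -> int:
        return self.W1.shape[0] - 2

    @property
    def n_coef(self) -> int:
        return self.W1.size + self.W2.size

    # -- parameter vector packing (W1 column-major by hidden unit, then W2)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(order="F"), self.W2])

    def with_coefficients(self, theta: np.ndarray) -> "HazardNet":
        W1, W2 = unpack(theta, self.p, self.H)
        return HazardNet(
            self.H, W1, W2, self.lam, self.time_scale, self.encoding, self.grid
        )

    # -- prediction

    def predict_hazard(self, x_enc: np.ndarray, t_months) -> np.ndarray | float:
        """Hazard (events/month) at encoded covariates and time in months."""
        t = np.asarray(t_months, float)
        scalar = t.ndim == 0 and np.asarray(x_enc).ndim <= 1
        h = hazard_forward(self, np.atleast_2d(x_enc), np.atleast_1d(t / self.time_scale))
        return float(h[0]) if scalar and h.size == 1 else h

    # -- serialization

    def to_dict(self) -> dict:
        d = {
            "H": self.H,
            "lam": self.lam,
            "time_scale": self.time_scale,
            "W1": self.W1.tolist(),
            "W2": self.W2.tolist(),
        }
        if self.encoding is not None:
            d["encoding"] = self.encoding.to_dict()
        if self.grid is not None:
            d["grid"] = self.grid.to_dict()
        if self.diagnostics:
            d["diagnostics"] = self.diagnostics
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "HazardNet":
        return cls(
            H=int(d["H"]),
            W1=np.asarray(d["W1"], float),
            W2=np.asarray(d["W2"], float),
            lam=float(d["lam"]),
            time_scale=float(d["time_scale"]),
            encoding=EncodingMap.from_dict(d["encoding"]) if "encoding" in d else None,
            grid=IntervalGrid.from_dict(d["grid"]) if "grid" in d else None,
            diagnostics=dict(d.get("diagnostics", {})),
        )


def unpack(theta: np.ndarray, p: int, H: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, float)
    n1 = (p + 2) * H
    if theta.size != n1 + H + 1:
        raise ValueError("parameter vector has wrong length")
    W1 = theta[:n1].reshape((p + 2, H), order="F")
    W2 = theta[n1:]
    return W1, W2


@dataclass
class Ensemble:
    """A bag of networks fitted from different random initializations.

    Prediction averages the member *hazard functions* (not their
    coefficients): the members are exchangeable local optima and averaging on
    the hazard scale is what stabilizes the estimate.
    """

    members: list[HazardNet]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must be nonempty")
        h0, l0 = self.members[0].H, self.members[0].lam
        for m in self.members[1:]:
            if m.H != h0 or m.lam != l0 or m.time_scale != self.members[0].time_scale:
                raise ValueError("ensemble members must share hyperparameters")

    @property
    def H(self) -> int:
        return self.members[0].H

    @property
    def lam(self) -> float:
        return self.members[0].lam

    @property
    def encoding(self) -> EncodingMap | None:
        return self.members[0].encoding

    @property
    def grid(self) -> IntervalGrid | None:
        return self.members[0].grid

    def to_dict(self) -> dict:
        return {"members": [m.to_dict() for m in self.members]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Ensemble":
        return cls([HazardNet.from_dict(m) for m in d["members"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Ensemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# forward pass, likelihood, gradient


def hazard_forward(net: HazardNet, X: np.ndarray, t_scaled: np.ndarray) -> np.ndarray:
    """Network hazard for rows of ``X`` at scaled times ``t_scaled``.

    ``X`` is (n, p) encoded covariates; ``t_scaled`` is (n,) time already on
    the network's input scale.  Returns the strictly positive hazard per
    month.
    """
    X = np.atleast_2d(np.asarray(X, float))
    t = np.atleast_1d(np.asarray(t_scaled, float))
    if X.shape[1] != net.p:
        raise ValueError(f"expected {net.p} covariate columns, got {X.shape[1]}")
    if t.size == 1 and X.shape[0] > 1:
        t = np.full(X.shape[0], t[0])
    if X.shape[0] == 1 and t.size > 1:
        X = np.broadcast_to(X, (t.size, net.p))
    A = net.W1[0] + X @ net.W1[1:-1] + t[:, None] * net.W1[-1]
    Z = _logistic(A)
    eta = net.W2[0] + Z @ net.W2[1:]
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def _forward_parts(
    W1: np.ndarray, W2: np.ndarray, X: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = W1[0] + X @ W1[1:-1] + t[:, None] * W1[-1]
    Z = _logistic(A)
    eta = W2[0] + Z @ W2[1:]
    eta_c = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return Z, eta_c, np.exp(eta_c)


def neg_log_lik(net: HazardNet, pp: PersonPeriodTable) -> float:
    """Negative log-likelihood of the piecewise exponential model.

    -sum_ij [ d_ij * log h(t_j; x_i) - h(t_j; x_i) * tau_ij ].
    """
    _, eta, h = _forward_parts(net.W1, net.W2, pp.X, pp.t_scaled)
    return float(-(pp.d @ eta - pp.tau @ h))


def objective(net: HazardNet, pp: PersonPeriodTable) -> float:
    """Penalized objective E = neg_log_lik + lambda * sum(beta^2), biases included."""
    pen = net.lam * (np.sum(net.W1**2) + np.sum(net.W2**2))
    return neg_log_lik(net, pp) + pen


def gradient(net: HazardNet, pp: PersonPeriodTable) -> np.ndarray:
    """Analytic gradient of :func:`objective` in packed-parameter layout."""
    return objective_and_gradient(net.pack(), pp, net.p, net.H, net.lam)[1]


def objective_and_gradient(
    theta: np.ndarray, pp: PersonPeriodTable, p: int, H: int, lam: float
) -> tuple[float, np.ndarray]:
    """Penalized objective and its exact gradient, for the optimizer.

    The gradient follows from the Poisson-form likelihood: with residual
    r_ij = h * tau - d, dE/d(eta) = r, then the chain rule through the output
    layer and the logistic derivative z(1-z) for the first layer.  Where the
    overflow clip on eta binds, the local derivative is zero.
    """
    W1, W2 = unpack(theta, p, H)
    X, t, d, tau = pp.X, pp.t_scaled, pp.d, pp.tau
    A = W1[0] + X @ W1[1:-1] + t[:, None] * W1[-1]
    Z = _logistic(A)
    eta = W2[0] + Z @ W2[1:]
    clipped = np.abs(eta) > _ETA_CLIP
    eta_c = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    h = np.exp(eta_c)

    nll = -(d @ eta_c - tau @ h)
    pen = lam * float(theta @ theta)

    r = h * tau - d  # dE/d eta
    if clipped.any():
        r = np.where(clipped, 0.0, r)
    gW2 = np.empty(H + 1)
    gW2[0] = r.sum()
    gW2[1:] = Z.T @ r
    dA = (r[:, None] * W2[1:]) * (Z * (1.0 - Z))  # (n, H)
    gW1 = np.empty((p + 2, H))
    gW1[0] = dA.sum(axis=0)
    gW1[1:-1] = X.T @ dA
    gW1[-1] = t @ dA
    grad = np.concatenate([gW1.ravel(order="F"), gW2]) + 2.0 * lam * theta
    return float(nll + pen), grad
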