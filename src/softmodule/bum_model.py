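"""Beta-uniform mixture (BUM) model of a p-value distribution.

Under the null a differential-expression p-value is Uniform(0,1); signal
p-values concentrate near zero and are modelled as beta(a, 1) with shape
``a`` in (0, 1).  The marginal density of all p-values is the two-component
mixture

    f(x) = lam + (1 - lam) * a * x**(a - 1),

where ``lam`` is the weight of the uniform (noise) component.  The fitted
``lam`` also yields a point estimate of the active-module order,
k = (1 - lam) * n, since 1 - lam is the expected fraction of signal
vertices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

__all__ = [
    "BumParameters",
    "MIN_PVALUE",
    "bum_density",
    "bum_log_likelihood",
    "fit_bum",
    "estimate_module_order",
    "clamp_weights",
]

#: p-values of exactly zero are clamped up to this before any use of
#: x**(a-1), which diverges at zero.
MIN_PVALUE = 1e-16

_BOUND = 1e-6  # optimisation box is [_BOUND, 1 - _BOUND]^2


@dataclass(frozen=True)
class BumParameters:
    """Mixture weight ``lam`` of the uniform component and beta shape ``a``.

    Both are dimensionless and restricted to (0, 1); ``a < 1`` is what makes
    small p-values enriched in the signal component.
    """

    lam: float
    a: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lam must be in (0,1), got {self.lam}")
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"a must be in (0,1), got {self.a}")


def bum_density(x, params: BumParameters):
    """BUM density lam + (1-lam)*a*x**(a-1); accepts scalars or arrays."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    out = params.lam + (1.0 - params.lam) * params.a * arr ** (params.a - 1.0)
    return float(out) if np.isscalar(x) else out


def bum_log_likelihood(pvalues: np.ndarray, lam: float, a: float) -> float:
    p = np.asarray(pvalues, dtype=float)
    return float(np.sum(np.log(lam + (1.0 - lam) * a * p ** (a - 1.0))))


def clamp_weights(weights: Mapping[str, float]) -> dict[str, float]:
    """Clamp weights into (0, 1]; values below :data:`MIN_PVALUE` are raised
    to it.  Values outside [0, 1] raise."""
    out = {}
    for v, w in weights.items():
        w = float(w)
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"weight of {v!r} outside [0,1]: {w}")
        out[v] = max(w, MIN_PVALUE)
    return out


def fit_bum(weights: Mapping[str, float] | np.ndarray) -> BumParameters:
    """Maximum-likelihood fit of (lam, a) to a sample of p-values.

    The likelihood surface can carry a boundary ridge, so a bounded
    L-BFGS-B search is launched from a 3x3 grid of starting points over the
    box and the best converged optimum is kept.  On signal-free data the
    model is not identifiable: lam -> 0 with a -> 1 mimics the uniform
    density just as lam -> 1 does.  Among optima whose log-likelihoods are
    statistically indistinguishable (within 0.5) the fit therefore prefers
    the largest uniform weight, so absence of signal is always expressed
    through lam, never through a.

    Parameters
    ----------
    weights:
        Mapping vertex -> p-value, or a bare array of p-values.  At least
        10 values are required.  Zeros are clamped to :data:`MIN_PVALUE`.
    """
    if isinstance(weights, Mapping):
        vals = np.array(list(weights.values()), dtype=float)
    else:
        vals = np.asarray(weights, dtype=float).ravel()
    if vals.size < 10:
        raise ValueError(f"need at least 10 p-values to fit, got {vals.size}")
    if np.any(vals < 0.0) or np.any(vals > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    vals = np.maximum(vals, MIN_PVALUE)
    logp = np.log(vals)

    def neg_loglik(theta):
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -np.sum(np.log(dens))

    converged = []
    starts = [0.2, 0.5, 0.8]
    for lam0 in starts:
        for a0 in starts:
            res = optimize.minimize(
                neg_loglik,
                x0=np.array([lam0, a0]),
                method="L-BFGS-B",
                bounds=[(_BOUND, 1.0 - _BOUND)] * 2,
            )
            if res.success:
                converged.append(res)
    if not converged:
        raise RuntimeError("BUM maximum-likelihood fit failed from all starts")
    best_fun = min(r.fun for r in converged)
    # indistinguishable optima (the no-signal ridge): prefer largest lam
    lam_hat, a_hat = max(
        (r.x for r in converged if r.fun <= best_fun + 0.5),
        key=lambda x: x[0],
    )
    return BumParameters(lam=float(lam_hat), a=float(a_hat))


def estimate_module_order(params: BumParameters, n: int) -> int:
    """Point estimate of the module order, k = round((1 - lam) * n).

    Round-half-to-even; clamped into [1, n-1] so a fixed-order chain always
    has both a non-empty module and a non-empty complement.
    """
    if n < 2:
        raise ValueError("graph must have at least 2 vertices")
    k = int(round((1.0 - params.lam) * n))
    return max(1, min(k, n - 1))
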