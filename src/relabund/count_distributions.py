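"""Count distributions for the N-mixture submodels.

The between-site (abundance) submodel is Poisson or negative binomial; the
within-site (detection) submodel is binomial or beta-binomial.  Besides the
log pmfs this module exposes the closed-form log pmf *ratios* in the latent
abundance N (N -> N+1), which let the marginal N-mixture likelihood advance
through the truncated sum with cheap arithmetic instead of repeated
log-gamma evaluations, and a streaming log-sum-exp accumulator.

Parameterizations
-----------------
* negative binomial: mean ``lambda`` and size ``theta_b``; variance
  ``lambda + lambda**2 / theta_b`` (the "nbinom2" convention).
* beta-binomial: mean ``p`` and precision ``theta_w``; Beta shapes
  ``alpha = p * theta_w``, ``beta = (1 - p) * theta_w``, so logit-link
  covariates act on the mean detection probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AbundanceDist",
    "DetectionDist",
    "abundance_log_pmf",
    "detection_log_pmf",
    "abundance_log_ratio",
    "detection_log_ratio",
    "StreamLogSum",
]


@dataclass(frozen=True)
class AbundanceDist:
    """Between-site distribution of latent abundance N_i.

    ``theta_b`` must be absent for ``family='poisson'`` and present
    (positive) for ``family='negbinom'``.
    """

    family: str
    lam: float
    theta_b: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbinom"):
            raise ValueError(f"unknown abundance family {self.family!r}")
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if self.family == "poisson" and self.theta_b is not None:
            raise ValueError("theta_b must be absent for poisson")
        if self.family == "negbinom" and (
            self.theta_b is None or not self.theta_b > 0
        ):
            raise ValueError("theta_b must be positive for negbinom")


@dataclass(frozen=True)
class DetectionDist:
    """Within-site distribution of a count y_ij given latent N_i.

    ``theta_w`` must be absent for ``family='binomial'`` and present
    (positive) for ``family='betabinom'``.
    """

    family: str
    p: float
    theta_w: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "betabinom"):
            raise ValueError(f"unknown detection family {self.family!r}")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")
        if self.family == "binomial" and self.theta_w is not None:
            raise ValueError("theta_w must be absent for binomial")
        if self.family == "betabinom" and (
            self.theta_w is None or not self.theta_w > 0
        ):
            raise ValueError("theta_w must be positive for betabinom")


def _check_counts(n, name: str = "n") -> np.ndarray:
    arr = np.asarray(n)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{name} must be integer-valued")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def abundance_log_pmf(dist: AbundanceDist, n) -> np.ndarray | float:
    """log f(n) of the abundance distribution; vectorized over ``n``."""
    n = _check_counts(n)
    if dist.family == "poisson":
        out = stats.poisson.logpmf(n, dist.lam)
    else:
        th = dist.theta_b
        out = stats.nbinom.logpmf(n, th, th / (th + dist.lam))
    return out if np.ndim(out) else float(out)


def detection_log_pmf(
    dist: DetectionDist, y, n, *, strict: bool = True
) -> np.ndarray | float:
    """log f(y | n) of the detection distribution; vectorized.

    With ``strict=True`` (validation contexts) any ``y > n`` raises; with
    ``strict=False`` such cells are -inf, which is the convention needed
    when a caller wants total-mass bookkeeping over a grid of N.
    """
    y = _check_counts(y, "y")
    n = _check_counts(n, "n")
    if strict and np.any(y > np.broadcast_to(n, np.broadcast_shapes(np.shape(y), np.shape(n)))):
        raise ValueError("y must not exceed n")
    if dist.family == "binomial":
        out = stats.binom.logpmf(y, n, dist.p)
    else:
        a = dist.p * dist.theta_w
        b = (1.0 - dist.p) * dist.theta_w
        out = stats.betabinom.logpmf(y, n, a, b)
    return out if np.ndim(out) else float(out)


def abundance_log_ratio(dist: AbundanceDist, n) -> np.ndarray | float:
    """log f(n+1) - log f(n) in closed form (no log-gamma)."""
    n = _check_counts(n)
    if dist.family == "poisson":
        out = np.log(dist.lam) - np.log1p(n)
    else:
        th = dist.theta_b
        out = (
            np.log(n + th)
            - np.log1p(n)
            + math.log(dist.lam)
            - math.log(dist.lam + th)
        )
    return out if np.ndim(out) else float(out)


def detection_log_ratio(dist: DetectionDist, y, n) -> np.ndarray | float:
    """log f(y | n+1) - log f(y | n) in closed form (no log-gamma).

    Requires ``n >= y`` so both pmfs in the ratio are positive.
    """
    y = _check_counts(y, "y")
    n = _check_counts(n, "n")
    if np.any(np.broadcast_to(n, np.broadcast_shapes(np.shape(y), np.shape(n))) < y):
        raise ValueError("n must be >= y")
    n = n.astype(float)
    if dist.family == "binomial":
        out = np.log((n + 1.0) * (1.0 - dist.p)) - np.log(n + 1.0 - y)
    else:
        a = dist.p * dist.theta_w
        b = (1.0 - dist.p) * dist.theta_w
        out = np.log((n + 1.0) * (n - y + b)) - np.log(
            (n + 1.0 - y) * (n + a + b)
        )
    return out if np.ndim(out) else float(out)


class StreamLogSum:
    """Streaming log-sum-exp: accumulate log-terms, read off log of the sum.

    Keeps the running maximum and the sum of terms rescaled by it, so the
    result is finite whenever any term is, regardless of term magnitudes.
    -inf terms are absorbed without effect.
    """

    __slots__ = ("_max", "_scaled")

    def __init__(self) -> None:
        self._max = -math.inf
        self._scaled = 0.0

    def add(self, log_term: float) -> "StreamLogSum":
        if log_term == -math.inf:
            return self
        if log_term <= self._max:
            self._scaled += math.exp(log_term - self._max)
        else:
            self._scaled = self._scaled * math.exp(self._max - log_term) + 1.0
            self._max = log_term
        return self

    @property
    def value(self) -> float:
        if self._max == -math.inf:
            return -math.inf
        return self._max + math.log(self._scaled)
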