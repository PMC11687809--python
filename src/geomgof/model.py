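"""Geometric probability model on the support {1, 2, ...}.

The model is parametrised by the per-trial success probability ``theta``:
``p_i(theta) = (1 - theta)**(i - 1) * theta`` is the probability that the
first success occurs on trial ``i``.  Everything downstream (test statistics,
asymptotic covariances, critical values) is built from the pmf, the CDF
``H_i = 1 - (1 - theta)**i``, the score vector ``b_j = dp_j/dtheta`` and the
maximum-likelihood estimator ``theta_hat = 1 / xbar``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


class DegenerateSampleError(ValueError):
    """Raised when every observation equals 1, putting the MLE on the boundary."""


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not 0.0 < theta < 1.0:
        raise ValueError(
            f"theta must lie strictly inside (0, 1); got {theta!r} "
            "(boundary values make the geometric model degenerate)"
        )
    return theta


def _check_k(k: int) -> int:
    k = int(k)
    if k < 1:
        raise ValueError(f"truncation index k must be a positive integer; got {k}")
    return k


def pmf_vector(theta: float, k: int) -> np.ndarray:
    """Probabilities ``p_i = (1-theta)**(i-1) * theta`` for cells ``i = 1..k``."""
    theta = _check_theta(theta)
    k = _check_k(k)
    i = np.arange(1, k + 1)
    return (1.0 - theta) ** (i - 1) * theta


def cdf_vector(theta: float, k: int) -> np.ndarray:
    """Distribution function ``H_i = 1 - (1-theta)**i`` for ``i = 1..k``.

    Closed form rather than a cumulative sum of :func:`pmf_vector`, so that
    downstream cumulative deviations do not accumulate cancellation error.
    """
    theta = _check_theta(theta)
    k = _check_k(k)
    i = np.arange(1, k + 1)
    return 1.0 - (1.0 - theta) ** i


def sf_vector(theta: float, k: int) -> np.ndarray:
    """Survival function ``1 - H_i = (1-theta)**i`` for ``i = 1..k``.

    Computed directly so that tail weights ``1 / (H_i (1 - H_i))`` stay
    finite where ``H_i`` rounds to 1 in double precision.
    """
    theta = _check_theta(theta)
    k = _check_k(k)
    i = np.arange(1, k + 1)
    return (1.0 - theta) ** i


def score_vector(theta: float, k: int) -> np.ndarray:
    """Derivatives ``b_j = dp_j/dtheta = (1-theta)**(j-2) * (1 - j*theta)``.

    Evaluated in closed form (``b_1`` is identically 1) so the MLE-corrected
    covariance is exact to round-off.
    """
    theta = _check_theta(theta)
    k = _check_k(k)
    j = np.arange(1, k + 1)
    return (1.0 - theta) ** (j - 2.0) * (1.0 - j * theta)


def fisher_information(theta: float) -> float:
    """Fisher information ``1 / (theta**2 * (1 - theta))`` of one observation."""
    theta = _check_theta(theta)
    return 1.0 / (theta**2 * (1.0 - theta))


def mle_theta(table) -> float:
    """Maximum-likelihood estimate ``theta_hat = 1 / xbar`` from a frequency table.

    Parameters
    ----------
    table
        A :class:`~geomgof.statistics.FrequencyTable` (anything exposing
        ``n``, ``k`` and ``mean``).

    Raises
    ------
    DegenerateSampleError
        If all observations equal 1, in which case ``theta_hat = 1`` sits on
        the boundary and the test statistics are undefined.
    """
    if table.n <= 0:
        raise ValueError("frequency table holds no observations")
    if table.k == 1:
        raise DegenerateSampleError(
            "all observations equal 1: theta_hat = 1 lies on the boundary "
            "and the geometric fit is degenerate"
        )
    return 1.0 / table.mean


def wald_ci(theta_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Delta-method (Wald) confidence interval for theta.

    The MLE is ``1 / xbar``; the delta method gives
    ``Var(theta_hat) ~ theta**2 * (1 - theta) / n``, hence the interval
    ``theta_hat +- z * sqrt(theta_hat**2 * (1 - theta_hat) / n)``, clipped to
    the open unit interval.
    """
    theta_hat = _check_theta(theta_hat)
    n = int(n)
    if n < 2:
        raise ValueError("need at least n = 2 observations for an interval")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1); got {level}")
    z = _stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(theta_hat**2 * (1.0 - theta_hat) / n)
    eps = np.finfo(float).tiny
    return (max(theta_hat - half, eps), min(theta_hat + half, 1.0 - 1e-15))


@dataclass(frozen=True)
class GeometricModel:
    """Geometric model truncated at cell ``k`` (support cells ``1..k``)."""

    theta: float
    k: int

    def __post_init__(self) -> None:
        _check_theta(self.theta)
        _check_k(self.k)

    @property
    def pmf(self) -> np.ndarray:
        return pmf_vector(self.theta, self.k)

    @property
    def cdf(self) -> np.ndarray:
        return cdf_vector(self.theta, self.k)

    @property
    def score(self) -> np.ndarray:
        return score_vector(self.theta, self.k)
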