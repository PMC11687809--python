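"""Asymptotic null-distribution machinery for the discrete EDF statistics.

The observed cell counts are multinomial, so the scaled cell deviations
``(o - e)/sqrt(n)`` are asymptotically normal with covariance
``Sigma_0 = D - P P^T`` (``D = diag(p)``).  The cumulative deviations
``Z = R (o - e)`` (``R`` the unit lower-triangular partial-sum matrix) then
have covariance ``Sigma = R Sigma_0 R^T``, whose (i, j) element reduces to
``min(H_i, H_j) - H_i H_j``.  When theta is replaced by its MLE the rank-one
correction ``Sigma_0 - b b^T / (b^T D^-1 b)`` applies, with ``b`` the vector
of pmf derivatives.  Both statistics are quadratic forms ``Z^T V Z / n``, so
their limit law is ``sum lambda_i nu_i**2`` with ``lambda_i`` the eigenvalues
of ``V^{1/2} Sigma V^{1/2}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from . import wchi2 as _wchi2

#: relative threshold below which small negative eigenvalues are treated as noise
EIGEN_CLIP_REL = 1e-10
#: residual geometric mass (1 - theta)**k allowed beyond the truncation cell
MASS_FLOOR = 1e-10
#: absolute change in the target quantile regarded as converged in k
QUANTILE_TOL = 5e-5
#: hard cap on the truncation search
K_MAX = 5000

_STATISTICS = ("watson", "anderson_darling")


def _check_statistic(statistic: str) -> str:
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}; got {statistic!r}")
    return statistic


def _sigma0(theta: float, k: int, estimated: bool) -> np.ndarray:
    p = _model.pmf_vector(theta, k)
    sigma0 = np.diag(p) - np.outer(p, p)
    if estimated:
        b = _model.score_vector(theta, k)
        info = float((b * b / p).sum())  # b^T D^-1 b, truncated Fisher information
        sigma0 = sigma0 - np.outer(b, b) / info
    return sigma0


def _partial_sum(mat: np.ndarray) -> np.ndarray:
    # R M R^T without forming R: cumulative sums along both axes
    return np.cumsum(np.cumsum(mat, axis=0), axis=1)


def covariance_known(theta: float, k: int) -> np.ndarray:
    """Covariance ``Sigma = R Sigma_0 R^T`` of the cumulative deviations."""
    return _partial_sum(_sigma0(theta, int(k), estimated=False))


def covariance_known_closed_form(theta: float, k: int) -> np.ndarray:
    """The same matrix via ``min(H_i, H_j) - H_i H_j`` (independent construction)."""
    H = _model.cdf_vector(theta, int(k))
    return np.minimum.outer(H, H) - np.outer(H, H)


def covariance_estimated(theta: float, k: int) -> np.ndarray:
    """MLE-corrected covariance ``R (Sigma_0 - b b^T / (b^T D^-1 b)) R^T``."""
    return _partial_sum(_sigma0(theta, int(k), estimated=True))


def weight_matrix(statistic: str, theta: float, k: int) -> np.ndarray:
    """Diagonal of the quadratic-form weight ``V``.

    ``V = D`` (entries ``p_i``) for the Watson statistic and ``V = D G^-1``
    (entries ``p_i / (H_i (1 - H_i))``) for Anderson-Darling.  Returned as
    the 1-D vector of diagonal entries; all entries are positive.
    """
    statistic = _check_statistic(statistic)
    p = _model.pmf_vector(theta, int(k))
    if statistic == "watson":
        return p
    # 1 - H_i computed as (1-theta)**i directly: H_i rounds to 1.0 in double
    # precision long before the truncation floor at small theta
    sf = _model.sf_vector(theta, int(k))
    return p / ((1.0 - sf) * sf)


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues of ``V^{1/2} Sigma V^{1/2}`` for one test configuration."""

    lambdas: np.ndarray = field(repr=False)
    statistic: str
    theta: float
    estimated: bool
    k: int

    @property
    def trace(self) -> float:
        return float(self.lambdas.sum())


def eigen_spectrum(
    statistic: str, theta: float, estimated: bool, k: int
) -> EigenSpectrum:
    """Spectrum defining the null law ``sum lambda_i nu_i**2``.

    The matrix is explicitly symmetrised before the symmetric eigensolver;
    eigenvalues more negative than ``-EIGEN_CLIP_REL * lambda_max`` indicate a
    real failure and raise, smaller negatives are clipped to zero.
    """
    statistic = _check_statistic(statistic)
    k = int(k)
    sigma = covariance_estimated(theta, k) if estimated else covariance_known(theta, k)
    sqrt_v = np.sqrt(weight_matrix(statistic, theta, k))
    m = sqrt_v[:, None] * sigma * sqrt_v[None, :]
    lam = np.linalg.eigvalsh(0.5 * (m + m.T))[::-1].copy()
    lmax = lam[0]
    if lmax <= 0:
        raise np.linalg.LinAlgError(
            f"spectrum is not positive (lambda_max={lmax!r}) for "
            f"{statistic}, theta={theta}, estimated={estimated}, k={k}"
        )
    trace = float(lam.sum())
    clipped = lam < EIGEN_CLIP_REL * lmax
    removed = float(np.abs(lam[clipped]).sum())
    if removed > 1e-6 * trace:
        raise np.linalg.LinAlgError(
            f"clipping near-zero eigenvalues would remove {removed!r} of a "
            f"trace {trace!r}; the covariance construction is inconsistent "
            f"({statistic}, theta={theta}, estimated={estimated}, k={k})"
        )
    lam[clipped] = 0.0
    return EigenSpectrum(lambdas=lam, statistic=statistic, theta=float(theta),
                         estimated=bool(estimated), k=k)


def truncation_floor(theta: float, mass_tol: float = MASS_FLOOR) -> int:
    """Smallest ``k`` with residual geometric mass ``(1-theta)**k < mass_tol``."""
    theta = float(theta)
    return max(1, math.ceil(math.log(mass_tol) / math.log1p(-theta)))


def choose_truncation(
    statistic: str,
    theta: float,
    estimated: bool,
    alpha: float,
    *,
    quantile_tol: float = QUANTILE_TOL,
    mass_tol: float = MASS_FLOOR,
    k_max: int = K_MAX,
) -> int:
    """Truncation ``k`` at which the alpha upper quantile has converged.

    Starting from the residual-mass floor, ``k`` is doubled until the target
    quantile of the induced weighted-chi-square law changes by less than
    ``quantile_tol`` between successive values.
    """
    _check_statistic(statistic)
    k = truncation_floor(theta, mass_tol)
    q_prev = _wchi2.upper_quantile(
        eigen_spectrum(statistic, theta, estimated, k).lambdas, alpha
    )
    while True:
        k_next = 2 * k
        if k_next > k_max:
            raise RuntimeError(
                f"quantile did not converge in k below {k_max} "
                f"(theta={theta}, statistic={statistic})"
            )
        q_next = _wchi2.upper_quantile(
            eigen_spectrum(statistic, theta, estimated, k_next).lambdas, alpha
        )
        if abs(q_next - q_prev) < quantile_tol:
            return k_next
        k, q_prev = k_next, q_next
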