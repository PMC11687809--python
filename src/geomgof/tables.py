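"""Critical-value tables and p-values for the geometric fit tests.

Upper-tail percentage points of the null law are tabulated over a theta grid
(seven conventional significance levels); the package ships pre-generated
grids for both statistics in estimated-theta mode, regenerable with
:func:`generate_table` (or ``geomgof tables`` from the shell).  Reported
p-values come in two forms: a bracket between adjacent tabulated levels
(classic look-up style) and a continuous p-value computed directly from the
eigen-spectrum at the estimated theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import asymptotics as _asym
from . import wchi2 as _wchi2

#: conventional significance levels (stored ascending)
DEFAULT_ALPHAS = (0.01, 0.025, 0.05, 0.10, 0.15, 0.25, 0.50)

#: packaged theta grids (the Watson grid omits 0.35)
WATSON_THETA_GRID = (
    0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.45, 0.48, 0.49, 0.50,
    0.51, 0.52, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95,
)
AD_THETA_GRID = (
    0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.48, 0.49, 0.50,
    0.51, 0.52, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95,
)

_CSV_COLUMNS = ["theta", "alpha", "critical_value", "statistic", "estimated"]


@dataclass(frozen=True)
class CriticalValueTable:
    """Grid of upper-tail percentage points over (theta, alpha)."""

    statistic: str
    estimated: bool
    thetas: np.ndarray = field(repr=False)
    alphas: np.ndarray = field(repr=False)
    points: np.ndarray = field(repr=False)  # shape (len(thetas), len(alphas))

    def __post_init__(self) -> None:
        thetas = np.asarray(self.thetas, dtype=float)
        alphas = np.asarray(self.alphas, dtype=float)
        points = np.asarray(self.points, dtype=float)
        if np.any(np.diff(thetas) <= 0) or np.any(np.diff(alphas) <= 0):
            raise ValueError("theta and alpha grids must be strictly increasing")
        if points.shape != (thetas.size, alphas.size):
            raise ValueError("points matrix does not match the grids")
        if np.any(points <= 0):
            raise ValueError("all percentage points must be positive")
        if np.any(np.diff(points, axis=1) >= 0):
            raise ValueError("upper-tail points must shrink as alpha grows")
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "points", points)

    def critical_values(self, theta_hat: float) -> np.ndarray:
        """Percentage points at ``theta_hat``, linearly interpolated in theta."""
        theta_hat = float(theta_hat)
        if not self.thetas[0] <= theta_hat <= self.thetas[-1]:
            raise ValueError(
                f"theta_hat={theta_hat} outside the tabulated range "
                f"[{self.thetas[0]}, {self.thetas[-1]}]; compute the "
                "continuous p-value directly instead"
            )
        return np.array(
            [np.interp(theta_hat, self.thetas, col) for col in self.points.T]
        )


def generate_table(
    statistic: str,
    thetas,
    alphas=DEFAULT_ALPHAS,
    estimated: bool = True,
) -> CriticalValueTable:
    """Regenerate a percentage-point grid from the asymptotic spectra.

    For each theta the truncation is chosen once at the smallest (hardest)
    alpha, then all levels share the same eigen-spectrum.
    """
    thetas = np.sort(np.asarray(thetas, dtype=float))
    alphas = np.sort(np.asarray(alphas, dtype=float))
    if thetas.size == 0 or alphas.size == 0:
        raise ValueError("empty theta or alpha grid")
    rows = []
    for theta in thetas:
        k = _asym.choose_truncation(statistic, theta, estimated, float(alphas[0]))
        lam = _asym.eigen_spectrum(statistic, theta, estimated, k).lambdas
        rows.append([_wchi2.upper_quantile(lam, float(a)) for a in alphas])
    return CriticalValueTable(
        statistic=statistic,
        estimated=bool(estimated),
        thetas=thetas,
        alphas=alphas,
        points=np.asarray(rows),
    )


def write_table_csv(table: CriticalValueTable, path) -> None:
    """Serialise a table (full float precision, bit-exact round trip)."""
    tt, aa = np.meshgrid(table.thetas, table.alphas, indexing="ij")
    df = pd.DataFrame(
        {
            "theta": tt.ravel(),
            "alpha": aa.ravel(),
            "critical_value": table.points.ravel(),
            "statistic": table.statistic,
            "estimated": table.estimated,
        }
    )
    # default float formatting emits the shortest round-trippable repr;
    # reading back with float_precision="round_trip" makes the cycle bit-exact
    df.to_csv(path, index=False)


def read_table_csv(path) -> CriticalValueTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"critical-value CSV is missing columns {sorted(missing)}")
    stats = df["statistic"].unique()
    flags = df["estimated"].unique()
    if len(stats) != 1 or len(flags) != 1:
        raise ValueError("critical-value CSV must hold exactly one configuration")
    thetas = np.sort(df["theta"].unique())
    alphas = np.sort(df["alpha"].unique())
    piv = df.pivot(index="theta", columns="alpha", values="critical_value")
    piv = piv.sort_index().sort_index(axis=1)
    return CriticalValueTable(
        statistic=str(stats[0]),
        estimated=bool(flags[0]),
        thetas=thetas,
        alphas=alphas,
        points=piv.to_numpy(),
    )


def load_packaged_table(statistic: str) -> CriticalValueTable:
    """The shipped estimated-theta grid for ``'watson'`` or ``'anderson_darling'``."""
    _asym._check_statistic(statistic)
    name = f"critical_values_{statistic}_estimated.csv"
    with resources.as_file(resources.files("geomgof.data") / name) as path:
        return read_table_csv(path)


def pvalue_bracket(
    table: CriticalValueTable, theta_hat: float, statistic_value: float
) -> tuple[float, float]:
    """Bracket ``(lo, hi)`` of tabulated levels with ``lo < p < hi``.

    Open-ended results use ``lo = 0`` (``p`` below the smallest level) and
    ``hi = 1`` (``p`` above the largest).  Critical values are interpolated
    linearly in theta at ``theta_hat``.
    """
    statistic_value = float(statistic_value)
    if statistic_value < 0:
        raise ValueError("statistic value must be non-negative")
    crit = table.critical_values(theta_hat)  # decreasing across ascending alpha
    alphas = table.alphas
    if statistic_value >= crit[0]:
        return (0.0, float(alphas[0]))
    if statistic_value < crit[-1]:
        return (float(alphas[-1]), 1.0)
    i = int(np.sum(crit > statistic_value)) - 1  # crit[i] > value >= crit[i+1]
    return (float(alphas[i]), float(alphas[i + 1]))


def format_bracket(bracket: tuple[float, float]) -> str:
    lo, hi = bracket
    if lo == 0.0:
        return f"p < {hi:g}"
    if hi == 1.0:
        return f"p > {lo:g}"
    return f"{lo:g} < p < {hi:g}"


def continuous_pvalue(
    statistic: str,
    theta_hat: float,
    statistic_value: float,
    estimated: bool = True,
    k: int | None = None,
) -> float:
    """Asymptotic p-value ``P(sum lambda_i nu_i**2 > value)`` at ``theta_hat``.

    The spectrum is truncated at twice the residual-mass floor by default,
    which the table-generation convergence checks show is ample; pass ``k``
    to override.
    """
    if statistic_value < 0:
        raise ValueError("statistic value must be non-negative")
    if k is None:
        k = 2 * _asym.truncation_floor(theta_hat)
    lam = _asym.eigen_spectrum(statistic, theta_hat, estimated, k).lambdas
    return _wchi2.upper_tail(lam, float(statistic_value))
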