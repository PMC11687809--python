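"""Discrete Watson W^2 and Anderson-Darling A^2 statistics for grouped data.

Observed counts ``o_1..o_k`` (``k`` = last non-empty cell) are compared with
expected counts ``e_i = n * p_i(theta)`` through the cumulative deviations
``Z_j = S_j - T_j`` where ``S_j = sum_{i<=j} o_i`` and ``T_j = n * H_j``:

    W^2 = n**-1 * sum_i Z_i**2 * p_i(theta)
    A^2 = n**-1 * sum_i Z_i**2 * p_i(theta) / (H_i * (1 - H_i))

Counts are allowed to be fractional so that exact-fit fixtures (``o = e``)
can exercise the zero of both statistics; real data always has integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from . import model as _model


@dataclass(frozen=True)
class FrequencyTable:
    """Dense table of observed counts over cells ``1..k``.

    ``counts[i - 1]`` is the count of outcome value ``i``; interior zero
    cells are kept (they still contribute cumulative-deviation terms), while
    trailing zero cells are trimmed so that ``k`` is always the last cell
    that actually carries data.
    """

    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        # trim trailing zeros: k is defined by the data, not by the caller
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            raise ValueError("frequency table holds no observations")
        counts = counts[: nz[-1] + 1]
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, mapping: Mapping[int, float]) -> "FrequencyTable":
        """Build from a ``{value: count}`` mapping with values >= 1."""
        if not mapping:
            raise ValueError("empty count mapping")
        values = np.array(sorted(mapping), dtype=float)
        if np.any(values < 1) or np.any(values != np.round(values)):
            raise ValueError("outcome values must be positive integers")
        dense = np.zeros(int(values[-1]), dtype=float)
        for v, c in mapping.items():
            dense[int(v) - 1] = c
        return cls(dense)

    @classmethod
    def from_sample(cls, sample: Iterable[int]) -> "FrequencyTable":
        """Tally a raw sample of positive integers."""
        x = np.asarray(list(sample), dtype=float)
        if x.size == 0:
            raise ValueError("empty sample")
        if np.any(x < 1) or np.any(x != np.round(x)):
            raise ValueError("sample values must be positive integers")
        return cls(np.bincount(x.astype(int))[1:].astype(float))

    @property
    def k(self) -> int:
        return self.counts.size

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def values(self) -> np.ndarray:
        return np.arange(1, self.k + 1)

    @property
    def mean(self) -> float:
        """Sample mean ``sum(i * o_i) / n``."""
        return float((self.values * self.counts).sum() / self.n)


@dataclass(frozen=True)
class GofStatistics:
    """The (W^2, A^2) pair together with the intermediates for one dataset."""

    w2: float
    a2: float
    theta_used: float
    estimated: bool
    S: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)


def cumulative_deviations(
    table: FrequencyTable, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectors ``(S, T, Z, H)`` over cells ``1..k``.

    ``T`` is computed from the closed-form CDF (``T_j = n * H_j``) rather
    than by summing the pmf, limiting cancellation in ``Z`` at large ``k``.
    """
    H = _model.cdf_vector(theta, table.k)
    S = np.cumsum(table.counts)
    T = table.n * H
    return S, T, S - T, H


def watson_w2(table: FrequencyTable, theta: float) -> float:
    """Discrete Watson statistic ``n**-1 * sum Z_i**2 * p_i(theta)``."""
    _, _, Z, _ = cumulative_deviations(table, theta)
    p = _model.pmf_vector(theta, table.k)
    return float((Z**2 * p).sum() / table.n)


def anderson_darling_a2(table: FrequencyTable, theta: float) -> float:
    """Discrete Anderson-Darling statistic with weights ``1 / (H_i (1 - H_i))``."""
    _, _, Z, _ = cumulative_deviations(table, theta)
    p = _model.pmf_vector(theta, table.k)
    sf = _model.sf_vector(theta, table.k)  # 1 - H without cancellation
    return float((Z**2 * p / ((1.0 - sf) * sf)).sum() / table.n)


def gof_statistics(table: FrequencyTable, theta: float | None = None) -> GofStatistics:
    """Compute both statistics; ``theta=None`` plugs in the MLE ``1 / xbar``."""
    estimated = theta is None
    if estimated:
        theta = _model.mle_theta(table)
    S, T, Z, H = cumulative_deviations(table, theta)
    p = _model.pmf_vector(theta, table.k)
    sf = _model.sf_vector(theta, table.k)
    w2 = float((Z**2 * p).sum() / table.n)
    a2 = float((Z**2 * p / ((1.0 - sf) * sf)).sum() / table.n)
    return GofStatistics(w2=w2, a2=a2, theta_used=float(theta), estimated=estimated,
                         S=S, T=T, Z=Z, H=H)
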