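"""Extraction of up/down run lengths from a numeric time series.

A "run" is a maximal streak of consecutive same-direction moves (first
differences of the series); its length counts the moves in the streak.  Run
lengths of efficient price series are the canonical geometric-fit use case:
if daily direction changes are Bernoulli(theta), run lengths are geometric.

Zero differences (tied consecutive values) have no inherent direction and the
treatment is a modelling choice, so ``zero_policy`` is a required argument:

``"error"``
    reject the series (safest: forces the caller to decide),
``"break"``
    a tie terminates the current run; the next non-zero move starts a new one,
``"drop"``
    delete the tied observation and recompute the differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .statistics import FrequencyTable

ZERO_POLICIES = ("error", "break", "drop")


@dataclass(frozen=True)
class RunSeries:
    lengths: np.ndarray = field(repr=False)   # positive integers
    directions: np.ndarray = field(repr=False)  # parallel array of "up"/"down"

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        directions = np.asarray(self.directions, dtype=object)
        if lengths.size == 0:
            raise ValueError("no runs")
        if lengths.shape != directions.shape:
            raise ValueError("lengths and directions must be parallel")
        if np.any(lengths < 1):
            raise ValueError("run lengths must be positive")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "directions", directions)


def runs_from_series(series, zero_policy: str) -> RunSeries:
    """Group consecutive same-sign first differences into runs."""
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of at least two values")

    if zero_policy == "drop":
        # remove the later element of each tie, repeatedly, then re-diff
        while x.size >= 2:
            keep = np.concatenate(([True], np.diff(x) != 0.0))
            if keep.all():
                break
            x = x[keep]

    d = np.sign(np.diff(x))
    if zero_policy == "error" and np.any(d == 0.0):
        tie = int(np.nonzero(d == 0.0)[0][0])
        raise ValueError(
            f"tied consecutive values at positions {tie}..{tie + 1}; "
            "choose zero_policy='break' or 'drop' to proceed"
        )

    lengths: list[int] = []
    directions: list[str] = []
    current_sign = 0.0
    current_len = 0

    def close() -> None:
        nonlocal current_len, current_sign
        if current_len:
            lengths.append(current_len)
            directions.append("up" if current_sign > 0 else "down")
        current_len, current_sign = 0, 0.0

    for s in d:
        if s == 0.0:  # only reachable under "break"
            close()
        elif s == current_sign:
            current_len += 1
        else:
            close()
            current_sign, current_len = s, 1
    close()

    if not lengths:
        raise ValueError("series has no non-zero moves; no runs to extract")
    return RunSeries(np.array(lengths), np.array(directions, dtype=object))


def runs_to_frequency_table(runs: RunSeries) -> FrequencyTable:
    """Counts of each run length, pooled over up and down runs."""
    return FrequencyTable.from_sample(runs.lengths)
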