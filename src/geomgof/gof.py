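"""End-to-end geometric goodness-of-fit procedure, report objects and file I/O.

The test runs in five steps: (1) estimate ``theta_hat = 1 / xbar``; (2)
evaluate the geometric pmf at ``theta_hat`` over the observed cells ``1..k``;
(3) compute W^2(theta_hat) and/or A^2(theta_hat); (4) enter the critical-value
table at ``theta_hat`` (a continuous p-value from the eigen-spectrum is
reported alongside the classical bracket); (5) reject at level alpha when the
statistic exceeds the tabulated point.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from . import model as _model
from . import tables as _tables
from .statistics import FrequencyTable, gof_statistics

_TAGS = {"watson": "W2", "anderson_darling": "A2"}

#: packaged example datasets: run-length frequencies of daily moves of four
#: stock indices (NASDAQ, DJIA, Nikkei 225, Mexican IPC), 2015-2022.
EXAMPLE_DATASETS = ("nasdaq", "djia", "nikkei225", "ipc")


@dataclass(frozen=True)
class StatisticResult:
    """One statistic's value, p-values and decision."""

    statistic: str
    value: float
    bracket: tuple[float, float] | None
    bracket_text: str | None
    pvalue: float
    critical_value: float | None
    reject: bool


@dataclass(frozen=True)
class GofReport:
    """Everything the test procedure produces for one dataset."""

    n: float
    mean: float
    theta_hat: float
    ci_level: float
    ci: tuple[float, float]
    alpha: float
    results: dict[str, StatisticResult]
    table_source: str
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["results"] = {k: asdict(v) for k, v in self.results.items()}
        return d


def gof_test(
    data: FrequencyTable,
    statistic: str = "both",
    alpha: float = 0.05,
    ci_level: float = 0.95,
) -> GofReport:
    """Run the full fit test on a frequency table of positive integers."""
    if statistic not in ("both", *_TAGS):
        raise ValueError(f"statistic must be 'both' or one of {tuple(_TAGS)}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    wanted = list(_TAGS) if statistic == "both" else [statistic]

    theta_hat = _model.mle_theta(data)
    ci = _model.wald_ci(theta_hat, int(round(data.n)), ci_level)
    stats = gof_statistics(data)  # computes both W2 and A2 at theta_hat

    notes: list[str] = []
    results: dict[str, StatisticResult] = {}
    for tag in wanted:
        value = stats.w2 if tag == "watson" else stats.a2
        table = _tables.load_packaged_table(tag)
        bracket = bracket_text = crit = None
        in_grid = table.thetas[0] <= theta_hat <= table.thetas[-1]
        if in_grid:
            bracket = _tables.pvalue_bracket(table, theta_hat, value)
            bracket_text = _tables.format_bracket(bracket)
            alpha_cols = table.critical_values(theta_hat)
            idx = np.nonzero(np.isclose(table.alphas, alpha))[0]
            if idx.size:
                crit = float(alpha_cols[idx[0]])
        else:
            notes.append(
                f"theta_hat={theta_hat:.4f} outside the tabulated grid for "
                f"{tag}; only the continuous p-value is reported"
            )
        pvalue = _tables.continuous_pvalue(tag, theta_hat, value)
        reject = value > crit if crit is not None else pvalue < alpha
        results[tag] = StatisticResult(
            statistic=tag, value=value, bracket=bracket,
            bracket_text=bracket_text, pvalue=pvalue,
            critical_value=crit, reject=reject,
        )

    return GofReport(
        n=data.n, mean=data.mean, theta_hat=theta_hat, ci_level=ci_level,
        ci=ci, alpha=alpha, results=results,
        table_source="packaged asymptotic grid (estimated theta)",
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=",;\t ").delimiter
    except csv.Error:
        return ","


def read_frequency_table(path, format: str = "counts_csv") -> FrequencyTable:
    """Read a frequency table from disk.

    ``counts_csv`` expects a header ``value,count`` (comma or tab delimited)
    with positive-integer values and non-negative integer counts;
    ``raw_sample`` expects one positive integer per line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]

    if format == "raw_sample":
        sample = []
        for lineno, ln in enumerate(lines, start=1):
            if not ln:
                continue
            try:
                v = int(ln)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: not an integer: {ln!r}") from None
            if v < 1:
                raise ValueError(f"{path}:{lineno}: values must be >= 1, got {v}")
            sample.append(v)
        if not sample:
            raise ValueError(f"{path}: no observations")
        return FrequencyTable.from_sample(sample)

    if format != "counts_csv":
        raise ValueError("format must be 'counts_csv' or 'raw_sample'")

    body = [(lineno, ln) for lineno, ln in enumerate(lines, start=1) if ln]
    if not body:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(body[0][1])
    if body[0][1].split(delim)[0].strip().lower() in ("value", "length"):
        body = body[1:]
    counts: dict[int, float] = {}
    for lineno, ln in body:
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two fields, got {len(parts)}")
        try:
            value, count = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed row {ln!r}") from None
        if value < 1:
            raise ValueError(f"{path}:{lineno}: outcome values must be >= 1")
        if count < 0:
            raise ValueError(f"{path}:{lineno}: counts must be >= 0")
        if value in counts:
            raise ValueError(f"{path}:{lineno}: duplicate row for value {value}")
        counts[value] = count
    if not counts:
        raise ValueError(f"{path}: no data rows")
    return FrequencyTable.from_counts(counts)


def load_example(name: str) -> FrequencyTable:
    """Load one of the packaged example run-length tables (see EXAMPLE_DATASETS)."""
    if name not in EXAMPLE_DATASETS:
        raise ValueError(f"unknown example {name!r}; choose from {EXAMPLE_DATASETS}")
    with resources.as_file(
        resources.files("geomgof.data.examples") / f"{name}.csv"
    ) as path:
        return read_frequency_table(path, "counts_csv")


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------

def write_report(report: GofReport, format: str = "json") -> str:
    """Serialise a report as full-precision JSON or a 3-decimal text summary."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format != "text":
        raise ValueError("format must be 'json' or 'text'")
    lines = [
        "Geometric goodness-of-fit test",
        f"  n          {report.n:.0f}",
        f"  mean       {report.mean:.3f}",
        f"  theta_hat  {report.theta_hat:.3f}",
        f"  {report.ci_level * 100:.0f}% CI     [{report.ci[0]:.3f}, {report.ci[1]:.3f}]",
    ]
    for tag, res in report.results.items():
        label = _TAGS[tag]
        lines.append(f"  {label:3s}        {res.value:.3f}")
        if res.bracket_text is not None:
            lines.append(f"    bracket  {res.bracket_text}")
        lines.append(f"    p-value  {res.pvalue:.3f}")
        decision = "reject" if res.reject else "do not reject"
        lines.append(f"    decision {decision} at alpha={report.alpha:g}")
    for w in report.warnings:
        lines.append(f"  note: {w}")
    return "\n".join(lines) + "\n"


def read_report_json(text: str) -> GofReport:
    """Inverse of ``write_report(..., 'json')``."""
    d = json.loads(text)
    results = {
        k: StatisticResult(
            statistic=v["statistic"], value=v["value"],
            bracket=tuple(v["bracket"]) if v["bracket"] is not None else None,
            bracket_text=v["bracket_text"], pvalue=v["pvalue"],
            critical_value=v["critical_value"], reject=v["reject"],
        )
        for k, v in d["results"].items()
    }
    return GofReport(
        n=d["n"], mean=d["mean"], theta_hat=d["theta_hat"],
        ci_level=d["ci_level"], ci=tuple(d["ci"]), alpha=d["alpha"],
        results=results, table_source=d["table_source"],
        warnings=tuple(d["warnings"]),
    )
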