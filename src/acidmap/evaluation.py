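"""Error metrics, model-improvement arithmetic, chip grouping and reports.

Metrics follow the per-pH-level convention of chemometric calibration
benchmarks: for each nominal level, the mean absolute error (MAE), the
standard deviation of the absolute errors (SD) and the sum of squared
errors (SSE); the Average row is the unweighted mean over levels, and R^2
is computed once over all test pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AssignmentError
from .io import RamanSpectrum

#: Benchmark per-level test metrics of a deep-learning calibration versus a
#: nonlinear-regression control on a 40-chip SERS pH database (13 levels,
#: pH 5.00-8.00). Used for report layout checks and improvement arithmetic.
REFERENCE_METRICS = pd.DataFrame(
    {
        "ph": [5.00, 5.25, 5.50, 5.75, 6.00, 6.25, 6.50,
               6.75, 7.00, 7.25, 7.50, 7.75, 8.00],
        "mae_dl": [0.26, 0.27, 0.27, 0.23, 0.19, 0.16, 0.11,
                   0.12, 0.15, 0.17, 0.18, 0.18, 0.32],
        "mae_reg": [0.37, 0.28, 0.38, 0.40, 0.33, 0.45, 0.29,
                    0.31, 0.32, 0.25, 0.34, 0.40, 0.63],
        "sd_dl": [0.15, 0.16, 0.14, 0.13, 0.12, 0.10, 0.10,
                  0.09, 0.12, 0.12, 0.12, 0.15, 0.15],
        "sd_reg": [0.33, 0.23, 0.30, 0.30, 0.30, 0.31, 0.24,
                   0.21, 0.22, 0.22, 0.27, 0.36, 0.31],
        "sse_dl": [11.94, 13.18, 12.70, 9.42, 6.86, 4.43, 2.85,
                   2.98, 4.74, 5.59, 5.99, 7.30, 16.11],
        "sse_reg": [32.74, 17.86, 31.52, 33.63, 26.95, 39.40, 18.91,
                    18.31, 20.05, 14.87, 25.36, 38.21, 65.30],
    }
).set_index("ph")

#: Average row of the benchmark table (printed to two decimals there)
REFERENCE_AVERAGES = {"mae_dl": 0.20, "mae_reg": 0.37, "sd_dl": 0.13,
                      "sd_reg": 0.28, "sse_dl": 8.01, "sse_reg": 29.47}


@dataclass
class MetricsTable:
    """Per-level error metrics plus an unweighted averages row and global R^2."""

    table: pd.DataFrame  # index: nominal level; columns: mae, sd, sse, n
    average: pd.Series
    r2: float

    @property
    def levels(self) -> np.ndarray:
        return self.table.index.to_numpy()


def error_table(
    predictions: np.ndarray, labels: np.ndarray, levels: np.ndarray | None = None
) -> MetricsTable:
    """Per-level MAE / SD / SSE and overall R^2.

    ``labels`` are the reference pH values the errors are taken against;
    ``levels`` (defaulting to ``labels``) keys each pair to its nominal
    grid level. Empty levels are simply absent from the table.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    levels = labels if levels is None else np.asarray(levels, dtype=float)
    err = predictions - labels
    frame = pd.DataFrame({"level": levels, "err": err, "abs": np.abs(err)})
    grouped = frame.groupby("level")
    table = pd.DataFrame(
        {
            "mae": grouped["abs"].mean(),
            "sd": grouped["abs"].std(ddof=0),
            "sse": grouped["err"].apply(lambda e: float(np.sum(e**2))),
            "n": grouped.size(),
        }
    )
    # Cauchy-Schwarz: per-level SSE >= (sum |e|)^2 / n = n * MAE^2
    check = table["sse"] + 1e-9 >= table["n"] * table["mae"] ** 2
    assert bool(check.all()), "per-level SSE fell below its Cauchy-Schwarz bound"
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((labels - labels.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    average = table[["mae", "sd", "sse"]].mean()
    average["n"] = table["n"].sum()
    return MetricsTable(table=table, average=average, r2=r2)


def improvement(metric_reference: float, metric_candidate: float) -> float:
    """Relative improvement of a candidate over a reference, in percent."""
    if not metric_reference > 0:
        raise ValueError("reference metric must be positive")
    return 100.0 * (metric_reference - metric_candidate) / metric_reference


@dataclass(frozen=True)
class ChipGroupAssignment:
    chip_id: str | None
    err: float
    group: str


def assign_chip_group(
    spectra_at_650: list[RamanSpectrum],
    calibration: tuple[float, float],
    chip_id: str | None = None,
) -> ChipGroupAssignment:
    """Group a chip by its signed readout error at pH 6.50.

    ``calibration`` is the reference linear ratio calibration (a, b) with
    pH = a*r + b; err is the mean calculated pH over the provided pH-6.50
    acquisitions minus 6.50. Groups: a err > 0.5; b 0.1 < err <= 0.5;
    c -0.1 <= err <= 0.1; d -0.2 < err < -0.1; e err <= -0.2.
    """
    from .baseline import intensity_ratio
    from .simulate import group_from_err

    if not spectra_at_650:
        raise AssignmentError("no pH-6.50 acquisitions supplied")
    a, b = calibration
    preds = [a * intensity_ratio(s) + b for s in spectra_at_650]
    err = float(np.mean(preds)) - 6.50
    return ChipGroupAssignment(chip_id=chip_id, err=err, group=group_from_err(err))


def _quartiles(err: np.ndarray) -> tuple[float, float, float]:
    return tuple(np.percentile(err, [25, 50, 75]))


def report(
    metrics_dl: MetricsTable,
    metrics_reg: MetricsTable,
    path: str | None = None,
    errors_dl: tuple[np.ndarray, np.ndarray] | None = None,
    errors_reg: tuple[np.ndarray, np.ndarray] | None = None,
) -> str:
    """Comparison report: per-level table, improvements, box-plot summaries.

    Both tables must be on the same pH grid. ``errors_*`` optionally supply
    (levels, signed errors) pairs for the per-level quartile block. The
    rendered TSV is deterministic; regeneration from equal inputs is
    byte-identical. Returns the text (and writes it when ``path`` given).
    """
    if not np.array_equal(metrics_dl.levels, metrics_reg.levels):
        raise ValueError("metric tables are on different pH grids")
    lines = ["pH\tMAE_dl\tMAE_reg\tSD_dl\tSD_reg\tSSE_dl\tSSE_reg"]
    for level in metrics_dl.levels:
        d = metrics_dl.table.loc[level]
        r = metrics_reg.table.loc[level]
        lines.append(
            f"{level:.2f}\t{d.mae:.2f}\t{r.mae:.2f}\t{d.sd:.2f}\t{r.sd:.2f}"
            f"\t{d.sse:.2f}\t{r.sse:.2f}"
        )
    ad, ar = metrics_dl.average, metrics_reg.average
    lines.append(
        f"Average\t{ad.mae:.2f}\t{ar.mae:.2f}\t{ad.sd:.2f}\t{ar.sd:.2f}"
        f"\t{ad.sse:.2f}\t{ar.sse:.2f}"
    )
    lines.append("")
    lines.append("improvement_percent\tMAE\tSD\tSSE\tR2")
    imp = [improvement(ar.mae, ad.mae), improvement(ar.sd, ad.sd),
           improvement(ar.sse, ad.sse)]
    if np.isfinite(metrics_reg.r2) and (1.0 - metrics_reg.r2) > 0:
        # improvement in R^2 measured on the unexplained-variance shortfall
        r2_imp = improvement(1.0 - metrics_reg.r2, 1.0 - metrics_dl.r2)
    else:
        r2_imp = float("nan")
    lines.append(
        f"candidate_vs_reference\t{imp[0]:.1f}\t{imp[1]:.1f}\t{imp[2]:.1f}\t{r2_imp:.1f}"
    )
    for tag, pack in (("dl", errors_dl), ("reg", errors_reg)):
        if pack is None:
            continue
        levels, err = np.asarray(pack[0], dtype=float), np.asarray(pack[1], dtype=float)
        lines.append("")
        lines.append(f"boxplot_{tag}\tq1\tmedian\tq3")
        for level in metrics_dl.levels:
            sel = err[levels == level]
            if sel.size == 0:
                continue
            q1, q2, q3 = _quartiles(sel)
            lines.append(f"{level:.2f}\t{q1:.3f}\t{q2:.3f}\t{q3:.3f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
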