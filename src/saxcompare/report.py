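"""Figures and summary tables: Verity plots and correction bar charts.

A Verity plot shows the per-case differences for one clinical parameter as
a violin with jittered points, the bias as a rhombus with its confidence
interval, the variability tolerance interval as vertical lines, the BTR as
a grey band around zero and the VTR as two horizontal lines.  Intervals
are drawn blue when acceptable and red when not.  Points beyond the axis
limit are clamped and marked with an asterisk.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .corrections import CorrectionReport
from .verity import DifferenceSample, ToleranceRanges, VerityResult

PASS_COLOUR = "#1f77b4"  # blue: acceptable
FAIL_COLOUR = "#d62728"  # red: fail


def render_verity(result: VerityResult, sample: DifferenceSample,
                  ranges: ToleranceRanges, path: Path,
                  axis_limit: Optional[float] = None,
                  jitter_seed: int = 0) -> Path:
    """Render one Verity plot to ``path``; returns the path."""
    values = np.asarray(sample.values, float)
    if axis_limit is None:
        axis_limit = 1.1 * max(float(np.max(np.abs(values))) if len(values) else 1.0,
                               ranges.vtr) or 1.0

    fig, ax = plt.subplots(figsize=(3.2, 4.8))
    ax.axhspan(-ranges.btr, ranges.btr, color="0.85", zorder=0, label="BTR")
    for y in (-ranges.vtr, ranges.vtr):
        ax.axhline(y, color="0.3", lw=1.2, ls="--", zorder=1)

    clipped = np.clip(values, -axis_limit, axis_limit)
    outliers = np.abs(values) > axis_limit
    spread = float(np.std(clipped))
    if spread > 0:  # degenerate (point-mass) samples render as points only
        parts = ax.violinplot(clipped, positions=[0.0], widths=0.7,
                              showextrema=False)
        for body in parts["bodies"]:
            body.set_facecolor("0.7")
            body.set_alpha(0.4)
    rng = np.random.default_rng(jitter_seed)
    x = rng.uniform(-0.12, 0.12, size=len(clipped))
    ax.scatter(x[~outliers], clipped[~outliers], s=12, color="0.25", zorder=3)
    if outliers.any():
        ax.scatter(x[outliers], clipped[outliers], s=40, marker="*",
                   color="black", zorder=4,
                   label=f"outlier beyond ±{axis_limit:g} "
                         f"(range {values.min():.1f}..{values.max():.1f})")

    bias_col = PASS_COLOUR if result.bias_ok else FAIL_COLOUR
    var_col = PASS_COLOUR if result.variability_ok else FAIL_COLOUR
    ax.errorbar([0.0], [result.bias],
                yerr=[[result.bias - result.bias_ci[0]],
                      [result.bias_ci[1] - result.bias]],
                fmt="D", color=bias_col, ms=9, capsize=4, zorder=5,
                label=f"bias {result.bias:.2f}")
    for x_off in (-0.28, 0.28):
        ax.vlines(x_off, result.tol_interval[0], result.tol_interval[1],
                  color=var_col, lw=2.5, zorder=5)

    ax.set_xlim(-0.6, 0.6)
    ax.set_ylim(-axis_limit * 1.15, axis_limit * 1.15)
    ax.set_xticks([])
    ax.set_ylabel(f"{sample.parameter} difference ({sample.orientation})")
    ax.set_title(f"{sample.parameter}  n={result.n}\n"
                 f"BTR ±{ranges.btr:g}, VTR ±{ranges.vtr:g}", fontsize=9)
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_corrections(reports: dict[str, CorrectionReport], path: Path) -> Path:
    """Two-panel bar chart: mean contours needing correction per case per
    contour stratum (top) and mean slices needing any correction (bottom),
    one bar group per candidate reader."""
    readers = list(reports)
    strata = list(next(iter(reports.values())).contour_means.index)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(1.2 + 1.2 * len(strata), 6.4))

    width = 0.8 / max(len(readers), 1)
    xs = np.arange(len(strata))
    for i, reader in enumerate(readers):
        means = reports[reader].contour_means.reindex(strata)
        ax1.bar(xs + i * width, means.values, width=width, label=reader)
    ax1.set_xticks(xs + width * (len(readers) - 1) / 2)
    ax1.set_xticklabels(strata, rotation=30, ha="right", fontsize=8)
    ax1.set_ylabel("contours to correct\nper case")
    ax1.legend(fontsize=8)

    ax2.bar(readers, [reports[r].slice_mean for r in readers], color="0.4")
    ax2.set_ylabel("slices to correct\nper case (any contour)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def verity_table(results: Iterable[VerityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
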