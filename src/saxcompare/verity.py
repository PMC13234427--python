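"""Bias/variability acceptability statistics for clinical-parameter differences.

For each clinical parameter the per-case differences between a candidate
reader and the expert are summarised by two intervals:

* a Student-t **confidence interval** for the bias (mean difference),
  covering the true bias with 95% confidence by default, and
* a two-sided normal **tolerance interval** claimed to contain 68% of the
  difference distribution (roughly ±1 SD) with 95% confidence, using
  Howe's k-factor approximation
  ``k = z_{(1+p)/2} · sqrt(ν (1 + 1/n) / χ²_{ν, 1−γ})`` with ν = n − 1.

The candidate is *acceptable* for a parameter when the confidence interval
lies inside a predefined bias tolerance range (BTR) and the tolerance
interval inside a variability tolerance range (VTR); the ranges encode
expected intra-/inter-reader variability and are supplied by the user.
Pearson correlation (on the paired raw values) and a two-sided one-sample
t-test of zero bias are reported alongside, without multiple-comparison
correction — the tests are descriptive, not independent hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


class IntervalUndefinedError(ValueError):
    """Fewer than 3 observations: no interval can be computed."""


@dataclass
class DifferenceSample:
    """Per-case differences for one clinical parameter.

    ``orientation`` records which way the difference was taken
    (``ai-minus-expert`` by default, ``expert-minus-ai`` supported); it is
    fixed per report and stated in every output header.
    """

    parameter: str
    values: np.ndarray
    orientation: str = "ai-minus-expert"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("difference values must be one-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ToleranceRanges:
    """Symmetric acceptability limits (half-widths, parameter units):
    BTR for the bias confidence interval, VTR for the tolerance interval."""

    btr: float
    vtr: float

    def __post_init__(self) -> None:
        if self.btr <= 0 or self.vtr <= 0:
            raise ValueError("BTR and VTR half-widths must be > 0")


@dataclass(frozen=True)
class VerityResult:
    parameter: str
    n: int
    bias: float
    sd: float
    bias_ci: Tuple[float, float]
    tol_interval: Tuple[float, float]
    bias_ok: Optional[bool]
    variability_ok: Optional[bool]
    pearson_r: Optional[float]
    t_p_value: Optional[float]
    orientation: str = "ai-minus-expert"

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n": self.n,
            "orientation": self.orientation,
            "bias": self.bias,
            "sd": self.sd,
            "bias_ci_lo": self.bias_ci[0],
            "bias_ci_hi": self.bias_ci[1],
            "tol_lo": self.tol_interval[0],
            "tol_hi": self.tol_interval[1],
            "bias_ok": self.bias_ok,
            "variability_ok": self.variability_ok,
            "pearson_r": self.pearson_r,
            "t_p_value": self.t_p_value,
        }


def bias_ci(values: Sequence[float], conf: float = 0.95) -> Tuple[float, float]:
    """Student-t confidence interval for the mean difference:
    mean ± t_{(1+conf)/2, n−1} · s/√n."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise IntervalUndefinedError(f"bias CI needs n >= 3, got {n}")
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    half = stats.t.ppf((1 + conf) / 2, n - 1) * se
    return (m - half, m + half)


def howe_k(n: int, content: float = 0.68, conf: float = 0.95) -> float:
    """Two-sided normal tolerance-interval factor, Howe's approximation."""
    if n < 3:
        raise IntervalUndefinedError(f"tolerance factor needs n >= 3, got {n}")
    nu = n - 1
    z = stats.norm.ppf((1 + content) / 2)
    chi2 = stats.chi2.ppf(1 - conf, nu)
    return float(z * np.sqrt(nu * (1 + 1 / n) / chi2))


def tolerance_interval(values: Sequence[float], content: float = 0.68,
                       conf: float = 0.95) -> Tuple[float, float]:
    """Two-sided normal tolerance interval mean ± k(n, content, conf) · s."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise IntervalUndefinedError(f"tolerance interval needs n >= 3, got {n}")
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    half = howe_k(n, content, conf) * s
    return (m - half, m + half)


def _inside(interval: Tuple[float, float], half_width: float) -> bool:
    return -half_width <= interval[0] and interval[1] <= half_width


def verity(sample: DifferenceSample,
           expert_values: Sequence[float],
           ai_values: Sequence[float],
           ranges: ToleranceRanges,
           conf: float = 0.95,
           content: float = 0.68) -> VerityResult:
    """Full acceptability assessment of one parameter for one candidate.

    Verdicts follow the subset rule: bias acceptable iff the confidence
    interval lies inside ±BTR, variability acceptable iff the tolerance
    interval lies inside ±VTR.  Pearson r is computed on the paired raw
    expert/candidate values (not on differences); it is undefined (None)
    when either series has zero variance, as is the t-test p-value when the
    differences are constant at zero spread.
    """
    x = sample.values
    e = np.asarray(expert_values, dtype=float)
    a = np.asarray(ai_values, dtype=float)
    if len(e) != len(a):
        raise ValueError("expert and candidate series must be paired (equal length)")
    ci = bias_ci(x, conf)
    ti = tolerance_interval(x, content, conf)
    sd = float(np.std(x, ddof=1))

    r: Optional[float] = None
    if len(e) >= 3 and np.std(e) > 0 and np.std(a) > 0:
        r = float(stats.pearsonr(e, a).statistic)

    p: Optional[float] = None
    if sd > 0:
        p = float(stats.ttest_1samp(x, 0.0).pvalue)

    return VerityResult(
        parameter=sample.parameter,
        n=sample.n,
        bias=float(np.mean(x)),
        sd=sd,
        bias_ci=ci,
        tol_interval=ti,
        bias_ok=_inside(ci, ranges.btr),
        variability_ok=_inside(ti, ranges.vtr),
        pearson_r=r,
        t_p_value=p,
        orientation=sample.orientation,
    )


def example_tolerance_ranges() -> Dict[str, ToleranceRanges]:
    """Illustrative BTR/VTR table, one entry per clinical parameter.

    These half-widths are synthetic placeholders of plausible magnitude for
    adult CMR (ml for volumes, % for EF, g for mass).  They are NOT derived
    from any reader-variability study; supply your own calibrated table for
    real analyses.
    """
    return {
        "lv_edv": ToleranceRanges(btr=10.0, vtr=25.0),
        "lv_esv": ToleranceRanges(btr=8.0, vtr=20.0),
        "lv_sv": ToleranceRanges(btr=10.0, vtr=25.0),
        "lv_ef": ToleranceRanges(btr=5.0, vtr=12.0),
        "rv_edv": ToleranceRanges(btr=12.0, vtr=30.0),
        "rv_esv": ToleranceRanges(btr=10.0, vtr=25.0),
        "rv_sv": ToleranceRanges(btr=12.0, vtr=30.0),
        "rv_ef": ToleranceRanges(btr=5.0, vtr=12.0),
        "lvm": ToleranceRanges(btr=15.0, vtr=35.0),
    }
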