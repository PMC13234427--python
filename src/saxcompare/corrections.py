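"""Per-contour correction cut-offs and manual-correction counting.

A contour is deemed to need manual correction when its deviation from the
expert exceeds a per-(region, phase) tolerance: an absolute area difference
beyond the area cut-off, a Dice coefficient below the Dice cut-off, or a
slice-decision error (a false-positive or false-negative slice always needs
manual action).  A slice needs correction when *any* of its contours does
(logical OR across regions and phases on that slice).

Cut-offs are calibrated from an interobserver comparison of two human
readers: the area cut-off is ±1.96 standard deviations of the per-slice
interobserver area differences, and the Dice cut-off is the median Dice
minus its median absolute deviation (unscaled MAD, literally
median − MAD).  A shipped default set is provided for short-axis use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CohortComparison
from .segmetrics import METRIC_STRATA, SliceComparison, compare_cohort

StratumKey = Tuple[str, str]  # (region, phase)


class CalibrationSampleError(ValueError):
    """Too few calibration slices in a stratum to derive cut-offs."""


@dataclass(frozen=True)
class Cutoff:
    """Tolerances for one (region, phase): contours within ±area_cutoff cm²
    and with Dice above dice_cutoff pass without correction."""

    area_cutoff: float  # cm², symmetric
    dice_cutoff: float  # fraction in (0, 1)

    def __post_init__(self) -> None:
        if self.area_cutoff <= 0:
            raise ValueError("area_cutoff must be > 0")
        if not (0 < self.dice_cutoff < 1):
            raise ValueError("dice_cutoff must lie in (0, 1)")


CutoffSet = Dict[StratumKey, Cutoff]

#: Shipped short-axis defaults (area cm² / minimum Dice) per stratum.
DEFAULT_CUTOFFS: CutoffSet = {
    ("lv_endo", "ED"): Cutoff(5.6, 0.90),
    ("lv_endo", "ES"): Cutoff(4.0, 0.83),
    ("lv_myo", "ED"): Cutoff(5.0, 0.71),
    ("rv_endo", "ED"): Cutoff(7.4, 0.82),
    ("rv_endo", "ES"): Cutoff(5.5, 0.74),
}

MIN_CALIBRATION_SLICES = 10


@dataclass
class CorrectionReport:
    """Correction burden per case and on cohort average.

    ``per_case`` has one row per case with a contour-correction count per
    (region, phase) column plus ``slices`` (slices where at least one
    contour needs correction).  Cohort means are per-case averages.
    """

    per_case: pd.DataFrame
    contour_means: pd.Series
    slice_mean: float


def unscaled_mad(x: np.ndarray) -> float:
    """Raw median absolute deviation from the median (no consistency factor)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def cutoff_from_samples(area_diffs: Sequence[float], dices: Sequence[float]) -> Cutoff:
    """Cut-offs from per-slice interobserver samples: ±1.96·SD of the area
    differences (cm²) and median(Dice) − MAD(Dice), unscaled MAD.

    Degenerate samples (identical readers) are clamped to the open validity
    ranges rather than rejected.
    """
    diffs = np.asarray(area_diffs, dtype=float)
    dc = np.asarray(dices, dtype=float)
    area_cutoff = 1.96 * float(np.std(diffs, ddof=1))
    dice_cutoff = float(np.median(dc)) - unscaled_mad(dc)
    return Cutoff(max(area_cutoff, 1e-12), min(max(dice_cutoff, 1e-12), 1 - 1e-12))


def derive_cutoffs(calibration: CohortComparison,
                   strata: Sequence[StratumKey] = METRIC_STRATA,
                   min_slices: int = MIN_CALIBRATION_SLICES) -> CutoffSet:
    """Calibrate per-stratum cut-offs from a two-human-reader comparison.

    Per stratum: area cut-off = 1.96 · SD of the per-slice interobserver
    area differences (cm²); Dice cut-off = median(Dice) − MAD(Dice).
    Refuses strata with fewer than ``min_slices`` jointly-contoured slices.
    Identical readers give degenerate cut-offs (0 area, Dice 1), which are
    flagged with a warning rather than silently accepted.
    """
    comparisons = compare_cohort(calibration, strata=strata, with_metrics=True)
    out: CutoffSet = {}
    for region, phase in strata:
        both = [c for c in comparisons
                if c.region == region and c.phase == phase and c.decision == "both_present"]
        if len(both) < min_slices:
            raise CalibrationSampleError(
                f"stratum ({region}, {phase}): {len(both)} calibration slices "
                f"< required {min_slices}"
            )
        diffs = np.array([c.area_diff_abs for c in both], dtype=float)
        dices = np.array([c.dice for c in both], dtype=float)
        cutoff = cutoff_from_samples(diffs, dices)
        if cutoff.area_cutoff <= 1e-12 or cutoff.dice_cutoff >= 1 - 1e-12:
            warnings.warn(
                f"stratum ({region}, {phase}): degenerate calibration "
                f"(identical readers?) — area cut-off {cutoff.area_cutoff}, "
                f"Dice cut-off {cutoff.dice_cutoff}",
                UserWarning,
                stacklevel=2,
            )
        out[(region, phase)] = cutoff
    return out


def contour_needs_correction(c: SliceComparison, cutoff: Cutoff,
                             count_decision_errors: bool = True) -> bool:
    if c.decision in ("false_positive", "false_negative"):
        return count_decision_errors
    if c.decision != "both_present":
        return False
    if c.area_diff_abs is not None and abs(c.area_diff_abs) > cutoff.area_cutoff:
        return True
    return c.dice is not None and c.dice < cutoff.dice_cutoff


def count_corrections(comparisons: Sequence[SliceComparison],
                      cutoffs: CutoffSet = DEFAULT_CUTOFFS,
                      strata: Sequence[StratumKey] = METRIC_STRATA,
                      count_decision_errors: bool = True,
                      case_ids: Optional[Sequence[str]] = None) -> CorrectionReport:
    """Count contours and slices requiring manual correction per case.

    ``comparisons`` are slice comparisons from
    :func:`saxcompare.segmetrics.compare_cohort` (or reconstructed from its
    CSV).  ``case_ids`` fixes the case universe — pass it when some cases
    produced no comparison rows but should still average in as zeros.
    Every stratum present in the data must have a cut-off.
    """
    present = {(c.region, c.phase) for c in comparisons}
    missing = present - set(cutoffs)
    if missing:
        raise KeyError(f"no cut-off for strata: {sorted(missing)}")
    if case_ids is None:
        case_ids = sorted({c.case_id for c in comparisons})

    rows: Dict[str, Dict] = {
        cid: {f"{r}_{p}": 0 for r, p in strata} | {"slices": 0}
        for cid in case_ids
    }
    flagged_slices: Dict[str, set] = {cid: set() for cid in case_ids}
    for c in comparisons:
        if contour_needs_correction(c, cutoffs[(c.region, c.phase)], count_decision_errors):
            rows[c.case_id][f"{c.region}_{c.phase}"] += 1
            flagged_slices[c.case_id].add(c.slice_index)
    for cid, sl in flagged_slices.items():
        rows[cid]["slices"] = len(sl)

    per_case = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_case.index.name = "case_id"
    contour_cols = [col for col in per_case.columns if col != "slices"]
    return CorrectionReport(
        per_case=per_case,
        contour_means=per_case[contour_cols].mean(),
        slice_mean=float(per_case["slices"].mean()),
    )


def count_corrections_cohort(comparison: CohortComparison,
                             cutoffs: CutoffSet = DEFAULT_CUTOFFS,
                             strata: Sequence[StratumKey] = METRIC_STRATA,
                             count_decision_errors: bool = True) -> CorrectionReport:
    """Convenience wrapper: compute slice comparisons then count corrections."""
    comparisons = compare_cohort(comparison, strata=strata, with_metrics=True)
    return count_corrections(comparisons, cutoffs, strata, count_decision_errors,
                             case_ids=comparison.case_ids)


def comparisons_from_frame(df: pd.DataFrame) -> List[SliceComparison]:
    """Rebuild slice comparisons from a slice-metrics CSV frame."""
    out = []
    for rec in df.to_dict("records"):
        out.append(SliceComparison(
            case_id=str(rec["case_id"]),
            slice_index=int(rec["slice_index"]),
            phase=rec["phase"],
            region=rec["region"],
            position=rec["position"],
            stratum=rec["stratum"],
            decision=rec["decision"],
            dice=None if pd.isna(rec.get("dice")) else float(rec["dice"]),
            hd=None if pd.isna(rec.get("hd")) else float(rec["hd"]),
            area_diff_abs=(None if pd.isna(rec.get("area_diff_abs"))
                           else float(rec["area_diff_abs"])),
            area_diff_rel=(None if pd.isna(rec.get("area_diff_rel"))
                           else float(rec["area_diff_rel"])),
        ))
    return out
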