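"""Per-slice contour agreement and slice-decision classification.

Agreement between a candidate ("AI") reader and the expert is assessed two
ways.  Where both readers contoured a slice, overlap metrics are computed:
Dice coefficient on exact polygon areas, Hausdorff distance between
densified boundaries, and absolute/relative area differences.  Where they
disagree about *whether* a slice belongs to the ventricle, the slice is
classified as a false positive or false negative, stratified by cardiac
position.

Positions are defined by the expert's segmented slice range per region and
phase: the expert's most superior segmented slice is basal, the most
inferior apical, everything strictly between midventricular, and slices
outside the range out-of-scope.  Candidate contours above the expert's
basal slice are basal false positives; missing the expert's basal slice is
a basal false negative; symmetric rules apply apically; a missed in-range
slice is a midventricular false negative.  If the expert segmented a single
slice it is basal and apical at once; basal takes precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (CaseAnnotationSet, CohortComparison, densify_ring,
                   geometry_boundary_points)

logger = logging.getLogger(__name__)

POSITIONS = ("basal", "midventricular", "apical", "out_of_scope")
DECISIONS = ("both_present", "false_positive", "false_negative", "both_absent")

#: (region, phase) strata evaluated in reports: LV endo at both phases,
#: the myocardial annulus at ED only, RV endo at both phases.
METRIC_STRATA = (
    ("lv_endo", "ED"), ("lv_endo", "ES"),
    ("lv_myo", "ED"),
    ("rv_endo", "ED"), ("rv_endo", "ES"),
)

DEFAULT_MAX_ARC_MM = 0.1


def dice(a, b) -> Optional[float]:
    """Dice coefficient 2·|A∩B| / (|A|+|B|) on shapely geometries (mm²).

    Undefined (None) when both regions are empty — never 0/0.
    """
    area_a, area_b = a.area, b.area
    if area_a + area_b == 0:
        return None
    return 2.0 * a.intersection(b).area / (area_a + area_b)


def _directed_hausdorff(p: np.ndarray, q: np.ndarray, tree_q: cKDTree) -> float:
    d, _ = tree_q.query(p, k=1)
    return float(np.max(d))


def hausdorff_points(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (mm)."""
    if len(p) == 0 or len(q) == 0:
        raise ValueError("hausdorff requires non-empty boundaries")
    tp, tq = cKDTree(p), cKDTree(q)
    return max(_directed_hausdorff(p, q, tq), _directed_hausdorff(q, p, tp))


def hausdorff(a, b, max_arc: float = DEFAULT_MAX_ARC_MM) -> float:
    """Hausdorff distance between the boundaries of two geometries (mm),
    sampled so consecutive boundary points are at most ``max_arc`` apart."""
    return hausdorff_points(
        geometry_boundary_points(a, max_arc), geometry_boundary_points(b, max_arc)
    )


def area_differences(area_expert_mm2: Optional[float], area_ai_mm2: Optional[float]
                     ) -> Tuple[float, Optional[float]]:
    """(absolute cm², relative % or None) area difference, AI minus expert.

    An absent side contributes zero area, so a lone AI contour counts fully
    positive and a lone expert contour fully negative; the relative
    difference is undefined when the expert is absent.
    """
    if area_expert_mm2 is None and area_ai_mm2 is None:
        raise ValueError("area_differences: both sides absent")
    e = area_expert_mm2 or 0.0
    a = area_ai_mm2 or 0.0
    abs_cm2 = (a - e) / 100.0
    rel = None if area_expert_mm2 is None else 100.0 * (a - e) / e
    return abs_cm2, rel


@dataclass
class SliceComparison:
    """Agreement record for one slice/phase/region of one case.

    ``position`` follows the expert's slice range; ``stratum`` is the
    position the decision counts toward in rate tables (an out-of-scope
    false positive above the base counts as basal, below the apex as
    apical).  ``dice``/``hd`` are present iff both readers contoured the
    slice; ``area_diff_*`` whenever at least one did.
    """

    case_id: str
    slice_index: int
    phase: str
    region: str
    position: str
    stratum: str
    decision: str
    dice: Optional[float] = None
    hd: Optional[float] = None
    area_diff_abs: Optional[float] = None  # cm², AI − expert
    area_diff_rel: Optional[float] = None  # %

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "slice_index": self.slice_index,
            "phase": self.phase,
            "region": self.region,
            "position": self.position,
            "stratum": self.stratum,
            "decision": self.decision,
            "dice": self.dice,
            "hd": self.hd,
            "area_diff_abs": self.area_diff_abs,
            "area_diff_rel": self.area_diff_rel,
        }


def _myo_hd(expert: CaseAnnotationSet, ai: CaseAnnotationSet, si: int,
            max_arc: float) -> float:
    # Annulus HD = max over the epicardial and endocardial surfaces, each
    # compared like-for-like, so either surface drifting is penalised.
    hds = []
    ps = expert.slice_geometry(si).pixel_spacing
    for ctype in ("lv_epi", "lv_endo"):
        e_cs = expert.get(si, "ED", ctype)
        a_cs = ai.get(si, "ED", ctype)
        if not e_cs or not a_cs:
            continue
        e_pts = np.concatenate([densify_ring(c.outer_ring * ps, max_arc) for c in e_cs])
        a_pts = np.concatenate([densify_ring(c.outer_ring * ps, max_arc) for c in a_cs])
        hds.append(hausdorff_points(e_pts, a_pts))
    if not hds:
        raise ValueError("annulus HD requires at least one shared surface")
    return max(hds)


def classify_slices(expert: CaseAnnotationSet, ai: CaseAnnotationSet,
                    region: str, phase: str,
                    with_metrics: bool = True,
                    max_arc: float = DEFAULT_MAX_ARC_MM) -> List[SliceComparison]:
    """Classify every relevant slice of one case for one region/phase.

    Emits one record per slice the expert segmented (decision both_present
    or false_negative) and one per out-of-range slice the candidate
    segmented (false_positive).  Returns an empty list — with a logged
    reason — when the expert segmented no slice for this region/phase, in
    which case the case is excluded from the stratum.
    """
    e_slices = expert.segmented_slices(region, phase)
    if not e_slices:
        logger.info("case %s: expert segmented no %s %s slices; excluded from stratum",
                    expert.case_id, region, phase)
        return []
    e_min, e_max = e_slices[0], e_slices[-1]
    a_slices = set(ai.segmented_slices(region, phase))
    out: List[SliceComparison] = []

    def position_of(si: int) -> Tuple[str, str]:
        if si < e_min:
            return "out_of_scope", "basal"
        if si > e_max:
            return "out_of_scope", "apical"
        if si == e_min:  # basal takes precedence on a single-slice range
            return "basal", "basal"
        if si == e_max:
            return "apical", "apical"
        return "midventricular", "midventricular"

    for si in sorted(set(expert.slice_indices) | a_slices):
        e_has = expert.has_region(si, phase, region)
        a_has = si in a_slices
        if not e_has and not a_has:
            continue
        position, stratum = position_of(si)
        if e_has and a_has:
            decision = "both_present"
        elif e_has:
            decision = "false_negative"
        else:
            decision = "false_positive"
        rec = SliceComparison(expert.case_id, si, phase, region, position, stratum, decision)
        e_area = expert.region_area_mm2(si, phase, region) if e_has else None
        a_area = ai.region_area_mm2(si, phase, region) if a_has else None
        rec.area_diff_abs, rec.area_diff_rel = area_differences(e_area, a_area)
        if decision == "both_present" and with_metrics:
            eg = expert.region_geometry(si, phase, region)
            ag = ai.region_geometry(si, phase, region)
            rec.dice = dice(eg, ag)
            if region == "lv_myo":
                rec.hd = _myo_hd(expert, ai, si, max_arc)
            else:
                rec.hd = hausdorff(eg, ag, max_arc)
        out.append(rec)
    return out


def compare_cohort(cohort: CohortComparison,
                   strata: Sequence[Tuple[str, str]] = METRIC_STRATA,
                   with_metrics: bool = True,
                   max_arc: float = DEFAULT_MAX_ARC_MM) -> List[SliceComparison]:
    """All slice comparisons for a paired cohort across the report strata."""
    out: List[SliceComparison] = []
    for cid in cohort.case_ids:
        e, a = cohort.pairs[cid]
        for region, phase in strata:
            out.extend(classify_slices(e, a, region, phase, with_metrics, max_arc))
    return out


def comparisons_frame(comparisons: Iterable[SliceComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.as_dict() for c in comparisons])


def decision_rates(comparisons: Sequence[SliceComparison]) -> Dict[str, Dict[str, Optional[float]]]:
    """False-positive / false-negative slice rates (%) per position stratum.

    Basal and apical rates use one labelled slice per case as the unit: the
    FN rate is the fraction of cases whose labelled slice the candidate
    missed, and the FP rate counts extra out-of-range slices per case (so
    it can exceed 100% in pathological inputs).  The midventricular FN rate
    is missed in-range slices over in-range slice opportunities.  Empty
    denominators yield None, never zero.
    """
    if not comparisons:
        return {}
    df = comparisons_frame(comparisons)
    n_cases = df["case_id"].nunique()
    rates: Dict[str, Dict[str, Optional[float]]] = {}
    for stratum in ("basal", "midventricular", "apical"):
        sub = df[df["stratum"] == stratum]
        fp = int((sub["decision"] == "false_positive").sum())
        fn = int((sub["decision"] == "false_negative").sum())
        if stratum == "midventricular":
            denom = int(sub["decision"].isin(["both_present", "false_negative"]).sum())
        else:
            denom = n_cases
        rates[stratum] = {
            "fp_rate": 100.0 * fp / n_cases if n_cases else None,
            "fn_rate": 100.0 * fn / denom if denom else None,
        }
    return rates


def stratum_summary(comparisons: Sequence[SliceComparison],
                    per_case_first: bool = False) -> pd.DataFrame:
    """Mean Dice (%), HD (mm) and area differences per position × region ×
    phase, in the layout of a position-sorted agreement table.

    By default means are taken directly over slices; with
    ``per_case_first`` slices are averaged within each case before the
    cohort mean (the two orders differ when cases contribute unequal slice
    counts).
    """
    df = comparisons_frame(comparisons)
    if df.empty:
        return pd.DataFrame()
    rows = []
    for (region, phase), sub_rp in df.groupby(["region", "phase"], sort=False):
        rates_all = decision_rates([c for c in comparisons
                                    if c.region == region and c.phase == phase])
        for position in ("basal", "midventricular", "apical"):
            sub = sub_rp[sub_rp["position"] == position]
            present = sub[sub["decision"] == "both_present"]
            if per_case_first and not present.empty:
                per_case = present.groupby("case_id")[["dice", "hd", "area_diff_abs",
                                                       "area_diff_rel"]].mean()
                means = per_case.mean()
            else:
                means = present[["dice", "hd", "area_diff_abs", "area_diff_rel"]].mean()
            r = rates_all.get(position, {})
            rows.append({
                "region": region,
                "phase": phase,
                "position": position,
                "n_slices": len(sub),
                "dice_pct": 100.0 * means.get("dice") if present["dice"].notna().any() else None,
                "hd_mm": means.get("hd") if present["hd"].notna().any() else None,
                "area_diff_abs_cm2": means.get("area_diff_abs"),
                "area_diff_rel_pct": means.get("area_diff_rel"),
                "fp_rate_pct": r.get("fp_rate"),
                "fn_rate_pct": r.get("fn_rate"),
            })
    return pd.DataFrame(rows)
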