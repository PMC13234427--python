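"""Ventricular volumes, function and mass by short-axis slice summation.

Volumes follow the slice-summation (Simpson) method standard in CMR
post-processing: each segmented slice contributes its contour-enclosed
area times the slab thickness (slice thickness + inter-slice gap).  LV
myocardial mass is myocardial volume times tissue density, 1.05 g/ml by
convention, at end-diastole only.

Papillary-muscle handling is explicit: under ``PmMode.INCLUDED`` the
papillary blobs (clipped to the endocardial cavity) are removed from the
LV blood pool and added to myocardial mass; under ``PmMode.EXCLUDED`` they
are ignored entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import CaseAnnotationSet

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

PARAMETER_NAMES = (
    "lv_edv", "lv_esv", "lv_sv", "lv_ef",
    "rv_edv", "rv_esv", "rv_sv", "rv_ef",
    "lvm",
)


class PmMode(str, Enum):
    EXCLUDED = "excluded"
    INCLUDED = "included"


class MissingEndoWarning(UserWarning):
    """A slice had an epicardial contour but no endocardial one; the full
    epicardial area was counted as myocardium."""


@dataclass(frozen=True)
class ClinicalParams:
    """LV/RV volumes (ml), ejection fractions (%) and LV mass (g) for one
    case, reader and papillary-muscle mode.  ``ef`` fields are None when the
    corresponding EDV is zero (undefined, recorded as missing)."""

    case_id: str
    reader_id: str
    pm_mode: PmMode
    lv_edv: float
    lv_esv: float
    lv_sv: float
    lv_ef: Optional[float]
    rv_edv: float
    rv_esv: float
    rv_sv: float
    rv_ef: Optional[float]
    lvm: float

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "reader_id": self.reader_id,
            "pm_mode": self.pm_mode.value,
            **{p: getattr(self, p) for p in PARAMETER_NAMES},
        }


def chamber_volume(ann: CaseAnnotationSet, contour_type: str, phase: str,
                   pm_mode: PmMode = PmMode.EXCLUDED) -> float:
    """Blood-pool volume (ml) of one chamber at one phase by slice summation.

    Slices without a contour contribute nothing — a missing slice is a
    legitimate reader decision, captured by the decision metrics rather
    than treated as an error here.
    """
    if contour_type not in ("lv_endo", "rv_endo"):
        raise ValueError(f"chamber_volume expects lv_endo or rv_endo, got {contour_type!r}")
    pm_adjust = contour_type == "lv_endo" and pm_mode is PmMode.INCLUDED
    total_mm3 = 0.0
    for geom in ann.slices:
        area = ann.region_area_mm2(geom.slice_index, phase, contour_type,
                                   pm_as_myocardium=pm_adjust)
        total_mm3 += area * geom.slab_thickness
    return total_mm3 / 1000.0


def lv_mass(ann: CaseAnnotationSet, pm_mode: PmMode = PmMode.EXCLUDED,
            density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> float:
    """LV myocardial mass (g) at end-diastole.

    Myocardial volume sums the annulus (epicardium minus endocardium, plus
    intracavitary papillary muscle when included) over slices.  A slice with
    an epicardial but no endocardial contour contributes its full epicardial
    area and emits a :class:`MissingEndoWarning`.
    """
    pm_adjust = pm_mode is PmMode.INCLUDED
    total_mm3 = 0.0
    for geom in ann.slices:
        si = geom.slice_index
        if not ann.has_region(si, "ED", "lv_myo"):
            continue
        if not ann.get(si, "ED", "lv_endo"):
            warnings.warn(
                f"case {ann.case_id} slice {si}: lv_epi without lv_endo; "
                "counting full epicardial area as myocardium",
                MissingEndoWarning,
                stacklevel=2,
            )
        area = ann.region_area_mm2(si, "ED", "lv_myo", pm_as_myocardium=pm_adjust)
        total_mm3 += area * geom.slab_thickness
    return total_mm3 / 1000.0 * density


def _ef(edv: float, esv: float) -> Optional[float]:
    if edv <= 0:
        return None
    return 100.0 * (edv - esv) / edv


def derive_params(ann: CaseAnnotationSet, pm_mode: PmMode = PmMode.EXCLUDED,
                  density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> ClinicalParams:
    """All clinical parameters for one annotation set.

    SV = EDV − ESV and EF = 100·SV/EDV per ventricle; EDV ≥ ESV is *not*
    enforced — readers can disagree and the value is recorded as-is.
    """
    lv_edv = chamber_volume(ann, "lv_endo", "ED", pm_mode)
    lv_esv = chamber_volume(ann, "lv_endo", "ES", pm_mode)
    rv_edv = chamber_volume(ann, "rv_endo", "ED", pm_mode)
    rv_esv = chamber_volume(ann, "rv_endo", "ES", pm_mode)
    return ClinicalParams(
        case_id=ann.case_id,
        reader_id=ann.reader_id,
        pm_mode=pm_mode,
        lv_edv=lv_edv,
        lv_esv=lv_esv,
        lv_sv=lv_edv - lv_esv,
        lv_ef=_ef(lv_edv, lv_esv),
        rv_edv=rv_edv,
        rv_esv=rv_esv,
        rv_sv=rv_edv - rv_esv,
        rv_ef=_ef(rv_edv, rv_esv),
        lvm=lv_mass(ann, pm_mode, density),
    )
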