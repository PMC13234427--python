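"""Phantom short-axis cohorts with analytic ground truth.

Each phantom case is a stack of parallel slices carrying near-circular LV
endo/epi rings that taper linearly toward the apex, a crescent-shaped RV
built as the difference of two offset discs, and optional papillary-muscle
blobs inside the LV cavity.  End-systole shrinks all in-plane radii by a
per-case fraction, so ejection fraction has a closed form
``EF = 100·(1 − s²)`` for ES scale s.

The "expert" annotation is the noiseless truth; "AI-like" candidate
readers are derived from it by a :class:`PerturbationProfile`: a smooth
radial displacement field (systematic bias plus correlated Gaussian noise
with exact per-vertex marginal N(0, sd²)), plus slice-decision errors —
extra contoured slices above the base / below the apex (false positives)
and omitted basal/apical/midventricular slices (false negatives) — and
optional papillary-muscle omission.

Anatomy and perturbation use independent seed streams, so one cohort can
be re-perturbed reproducibly under several profiles.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .clinical import MYOCARDIAL_DENSITY_G_PER_ML
from .core import (CaseAnnotationSet, CohortComparison, Contour,
                   ContourValidationError, SliceGeometry)

EXPERT_READER_ID = "expert"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of a phantom cohort.

    Distances in mm.  The stack has ``slices_per_case`` acquired slices;
    the expert segments all but the outermost two (one unsegmented slice
    above the base and one below the apex leave room for over-inclusion
    errors).  ``apical_taper`` shrinks radii linearly per segmented slice;
    ``ed_es_scale`` is the ES/ED in-plane radius ratio.  Per-case anatomy
    is jittered (overall scale, wall thickness, ES scale) so the cohort
    has realistic between-case spread; all draws are deterministic in
    ``seed``.
    """

    n_cases: int = 20
    slices_per_case: int = 12
    lv_endo_base_radius: float = 27.0
    apical_taper: float = 0.05
    wall_thickness: float = 8.0
    rv_crescent_params: Tuple[float, float] = (35.0, 28.0)  # outer radius, centre offset
    pm: Optional[Tuple[int, float]] = (2, 4.0)  # (blob count, radius mm)
    pixel_spacing: float = 1.79
    slice_thickness: float = 7.08
    slice_gap: float = 0.0
    ed_es_scale: float = 0.63
    seed: int = 0
    n_vertices: int = 360
    case_scale_sd: float = 0.08
    wall_scale_sd: float = 0.05
    es_scale_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.slices_per_case < 4:
            raise ValueError("need n_cases >= 1 and slices_per_case >= 4")
        if min(self.lv_endo_base_radius, self.wall_thickness,
               self.pixel_spacing, self.slice_thickness) <= 0:
            raise ValueError("radii, wall, spacing and thickness must be > 0")
        if not (0 <= self.apical_taper <= 1):
            raise ValueError("apical_taper must lie in [0, 1]")
        if not (0 < self.ed_es_scale < 1):
            raise ValueError("ed_es_scale must lie in (0, 1)")
        n_seg = self.slices_per_case - 2
        if self.apical_taper * (n_seg - 1) >= 1:
            raise ValueError("apical_taper too steep: apical radius would vanish")
        if self.pm is not None and self.pm[1] > 0.5 * self.lv_endo_base_radius:
            raise ValueError("papillary blob radius must stay inside the cavity")


@dataclass(frozen=True)
class PerturbationProfile:
    """AI-like deviation profile applied to expert contours.

    ``radial_bias`` dilates (+) or erodes (−) every contour by that many mm
    on average; ``radial_noise_sd`` adds a smooth, zero-mean radial field
    whose per-vertex marginal is N(0, sd²).  The slice-decision
    probabilities draw independently per case, structure group (LV vs RV)
    and phase.  ``segments_pm=False`` drops papillary contours entirely.
    """

    reader_id: str = "ai"
    radial_noise_sd: float = 0.0
    radial_bias: float = 0.0
    p_basal_fp: float = 0.0
    p_basal_fn: float = 0.0
    p_apical_fp: float = 0.0
    p_apical_fn: float = 0.0
    p_midv_fn: float = 0.0
    segments_pm: bool = True
    seed: int = 0
    harmonics: int = 8

    def __post_init__(self) -> None:
        for name in ("p_basal_fp", "p_basal_fn", "p_apical_fp", "p_apical_fn", "p_midv_fn"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.radial_noise_sd < 0:
            raise ValueError("radial_noise_sd must be >= 0")


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    cases: List[CaseAnnotationSet]
    truth: pd.DataFrame  # indexed by case_id, closed-form parameters


# ---------------------------------------------------------------------------
# geometry helpers

_CENTRE_PX = (96.0, 96.0)


def _circle_ring(cx: float, cy: float, r_px: float, n: int) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r_px * np.cos(th), cy + r_px * np.sin(th)])


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two discs with centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * math.sqrt((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    return a1 + a2 - tri


def crescent_area(rv_radius: float, offset: float, epi_radius: float) -> float:
    """Closed-form area (mm²) of the RV crescent: the RV disc minus its
    overlap with the epicardial disc."""
    return math.pi * rv_radius**2 - _lens_area(offset, rv_radius, epi_radius)


def _rv_contour(phase: str, rv_r_mm: float, offset_mm: float, epi_r_mm: float,
                ps: float, n: int) -> Contour:
    cx, cy = _CENTRE_PX
    rv = Polygon(_circle_ring(cx - offset_mm / ps, cy, rv_r_mm / ps, n))
    epi = Polygon(_circle_ring(cx, cy, epi_r_mm / ps, n))
    crescent = rv.difference(epi)
    if crescent.geom_type != "Polygon" or crescent.is_empty:
        raise ValueError("RV crescent parameters do not yield a single region")
    ring = np.asarray(crescent.exterior.coords)[:-1]
    return Contour("rv_endo", phase, ring)


# ---------------------------------------------------------------------------
# expert generation

def _case_anatomy(spec: PhantomSpec, case_index: int) -> Dict[str, float]:
    rng = np.random.default_rng([spec.seed, case_index])
    scale = float(np.clip(1 + spec.case_scale_sd * rng.standard_normal(), 0.7, 1.35))
    wall = spec.wall_thickness * float(
        np.clip(1 + spec.wall_scale_sd * rng.standard_normal(), 0.75, 1.25))
    es = float(np.clip(spec.ed_es_scale + spec.es_scale_sd * rng.standard_normal(),
                       0.40, 0.88))
    return {"scale": scale, "wall": wall, "es_scale": es}


def generate_case(spec: PhantomSpec, case_index: int) -> Tuple[CaseAnnotationSet, Dict[str, float]]:
    """One phantom case plus its closed-form truth parameters."""
    anat = _case_anatomy(spec, case_index)
    scale, wall, es = anat["scale"], anat["wall"], anat["es_scale"]
    ps, n = spec.pixel_spacing, spec.n_vertices
    cx, cy = _CENTRE_PX
    slab = spec.slice_thickness + spec.slice_gap
    rv_r0, rv_d0 = spec.rv_crescent_params

    slices = [SliceGeometry(i, ps, spec.slice_thickness, spec.slice_gap)
              for i in range(spec.slices_per_case)]
    contours: Dict[Tuple[int, str, str], List[Contour]] = {}
    n_seg = spec.slices_per_case - 2

    lv_area_ed = lv_area_es = myo_area = 0.0
    rv_area_ed = rv_area_es = 0.0
    pm_area_ed = pm_area_es = 0.0

    for k in range(n_seg):
        si = k + 1
        f = 1 - spec.apical_taper * k
        r_ed = spec.lv_endo_base_radius * scale * f
        epi_ed = r_ed + wall
        rv_r, rv_d = rv_r0 * scale * f, rv_d0 * scale * f

        for phase, ph_scale in (("ED", 1.0), ("ES", es)):
            r = r_ed * ph_scale
            contours[(si, phase, "lv_endo")] = [
                Contour("lv_endo", phase, _circle_ring(cx, cy, r / ps, n))]
            if phase == "ED":
                contours[(si, "ED", "lv_epi")] = [
                    Contour("lv_epi", "ED", _circle_ring(cx, cy, epi_ed / ps, n))]
            # ES shrinks the whole RV construct (disc, offset and carving
            # epicardial disc) by the phase scale, so ES geometry is similar
            # to ED and RV EF shares the closed form 100·(1 − s²).
            epi_carve = epi_ed * ph_scale
            contours[(si, phase, "rv_endo")] = [
                _rv_contour(phase, rv_r * ph_scale, rv_d * ph_scale, epi_carve, ps, n)]
            if spec.pm is not None:
                count, pm_r0 = spec.pm
                pm_r = pm_r0 * scale * f * ph_scale
                blobs = []
                for j in range(count):
                    ang = math.pi / 2 + j * 2 * math.pi / count
                    bx = cx + 0.5 * r / ps * math.cos(ang)
                    by = cy + 0.5 * r / ps * math.sin(ang)
                    blobs.append(Contour("pm", phase, _circle_ring(bx, by, pm_r / ps, n)))
                contours[(si, phase, "pm")] = blobs
                if phase == "ED":
                    pm_area_ed += count * math.pi * pm_r**2
                else:
                    pm_area_es += count * math.pi * pm_r**2
            if phase == "ED":
                lv_area_ed += math.pi * r**2
                myo_area += math.pi * (epi_ed**2 - r**2)
                rv_area_ed += crescent_area(rv_r, rv_d, epi_carve)
            else:
                lv_area_es += math.pi * r**2
                rv_area_es += crescent_area(rv_r * es, rv_d * es, epi_carve)

    def ml(area_mm2: float) -> float:
        return area_mm2 * slab / 1000.0

    truth = {
        "lv_edv": ml(lv_area_ed), "lv_esv": ml(lv_area_es),
        "rv_edv": ml(rv_area_ed), "rv_esv": ml(rv_area_es),
        "lvm": ml(myo_area) * MYOCARDIAL_DENSITY_G_PER_ML,
        "pm_ed_ml": ml(pm_area_ed), "pm_es_ml": ml(pm_area_es),
        "es_scale": es,
    }
    truth["lv_sv"] = truth["lv_edv"] - truth["lv_esv"]
    truth["lv_ef"] = 100.0 * truth["lv_sv"] / truth["lv_edv"]
    truth["rv_sv"] = truth["rv_edv"] - truth["rv_esv"]
    truth["rv_ef"] = 100.0 * truth["rv_sv"] / truth["rv_edv"]
    truth["lv_edv_pm_included"] = truth["lv_edv"] - truth["pm_ed_ml"]
    truth["lv_esv_pm_included"] = truth["lv_esv"] - truth["pm_es_ml"]
    truth["lvm_pm_included"] = truth["lvm"] + MYOCARDIAL_DENSITY_G_PER_ML * truth["pm_ed_ml"]

    ann = CaseAnnotationSet(
        case_id=f"case_{case_index:04d}",
        reader_id=EXPERT_READER_ID,
        slices=slices,
        contours=contours,
    )
    return ann, truth


def generate_expert(spec: PhantomSpec) -> PhantomCohort:
    """Deterministic phantom cohort with expert annotations and truth table."""
    cases, rows = [], []
    for i in range(spec.n_cases):
        ann, truth = generate_case(spec, i)
        cases.append(ann)
        rows.append({"case_id": ann.case_id, **truth})
    truth_df = pd.DataFrame(rows).set_index("case_id")
    return PhantomCohort(spec=spec, cases=cases, truth=truth_df)


# ---------------------------------------------------------------------------
# perturbation

def _smooth_radial_field(theta: np.ndarray, bias: float, sd: float,
                         rng: np.random.Generator, harmonics: int) -> np.ndarray:
    """Radial displacement (mm) at each vertex angle: systematic bias plus a
    band-limited Gaussian field with exact marginal N(0, sd²)."""
    delta = np.full_like(theta, bias)
    if sd > 0:
        amp = sd / math.sqrt(harmonics)
        for k in range(1, harmonics + 1):
            a, b = rng.standard_normal(2)
            delta = delta + amp * (a * np.cos(k * theta) + b * np.sin(k * theta))
    return delta


def _perturb_contour(c: Contour, bias: float, sd: float, ps: float,
                     rng: np.random.Generator, harmonics: int) -> Contour:
    if bias == 0.0 and sd == 0.0:
        return Contour(c.contour_type, c.phase, c.outer_ring.copy())
    ring = c.outer_ring
    centre = ring.mean(axis=0)
    vec = ring - centre
    rho = np.hypot(vec[:, 0], vec[:, 1])
    theta = np.arctan2(vec[:, 1], vec[:, 0])
    for _ in range(5):
        delta = _smooth_radial_field(theta, bias, sd, rng, harmonics)
        new_rho = np.maximum(rho + delta / ps, 0.05 * rho)
        new_ring = centre + (vec / rho[:, None]) * new_rho[:, None]
        try:
            return Contour(c.contour_type, c.phase, new_ring)
        except ContourValidationError:
            continue  # re-draw the noise field; heavy noise can fold the ring
    raise ContourValidationError(
        f"could not produce a simple perturbed {c.contour_type} ring after 5 draws")


_GROUPS = {"lv": ("lv_endo", "lv_epi", "pm"), "rv": ("rv_endo",)}


def perturb(expert: CaseAnnotationSet, profile: PerturbationProfile,
            rng: Optional[np.random.Generator] = None) -> CaseAnnotationSet:
    """AI-like annotation of one case derived from the expert's.

    Deterministic given the profile seed and the case id.  Slice-decision
    draws are independent per structure group (LV contours move together,
    RV separately) and phase; added false-positive slices reuse the
    neighbouring expert contour, perturbed like any other.
    """
    if rng is None:
        rng = np.random.default_rng([profile.seed, zlib.crc32(expert.case_id.encode())])

    keep: Dict[Tuple[int, str, str], bool] = {}
    add_fp: List[Tuple[int, str, str, int]] = []  # (new_si, phase, ctype, source_si)
    all_indices = set(expert.slice_indices)

    for group, ctypes in _GROUPS.items():
        ref_region = "lv_endo" if group == "lv" else "rv_endo"
        for phase in ("ED", "ES"):
            segmented = expert.segmented_slices(ref_region, phase)
            if not segmented:
                continue
            e_min, e_max = segmented[0], segmented[-1]
            basal_fp = rng.random() < profile.p_basal_fp and (e_min - 1) in all_indices
            basal_fn = rng.random() < profile.p_basal_fn
            apical_fp = rng.random() < profile.p_apical_fp and (e_max + 1) in all_indices
            apical_fn = rng.random() < profile.p_apical_fn
            for si in segmented:
                drop = (
                    (si == e_min and basal_fn)
                    or (si == e_max and si != e_min and apical_fn)
                    or (e_min < si < e_max and rng.random() < profile.p_midv_fn)
                )
                for ctype in ctypes:
                    keep[(si, phase, ctype)] = not drop
            if basal_fp:
                for ctype in ctypes:
                    add_fp.append((e_min - 1, phase, ctype, e_min))
            if apical_fp:
                for ctype in ctypes:
                    add_fp.append((e_max + 1, phase, ctype, e_max))

    bias, sd = profile.radial_bias, profile.radial_noise_sd
    contours: Dict[Tuple[int, str, str], List[Contour]] = {}

    def emit(target_si: int, phase: str, ctype: str, source: List[Contour]) -> None:
        if ctype == "pm" and not profile.segments_pm:
            return
        ps = expert.slice_geometry(target_si).pixel_spacing
        contours[(target_si, phase, ctype)] = [
            _perturb_contour(c, bias, sd, ps, rng, profile.harmonics) for c in source]

    for (si, phase, ctype), lst in expert.contours.items():
        if keep.get((si, phase, ctype), True):
            emit(si, phase, ctype, lst)
    for new_si, phase, ctype, source_si in add_fp:
        src = expert.get(source_si, phase, ctype)
        if src:
            emit(new_si, phase, ctype, src)

    return CaseAnnotationSet(
        case_id=expert.case_id,
        reader_id=profile.reader_id,
        slices=list(expert.slices),
        contours=contours,
    )


def perturb_cohort(cohort: PhantomCohort, profile: PerturbationProfile
                   ) -> List[CaseAnnotationSet]:
    return [perturb(case, profile) for case in cohort.cases]


def pair_cohort(expert_cases: Sequence[CaseAnnotationSet],
                candidate_cases: Sequence[CaseAnnotationSet]) -> CohortComparison:
    """Pair expert and candidate annotations into a CohortComparison."""
    cand = {c.case_id: c for c in candidate_cases}
    pairs = {e.case_id: (e, cand[e.case_id]) for e in expert_cases if e.case_id in cand}
    expert_id = expert_cases[0].reader_id if expert_cases else EXPERT_READER_ID
    cand_id = candidate_cases[0].reader_id if candidate_cases else "ai"
    return CohortComparison(expert=expert_id, candidate=cand_id, pairs=pairs)


# ---------------------------------------------------------------------------
# presets

def phantom_preset(name: str, n_cases: int = 20, seed: int = 0) -> PhantomSpec:
    """Disease-subgroup presets: ``normal``, ``dilated`` (larger cavity,
    weaker contraction), ``hypertrophic`` (thick wall, prominent papillary
    muscles, small cavity)."""
    base = PhantomSpec(n_cases=n_cases, seed=seed)
    if name == "normal":
        return base
    if name == "dilated":
        return replace(base, lv_endo_base_radius=34.0, wall_thickness=7.0,
                       apical_taper=0.04, ed_es_scale=0.80,
                       rv_crescent_params=(38.0, 32.0))
    if name == "hypertrophic":
        return replace(base, lv_endo_base_radius=24.0, wall_thickness=13.0,
                       pm=(2, 5.0), ed_es_scale=0.58)
    raise ValueError(f"unknown phantom preset {name!r}; "
                     "expected normal, dilated or hypertrophic")


def builtin_profiles(seed: int = 0) -> Dict[str, PerturbationProfile]:
    """Named AI-behaviour profiles.

    ``identity`` reproduces the expert exactly; ``inclusion_prone`` over-
    includes basally (extra superior slices, mild dilation);
    ``truncation_prone`` omits basal/apical slices and erodes slightly;
    ``no_pm`` behaves like ``inclusion_prone`` but never contours papillary
    muscles; ``reader2`` emulates a careful second human reader for
    cut-off calibration.
    """
    return {
        "identity": PerturbationProfile(reader_id="identity", seed=seed),
        "inclusion_prone": PerturbationProfile(
            reader_id="inclusion_prone", radial_noise_sd=0.8, radial_bias=0.5,
            p_basal_fp=0.25, p_basal_fn=0.03, p_apical_fp=0.04, p_apical_fn=0.25,
            p_midv_fn=0.01, segments_pm=True, seed=seed),
        "truncation_prone": PerturbationProfile(
            reader_id="truncation_prone", radial_noise_sd=0.6, radial_bias=-0.5,
            p_basal_fp=0.02, p_basal_fn=0.40, p_apical_fp=0.02, p_apical_fn=0.30,
            p_midv_fn=0.02, segments_pm=True, seed=seed),
        "no_pm": PerturbationProfile(
            reader_id="no_pm", radial_noise_sd=0.8, radial_bias=0.3,
            p_basal_fp=0.20, p_basal_fn=0.05, p_apical_fp=0.05, p_apical_fn=0.25,
            p_midv_fn=0.01, segments_pm=False, seed=seed),
        "reader2": PerturbationProfile(
            reader_id="reader2", radial_noise_sd=0.5, radial_bias=0.0,
            p_basal_fp=0.03, p_basal_fn=0.05, p_apical_fp=0.03, p_apical_fn=0.08,
            segments_pm=True, seed=seed),
    }
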