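"""Domain types and polygon primitives for short-axis contour annotations.

A case is an ordered stack of parallel short-axis slices (index 0 = most
basal acquired slice, increasing toward the apex).  Each reader annotates
each slice/phase with named closed polygons: LV endocardium (``lv_endo``),
LV epicardium (``lv_epi``, end-diastole only), RV endocardium (``rv_endo``)
and papillary-muscle blobs (``pm``, possibly several per slice).

Coordinates are 0-based pixel centres; physical position in mm is
``pixel * pixel_spacing``.  Outer rings are canonicalised counter-clockwise,
holes clockwise; self-intersecting rings are rejected rather than repaired
so annotation bugs surface instead of being silently patched.

The LV myocardium is never stored: it is materialised at comparison time as
the epicardial polygon minus the endocardial one (minus papillary muscle
when papillary muscles count as myocardium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

CONTOUR_TYPES = ("lv_endo", "lv_epi", "rv_endo", "pm")
PHASES = ("ED", "ES")
#: Region names that metrics can be computed on (lv_myo is derived).
REGION_TYPES = ("lv_endo", "rv_endo", "lv_myo")


class ContourValidationError(ValueError):
    """A ring is degenerate (< 3 vertices, zero area) or self-intersecting."""


class AnnotationValidationError(ValueError):
    """A CaseAnnotationSet violates its structural invariants."""


def _shoelace(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _canonical_ring(ring: Sequence[Sequence[float]], ccw: bool) -> np.ndarray:
    arr = np.asarray(ring, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ContourValidationError(f"ring must be an (N, 2) array, got shape {arr.shape}")
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) < 3:
        raise ContourValidationError(f"ring needs >= 3 distinct vertices, got {len(arr)}")
    signed = _shoelace(arr)
    if abs(signed) < 1e-12:
        raise ContourValidationError("ring has zero area")
    if (signed > 0) != ccw:
        arr = arr[::-1].copy()
    return arr


@dataclass(frozen=True)
class SliceGeometry:
    """Acquisition geometry of one short-axis slice.

    ``slice_index`` 0 is the most basal acquired slice, increasing toward
    the apex.  ``pixel_spacing`` is isotropic in-plane (mm/pixel);
    ``slice_thickness`` and the optional inter-slice ``slice_gap`` are in mm.
    """

    slice_index: int
    pixel_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise AnnotationValidationError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.slice_thickness <= 0:
            raise AnnotationValidationError(
                f"slice_thickness must be > 0, got {self.slice_thickness}"
            )
        if self.slice_gap < 0:
            raise AnnotationValidationError(f"slice_gap must be >= 0, got {self.slice_gap}")

    @property
    def slab_thickness(self) -> float:
        """Effective slab thickness (mm) for slice-summation volumetry."""
        return self.slice_thickness + self.slice_gap


@dataclass
class Contour:
    """One closed planar polygon for one structure on one slice/phase.

    The outer ring is stored counter-clockwise, holes clockwise (holes are
    only ever materialised internally, never read from annotation files).
    """

    contour_type: str
    phase: str
    outer_ring: np.ndarray
    holes: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.contour_type not in CONTOUR_TYPES:
            raise ContourValidationError(
                f"unknown contour type {self.contour_type!r}; expected one of {CONTOUR_TYPES}"
            )
        if self.phase not in PHASES:
            raise ContourValidationError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        self.outer_ring = _canonical_ring(self.outer_ring, ccw=True)
        self.holes = [_canonical_ring(h, ccw=False) for h in self.holes]
        poly = Polygon(self.outer_ring, self.holes)
        if not poly.is_valid:
            raise ContourValidationError(
                f"invalid (self-intersecting or mis-nested) {self.contour_type} ring: "
                f"{shapely.is_valid_reason(poly)}"
            )
        shell = Polygon(self.outer_ring)
        for h in self.holes:
            if not shell.contains(Polygon(h)):
                raise ContourValidationError("hole lies outside the outer ring")

    def polygon(self) -> Polygon:
        """Shapely polygon in pixel coordinates."""
        return Polygon(self.outer_ring, self.holes)

    def perimeter_px(self) -> float:
        return float(Polygon(self.outer_ring).exterior.length)


def polygon_area(contour: Contour, pixel_spacing: float = 1.0) -> float:
    """Enclosed area in mm²: shoelace area of the outer ring minus holes,
    scaled by ``pixel_spacing²``."""
    if pixel_spacing <= 0:
        raise AnnotationValidationError("pixel_spacing must be > 0")
    return float(contour.polygon().area) * pixel_spacing**2


def intersection_area(a: Contour, b: Contour, pixel_spacing: float = 1.0) -> float:
    """Exact polygon-clipping intersection area in mm² (symmetric)."""
    if pixel_spacing <= 0:
        raise AnnotationValidationError("pixel_spacing must be > 0")
    return float(a.polygon().intersection(b.polygon()).area) * pixel_spacing**2


def densify_ring(ring_mm: np.ndarray, max_arc: float) -> np.ndarray:
    """Insert points on each edge so consecutive samples are <= max_arc apart."""
    if max_arc <= 0:
        raise ValueError("max_arc must be > 0")
    pts: List[np.ndarray] = []
    n = len(ring_mm)
    for i in range(n):
        p, q = ring_mm[i], ring_mm[(i + 1) % n]
        seg = float(np.hypot(*(q - p)))
        k = max(1, int(math.ceil(seg / max_arc)))
        t = np.arange(k) / k
        pts.append(p[None, :] + t[:, None] * (q - p)[None, :])
    return np.concatenate(pts, axis=0)


def boundary_points(contour: Contour, max_arc: float, pixel_spacing: float = 1.0) -> np.ndarray:
    """Outer-ring boundary sampled in physical mm coordinates.

    Returns the ring vertices plus interpolated points so consecutive
    samples along each edge are at most ``max_arc`` mm apart.  When
    ``max_arc`` exceeds every edge length the original vertices come back
    unchanged.
    """
    ring_mm = contour.outer_ring * pixel_spacing
    return densify_ring(ring_mm, max_arc)


def geometry_boundary_points(geom, max_arc: float) -> np.ndarray:
    """Densified boundary samples of an arbitrary shapely geometry (mm)."""
    polys = _as_polygons(geom)
    parts = []
    for p in polys:
        for ring in [p.exterior, *p.interiors]:
            parts.append(densify_ring(np.asarray(ring.coords)[:-1], max_arc))
    if not parts:
        return np.empty((0, 2))
    return np.concatenate(parts, axis=0)


def _as_polygons(geom) -> List[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    # GeometryCollection from degenerate clipping: keep polygonal parts only
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


@dataclass
class CaseAnnotationSet:
    """One reader's full labelling of one case.

    ``contours`` maps ``(slice_index, phase, contour_type)`` to a list of
    contours (papillary muscles may have several blobs per slice; other
    types normally one).
    """

    case_id: str
    reader_id: str
    slices: List[SliceGeometry]
    contours: Dict[Tuple[int, str, str], List[Contour]]
    extras: dict = field(default_factory=dict)  # unknown file fields, preserved on round-trip

    def __post_init__(self) -> None:
        idx = [s.slice_index for s in self.slices]
        if len(set(idx)) != len(idx):
            raise AnnotationValidationError(f"case {self.case_id}: duplicate slice_index")
        self._slice_map = {s.slice_index: s for s in self.slices}
        for (si, phase, ctype), lst in self.contours.items():
            if si not in self._slice_map:
                raise AnnotationValidationError(
                    f"case {self.case_id}: contour references unknown slice {si}"
                )
            if ctype == "lv_epi" and phase != "ED":
                raise AnnotationValidationError(
                    f"case {self.case_id}: lv_epi is contoured at ED only (got {phase})"
                )
            for c in lst:
                if c.contour_type != ctype or c.phase != phase:
                    raise AnnotationValidationError(
                        f"case {self.case_id}: contour key {(si, phase, ctype)} "
                        f"disagrees with contour fields ({c.contour_type}, {c.phase})"
                    )
        # endo must lie within epi where both exist
        for (si, phase, ctype), lst in self.contours.items():
            if ctype != "lv_endo":
                continue
            epi = self.contours.get((si, phase, "lv_epi"))
            if epi:
                epi_poly = unary_union([c.polygon() for c in epi])
                for c in lst:
                    if not epi_poly.buffer(1e-6).contains(c.polygon()):
                        raise AnnotationValidationError(
                            f"case {self.case_id} slice {si} {phase}: lv_endo not inside lv_epi"
                        )

    # -- lookups ---------------------------------------------------------

    def slice_geometry(self, slice_index: int) -> SliceGeometry:
        return self._slice_map[slice_index]

    @property
    def slice_indices(self) -> List[int]:
        return sorted(self._slice_map)

    def get(self, slice_index: int, phase: str, contour_type: str) -> List[Contour]:
        return self.contours.get((slice_index, phase, contour_type), [])

    def has_region(self, slice_index: int, phase: str, region: str) -> bool:
        """Whether the reader provided the region on this slice/phase.

        The myocardial annulus exists wherever the epicardial contour does.
        """
        ctype = "lv_epi" if region == "lv_myo" else region
        return bool(self.get(slice_index, phase, ctype))

    def segmented_slices(self, region: str, phase: str) -> List[int]:
        """Sorted slice indices on which this reader segmented the region."""
        return sorted(si for si in self._slice_map if self.has_region(si, phase, region))

    # -- region materialisation -----------------------------------------

    def region_geometry(self, slice_index: int, phase: str, region: str,
                        pm_as_myocardium: bool = False):
        """Materialise a region as a shapely geometry in mm coordinates.

        ``region`` is one of ``lv_endo``, ``rv_endo``, ``lv_myo``.  With
        ``pm_as_myocardium`` papillary-muscle blobs (clipped to the
        endocardial cavity) are removed from the LV blood pool and added to
        the myocardial annulus.  Returns an empty geometry when the region
        was not contoured.
        """
        if region not in REGION_TYPES:
            raise AnnotationValidationError(f"unknown region {region!r}")
        ps = self._slice_map[slice_index].pixel_spacing

        def union_of(ctype: str):
            lst = self.get(slice_index, phase, ctype)
            if not lst:
                return Polygon()
            return unary_union([c.polygon() for c in lst])

        if region == "rv_endo":
            geom = union_of("rv_endo")
        elif region == "lv_endo":
            geom = union_of("lv_endo")
            if pm_as_myocardium and not geom.is_empty:
                geom = geom.difference(union_of("pm").intersection(geom))
        else:  # lv_myo = epi minus endo (+ pm when it counts as myocardium)
            epi = union_of("lv_epi")
            if epi.is_empty:
                geom = Polygon()
            else:
                endo = union_of("lv_endo")
                geom = epi.difference(endo)
                if pm_as_myocardium and not endo.is_empty:
                    geom = unary_union([geom, union_of("pm").intersection(endo)])
        return shapely.affinity.scale(geom, xfact=ps, yfact=ps, origin=(0, 0))

    def region_area_mm2(self, slice_index: int, phase: str, region: str,
                        pm_as_myocardium: bool = False) -> float:
        return float(self.region_geometry(slice_index, phase, region, pm_as_myocardium).area)


@dataclass
class CohortComparison:
    """Paired annotations of one candidate reader against the expert.

    ``pairs`` maps case_id to ``(expert, candidate)`` annotation sets that
    share identical slice geometry (same acquisition, different readers).
    """

    expert: str
    candidate: str
    pairs: Dict[str, Tuple[CaseAnnotationSet, CaseAnnotationSet]]

    def __post_init__(self) -> None:
        for cid, (e, a) in self.pairs.items():
            if e.slices != a.slices:
                raise AnnotationValidationError(
                    f"case {cid}: readers {e.reader_id!r} and {a.reader_id!r} "
                    "have mismatched slice geometry"
                )

    @property
    def case_ids(self) -> List[str]:
        return sorted(self.pairs)
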