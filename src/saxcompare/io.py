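"""File formats and run configuration.

Contour annotations travel in a small versioned JSON schema (one document
per case per reader), deliberately vendor-neutral::

    {"schema_version": "1.0", "case_id": ..., "reader_id": ...,
     "slices":  [{"slice_index": 0, "pixel_spacing_mm": 1.79,
                  "slice_thickness_mm": 7.08, "slice_gap_mm": 0.0}, ...],
     "contours": [{"slice_index": 3, "phase": "ED", "type": "lv_endo",
                   "rings": [[[x, y], ...]], "holes": []}, ...]}

Coordinates are serialised as reals in pixel units (mm conversion happens
only at compute time, avoiding double rounding).  Unknown top-level fields
are preserved on round-trip; writes are deterministic (sorted keys), so
write → read → write is byte-stable for canonicalised input.

A cohort on disk is ``<dir>/<reader_id>/<case_id>.json`` plus an optional
``truth.csv``.  Tolerance ranges (BTR/VTR) and cut-off sets are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .core import CaseAnnotationSet, CohortComparison, Contour, SliceGeometry
from .corrections import Cutoff, CutoffSet
from .verity import ToleranceRanges

SCHEMA_VERSION = "1.0"

_KNOWN_FIELDS = {"schema_version", "case_id", "reader_id", "slices", "contours"}


class SchemaError(ValueError):
    """A contour JSON document violates the file schema."""


def annotation_to_dict(ann: CaseAnnotationSet) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "case_id": ann.case_id,
        "reader_id": ann.reader_id,
        "slices": [
            {
                "slice_index": s.slice_index,
                "pixel_spacing_mm": s.pixel_spacing,
                "slice_thickness_mm": s.slice_thickness,
                "slice_gap_mm": s.slice_gap,
            }
            for s in sorted(ann.slices, key=lambda s: s.slice_index)
        ],
        "contours": [
            {
                "slice_index": si,
                "phase": phase,
                "type": ctype,
                "rings": [c.outer_ring.tolist() for c in lst],
                "holes": [[h.tolist() for h in c.holes] for c in lst],
            }
            for (si, phase, ctype), lst in sorted(ann.contours.items())
            if lst
        ],
    }
    doc.update(ann.extras)
    return doc


def annotation_from_dict(doc: dict) -> CaseAnnotationSet:
    for key in ("schema_version", "case_id", "reader_id", "slices", "contours"):
        if key not in doc:
            raise SchemaError(f"missing required field {key!r}")
    if str(doc["schema_version"]).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"unsupported schema_version {doc['schema_version']!r}")
    try:
        slices = [
            SliceGeometry(
                slice_index=int(s["slice_index"]),
                pixel_spacing=float(s["pixel_spacing_mm"]),
                slice_thickness=float(s["slice_thickness_mm"]),
                slice_gap=float(s.get("slice_gap_mm", 0.0)),
            )
            for s in doc["slices"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed slices block: {exc}") from exc
    contours: Dict[Tuple[int, str, str], List[Contour]] = {}
    for rec in doc["contours"]:
        try:
            si = int(rec["slice_index"])
            phase = rec["phase"]
            ctype = rec["type"]
            rings = rec["rings"]
            holes = rec.get("holes") or [[] for _ in rings]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed contour record: {exc}") from exc
        if len(holes) != len(rings):
            raise SchemaError("holes list must parallel rings list")
        lst = contours.setdefault((si, phase, ctype), [])
        for ring, hole_rings in zip(rings, holes):
            lst.append(Contour(ctype, phase, ring, [h for h in hole_rings]))
    extras = {k: v for k, v in doc.items() if k not in _KNOWN_FIELDS}
    return CaseAnnotationSet(
        case_id=str(doc["case_id"]),
        reader_id=str(doc["reader_id"]),
        slices=slices,
        contours=contours,
        extras=extras,
    )


def write_annotation(ann: CaseAnnotationSet, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(annotation_to_dict(ann), sort_keys=True, indent=1) + "\n")


def read_annotation(path: Path) -> CaseAnnotationSet:
    return annotation_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort directories

def write_cohort(cases: Sequence[CaseAnnotationSet], root: Path,
                 truth: Optional[pd.DataFrame] = None) -> None:
    root = Path(root)
    for ann in cases:
        write_annotation(ann, root / ann.reader_id / f"{ann.case_id}.json")
    if truth is not None:
        root.mkdir(parents=True, exist_ok=True)
        truth.to_csv(root / "truth.csv")


def read_reader(root: Path, reader_id: str) -> List[CaseAnnotationSet]:
    rdir = Path(root) / reader_id
    if not rdir.is_dir():
        raise FileNotFoundError(f"no annotations for reader {reader_id!r} under {root}")
    return [read_annotation(p) for p in sorted(rdir.glob("*.json"))]


def read_cohort_comparison(root: Path, expert: str, candidate: str) -> CohortComparison:
    e_cases = {a.case_id: a for a in read_reader(root, expert)}
    a_cases = {a.case_id: a for a in read_reader(root, candidate)}
    shared = sorted(set(e_cases) & set(a_cases))
    if not shared:
        raise SchemaError(f"readers {expert!r} and {candidate!r} share no cases")
    return CohortComparison(
        expert=expert,
        candidate=candidate,
        pairs={cid: (e_cases[cid], a_cases[cid]) for cid in shared},
    )


# ---------------------------------------------------------------------------
# tolerance ranges and cut-off sets (YAML)

def write_tolerance_ranges(ranges: Dict[str, ToleranceRanges], path: Path) -> None:
    doc = {param: {"btr": tr.btr, "vtr": tr.vtr} for param, tr in ranges.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_tolerance_ranges(path: Path) -> Dict[str, ToleranceRanges]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: tolerance-range file must map parameter -> {{btr, vtr}}")
    out = {}
    for param, entry in doc.items():
        try:
            out[param] = ToleranceRanges(btr=float(entry["btr"]), vtr=float(entry["vtr"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad entry for {param!r}: {exc}") from exc
    return out


def write_cutoffs(cutoffs: CutoffSet, path: Path) -> None:
    doc = {f"{region}/{phase}": {"area_cm2": c.area_cutoff, "dice": c.dice_cutoff}
           for (region, phase), c in cutoffs.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_cutoffs(path: Path) -> CutoffSet:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: cut-off file must map 'region/phase' -> {{area_cm2, dice}}")
    out: CutoffSet = {}
    for key, entry in doc.items():
        try:
            region, phase = key.split("/")
            out[(region, phase)] = Cutoff(area_cutoff=float(entry["area_cm2"]),
                                          dice_cutoff=float(entry["dice"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad entry for {key!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved options of one analysis run; written next to its outputs."""

    pm_mode: str = "excluded"
    orientation: str = "ai-minus-expert"
    max_arc_mm: float = 0.1
    myocardial_density: float = 1.05
    per_case_first: bool = False
    count_decision_errors: bool = True
    seed: int = 0
    btr_vtr_path: Optional[str] = None
    cutoffs_path: Optional[str] = None

    def write(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def read(cls, path: Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
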