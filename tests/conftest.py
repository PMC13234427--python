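import numpy as np
import pytest

from saxcompare.core import CaseAnnotationSet, Contour, SliceGeometry
from saxcompare.synthetic import (PhantomCohort, PhantomSpec, builtin_profiles,
                                  generate_expert, pair_cohort, perturb_cohort)


def circle_ring(cx: float, cy: float, r: float, n: int = 720) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def square_ring(x0: float, y0: float, side: float) -> np.ndarray:
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])


def make_case(case_id: str, reader_id: str, seg_slices, n_slices: int = 12,
              radius: float = 20.0, rv_radius: float = 12.0,
              thickness: float = 10.0, spacing: float = 1.0) -> CaseAnnotationSet:
    """Minimal hand-built case: circular LV endo and a circular 'RV' on each
    segmented slice, both phases, no epi/pm.  Used for decision-classifier
    fixtures where only presence and area matter."""
    slices = [SliceGeometry(i, spacing, thickness) for i in range(n_slices)]
    contours = {}
    for si in seg_slices:
        for phase in ("ED", "ES"):
            contours[(si, phase, "lv_endo")] = [
                Contour("lv_endo", phase, circle_ring(60, 60, radius, 180))]
            contours[(si, phase, "rv_endo")] = [
                Contour("rv_endo", phase, circle_ring(20, 60, rv_radius, 180))]
    return CaseAnnotationSet(case_id, reader_id, slices, contours)


@pytest.fixture(scope="session")
def small_cohort() -> PhantomCohort:
    return generate_expert(PhantomSpec(n_cases=6, seed=7))


@pytest.fixture(scope="session")
def noisy_pair(small_cohort):
    """Expert vs a truncation-prone AI reader on the small cohort."""
    profile = builtin_profiles(seed=11)["truncation_prone"]
    return pair_cohort(small_cohort.cases, perturb_cohort(small_cohort, profile))


@pytest.fixture(scope="session")
def calibration_pair(small_cohort):
    """Expert vs a careful second human reader, for cut-off calibration."""
    profile = builtin_profiles(seed=13)["reader2"]
    return pair_cohort(small_cohort.cases, perturb_cohort(small_cohort, profile))
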