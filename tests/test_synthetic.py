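"""Phantom generator: analytic truth, determinism, perturbation behaviour."""

import dataclasses
import json

import numpy as np
import pytest

from saxcompare.clinical import PmMode, derive_params
from saxcompare.io import annotation_to_dict
from saxcompare.segmetrics import classify_slices, decision_rates
from saxcompare.synthetic import (PerturbationProfile, PhantomSpec, builtin_profiles,
                                  crescent_area, generate_case, generate_expert,
                                  perturb, perturb_cohort, phantom_preset)


def rigid_spec(**kw):
    """Spec with per-case anatomy jitter off, so closed forms are exact."""
    defaults = dict(n_cases=2, case_scale_sd=0.0, wall_scale_sd=0.0, es_scale_sd=0.0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        {"lv_endo_base_radius": -1}, {"ed_es_scale": 1.2}, {"apical_taper": 1.5},
        {"slices_per_case": 3}, {"pm": (2, 20.0)},
        {"apical_taper": 0.2, "slices_per_case": 12},  # radius vanishes at apex
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            PhantomSpec(**kw)

    @pytest.mark.parametrize("kw", [{"p_basal_fn": 1.3}, {"radial_noise_sd": -1}])
    def test_invalid_profiles_rejected(self, kw):
        with pytest.raises(ValueError):
            PerturbationProfile(**kw)


class TestExpertTruth:
    def test_constant_radius_truth_is_stacked_cylinder(self):
        spec = rigid_spec(apical_taper=0.0, pm=None)
        ann, truth = generate_case(spec, 0)
        n_seg = spec.slices_per_case - 2
        expected = n_seg * np.pi * spec.lv_endo_base_radius**2 * spec.slice_thickness / 1000
        assert truth["lv_edv"] == pytest.approx(expected, rel=1e-12)

    def test_ef_closed_form_from_es_scale(self):
        spec = rigid_spec(ed_es_scale=0.7)
        _, truth = generate_case(spec, 0)
        assert truth["lv_ef"] == pytest.approx(100 * (1 - 0.49), rel=1e-12)
        assert truth["rv_ef"] == pytest.approx(100 * (1 - 0.49), rel=1e-12)

    def test_same_seed_byte_identical(self):
        spec = PhantomSpec(n_cases=2, seed=21)
        a = generate_expert(spec)
        b = generate_expert(spec)
        for ca, cb in zip(a.cases, b.cases):
            assert json.dumps(annotation_to_dict(ca)) == json.dumps(annotation_to_dict(cb))
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self):
        a = generate_expert(PhantomSpec(n_cases=1, seed=1))
        b = generate_expert(PhantomSpec(n_cases=1, seed=2))
        assert not a.truth.equals(b.truth)

    def test_pipeline_recovers_truth(self, small_cohort):
        ann = small_cohort.cases[2]
        truth = small_cohort.truth.loc[ann.case_id]
        p = derive_params(ann)
        assert p.lv_edv == pytest.approx(truth["lv_edv"], rel=1e-3)
        assert p.rv_edv == pytest.approx(truth["rv_edv"], rel=1e-3)
        pi = derive_params(ann, PmMode.INCLUDED)
        assert pi.lv_edv == pytest.approx(truth["lv_edv_pm_included"], rel=1e-3)
        assert pi.lvm == pytest.approx(truth["lvm_pm_included"], rel=1e-3)

    def test_crescent_area_closed_form_sanity(self):
        # disjoint discs: full disc area; contained: zero
        assert crescent_area(100, 0.0, 10) == pytest.approx(np.pi * (100**2 - 10**2))
        assert crescent_area(5, 0.0, 10) == pytest.approx(0.0)

    def test_presets(self):
        normal = phantom_preset("normal", n_cases=1)
        dilated = phantom_preset("dilated", n_cases=1)
        hyper = phantom_preset("hypertrophic", n_cases=1)
        assert dilated.lv_endo_base_radius > normal.lv_endo_base_radius
        assert hyper.wall_thickness > normal.wall_thickness
        with pytest.raises(ValueError):
            phantom_preset("unknown")
        # all presets must generate valid geometry end to end
        for spec in (dilated, hyper):
            cohort = generate_expert(dataclasses.replace(spec, seed=5))
            assert derive_params(cohort.cases[0]).lv_edv > 0


class TestPerturbation:
    def test_identity_profile_reproduces_expert(self, small_cohort):
        expert = small_cohort.cases[0]
        ai = perturb(expert, PerturbationProfile(reader_id="identity", seed=9))
        de, da = annotation_to_dict(expert), annotation_to_dict(ai)
        de["reader_id"] = da["reader_id"]
        assert json.dumps(de) == json.dumps(da)

    def test_radial_bias_area_oracle(self):
        # +1 mm dilation of a radius-20 circle grows area by pi(21^2 - 20^2)
        spec = rigid_spec(apical_taper=0.0, lv_endo_base_radius=20.0, pm=None)
        ann, _ = generate_case(spec, 0)
        ai = perturb(ann, PerturbationProfile(radial_bias=1.0, seed=3))
        si = ann.segmented_slices("lv_endo", "ED")[0]
        before = ann.region_area_mm2(si, "ED", "lv_endo")
        after = ai.region_area_mm2(si, "ED", "lv_endo")
        assert after - before == pytest.approx(np.pi * (21**2 - 20**2), rel=0.01)

    def test_basal_fn_rate_matches_binomial(self):
        q = 0.4
        cohort = generate_expert(PhantomSpec(n_cases=150, seed=31, pm=None))
        profile = PerturbationProfile(p_basal_fn=q, seed=77)
        ais = perturb_cohort(cohort, profile)
        comps = []
        for e, a in zip(cohort.cases, ais):
            comps += classify_slices(e, a, "lv_endo", "ED", with_metrics=False)
        rate = decision_rates(comps)["basal"]["fn_rate"]
        se = 100 * np.sqrt(q * (1 - q) / 150)
        assert abs(rate - 100 * q) <= 3 * se

    def test_pm_omission_shifts_volume_bias_positive(self, small_cohort):
        # a reader that ignores papillary muscles reports larger LV volumes
        # than one that segments them, when volumes subtract PM
        base = dict(radial_noise_sd=0.3, seed=19)
        with_pm = perturb_cohort(small_cohort, PerturbationProfile(
            reader_id="pm", segments_pm=True, **base))
        without_pm = perturb_cohort(small_cohort, PerturbationProfile(
            reader_id="nopm", segments_pm=False, **base))
        bias_with, bias_without = [], []
        for e, a_pm, a_no in zip(small_cohort.cases, with_pm, without_pm):
            ev = derive_params(e, PmMode.INCLUDED).lv_edv
            bias_with.append(derive_params(a_pm, PmMode.INCLUDED).lv_edv - ev)
            bias_without.append(derive_params(a_no, PmMode.INCLUDED).lv_edv - ev)
        assert np.mean(bias_without) > np.mean(bias_with)

    def test_deterministic_per_case(self, small_cohort):
        prof = builtin_profiles(seed=4)["inclusion_prone"]
        a1 = perturb(small_cohort.cases[0], prof)
        a2 = perturb(small_cohort.cases[0], prof)
        assert json.dumps(annotation_to_dict(a1)) == json.dumps(annotation_to_dict(a2))

    def test_anatomy_and_perturbation_seeds_independent(self):
        c1 = generate_expert(PhantomSpec(n_cases=1, seed=8))
        prof = PerturbationProfile(radial_noise_sd=0.5, seed=99)
        a1 = perturb(c1.cases[0], prof)
        # regenerating the same cohort and re-perturbing gives the same result
        c2 = generate_expert(PhantomSpec(n_cases=1, seed=8))
        a2 = perturb(c2.cases[0], prof)
        assert json.dumps(annotation_to_dict(a1)) == json.dumps(annotation_to_dict(a2))

    def test_basal_fp_adds_out_of_range_slice(self):
        cohort = generate_expert(PhantomSpec(n_cases=12, seed=41, pm=None))
        ais = perturb_cohort(cohort, PerturbationProfile(p_basal_fp=1.0, seed=6))
        for e, a in zip(cohort.cases, ais):
            e_min = e.segmented_slices("lv_endo", "ED")[0]
            assert a.has_region(e_min - 1, "ED", "lv_endo")

    def test_noise_changes_contours_but_keeps_validity(self, small_cohort):
        ai = perturb(small_cohort.cases[1],
                     PerturbationProfile(radial_noise_sd=1.0, seed=2))
        p = derive_params(ai)  # ring validity was enforced at construction
        assert p.lv_edv > 0 and p.rv_edv > 0
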