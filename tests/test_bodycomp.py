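"""Body-composition indices, thresholds and percentile cutoffs."""

import math

import numpy as np
import pytest

from compoct.bodycomp import (
    BodyComposition,
    Cutoffs,
    PatientMeta,
    area_cm2,
    classify,
    compute_indices,
    derive_cutoffs,
)
from compoct.groundtruth import make_ground_truth
from compoct.phantom import HUSlice, PhantomSpec, generate_phantom
from compoct.rois import ROI_NAMES


@pytest.mark.parametrize("npx,spacing,expected", [
    (1000, (1.0, 1.0), 10.0),
    (0, (1.0, 1.0), 0.0),
    (1000, (0.98, 0.98), 9.604),
])
def test_area_cm2(npx, spacing, expected):
    mask = np.zeros(2000, dtype=bool)
    mask[:npx] = True
    assert area_cm2(mask.reshape(40, 50), spacing) == pytest.approx(expected)


def test_area_rejects_bad_spacing():
    with pytest.raises(ValueError):
        area_cm2(np.ones((2, 2), dtype=bool), (0.0, 1.0))


def _uniform_slice_and_masks(hu=40.0, n=40, spacing=2.0):
    """A slice whose m01 mask covers the top half at constant HU."""
    values = np.full((n, n), hu)
    slc = HUSlice(values=values, pixel_spacing_mm=(spacing, spacing))
    masks = {r: np.zeros((n, n), dtype=bool) for r in ROI_NAMES}
    masks["m01"][: n // 2] = True
    from compoct.groundtruth import ROIMaskSet

    return slc, ROIMaskSet(masks=masks)


class TestComputeIndices:
    def test_smi_formula(self, meta_male):
        # 160 cm^2 at height 1.79 m -> 49.94 cm^2/m^2
        slc, masks = _uniform_slice_and_masks(n=40, spacing=2.0)
        # top half = 800 px * 4 mm^2 = 32 cm^2; scale via height instead
        bc = compute_indices(slc, masks, meta_male)
        assert bc.muscle_area_cm2 == pytest.approx(32.0)
        assert bc.smi == pytest.approx(32.0 / 1.79**2)
        assert 160.0 / 1.79**2 == pytest.approx(49.94, abs=0.01)

    def test_ma_of_uniform_muscle(self, meta_male):
        slc, masks = _uniform_slice_and_masks(hu=40.0)
        bc = compute_indices(slc, masks, meta_male)
        assert bc.ma_hu == pytest.approx(40.0)

    def test_phantom_generator_contract(self, meta_male):
        slc, lab = generate_phantom(
            PhantomSpec(target_muscle_mean_hu=36.1, noise_sd_hu=0.0, seed=11))
        gt = make_ground_truth(slc, lab)
        bc = compute_indices(slc, gt, meta_male)
        assert bc.ma_hu == pytest.approx(36.1, abs=1.0)

    def test_empty_muscle_warns_and_flags(self, meta_male):
        slc, masks = _uniform_slice_and_masks()
        for r in ROI_NAMES:
            masks.masks[r][:] = False
        with pytest.warns(UserWarning, match="empty muscle"):
            bc = compute_indices(slc, masks, meta_male)
        assert math.isnan(bc.ma_hu)
        assert bc.smi == 0.0

    def test_smi_scales_inverse_height_squared(self):
        slc, masks = _uniform_slice_and_masks()
        short = PatientMeta(sex="male", height_m=1.60, weight_kg=70,
                            age_years=50)
        tall = PatientMeta(sex="male", height_m=2.0, weight_kg=70,
                           age_years=50)
        b1 = compute_indices(slc, masks, short)
        b2 = compute_indices(slc, masks, tall)
        assert b2.smi == pytest.approx(b1.smi * (1.60 / 2.0) ** 2)

    def test_ma_invariant_to_spacing_area_invariant_to_hu(self, meta_male):
        a_slc, a_masks = _uniform_slice_and_masks(hu=35.0, spacing=1.0)
        b_slc, b_masks = _uniform_slice_and_masks(hu=35.0, spacing=3.0)
        ba = compute_indices(a_slc, a_masks, meta_male)
        bb = compute_indices(b_slc, b_masks, meta_male)
        assert ba.ma_hu == bb.ma_hu
        c_slc, c_masks = _uniform_slice_and_masks(hu=120.0, spacing=1.0)
        bc = compute_indices(c_slc, c_masks, meta_male)
        assert bc.muscle_area_cm2 == ba.muscle_area_cm2


class TestClassify:
    def _bc(self, smi=50.0, ma=35.0):
        return BodyComposition(muscle_area_cm2=smi * 1.79**2, smi=smi,
                               ma_hu=ma, vat_index=20.0, sat_index=30.0)

    def test_sarcopenia_threshold_male(self, meta_male):
        assert classify(self._bc(smi=54.9), meta_male).sarcopenic
        assert not classify(self._bc(smi=55.0), meta_male).sarcopenic

    def test_hypodensity_threshold_male(self, meta_male):
        assert classify(self._bc(ma=26.0), meta_male).hypodense
        assert not classify(self._bc(ma=26.7), meta_male).hypodense

    def test_female_thresholds(self):
        f = PatientMeta(sex="female", height_m=1.65, weight_kg=60,
                        age_years=45)
        assert classify(self._bc(smi=38.9), f).sarcopenic
        assert not classify(self._bc(smi=39.0), f).sarcopenic
        assert classify(self._bc(ma=23.0), f).hypodense

    def test_bmi_boundaries_strict(self):
        exactly_30 = PatientMeta(sex="female", height_m=1.60,
                                 weight_kg=30.0 * 1.6**2, age_years=40)
        out = classify(self._bc(), exactly_30)
        assert not out.obese and not out.underweight

    def test_undefined_ma_gives_undetermined_hypodensity(self, meta_male):
        bc = self._bc()
        bc.ma_hu = math.nan
        out = classify(bc, meta_male)
        assert out.hypodense is None
        assert out.sarcopenic is not None

    def test_monotone_in_ma(self, meta_male):
        flagged = classify(self._bc(ma=25.0), meta_male).hypodense
        lower = classify(self._bc(ma=20.0), meta_male).hypodense
        assert not flagged or lower  # lowering MA never clears the flag


class TestDeriveCutoffs:
    def _cohort(self, male_ma, female_ma):
        out = []
        for sex, vals, h in (("male", male_ma, 1.78),
                             ("female", female_ma, 1.64)):
            for v in vals:
                meta = PatientMeta(sex=sex, height_m=h, weight_kg=70,
                                   age_years=50)
                bc = BodyComposition(muscle_area_cm2=150, smi=47,
                                     ma_hu=float(v), vat_index=20,
                                     sat_index=30)
                out.append((meta, bc))
        return out

    def test_linear_interpolation_percentile(self):
        cohort = self._cohort(range(1, 101), range(1, 101))
        cuts = derive_cutoffs(cohort, percentile=10.0)
        assert cuts.hypodensity_male_hu == pytest.approx(10.9)

    def test_constant_distribution(self):
        cohort = self._cohort([33.0] * 20, [31.0] * 20)
        cuts = derive_cutoffs(cohort)
        assert cuts.hypodensity_male_hu == 33.0
        assert cuts.hypodensity_female_hu == 31.0

    def test_missing_sex_rejected(self):
        cohort = self._cohort(range(30), [])
        with pytest.raises(ValueError, match="female"):
            derive_cutoffs(cohort)

    def test_simulated_cohort_flags_about_ten_percent(self):
        from compoct.cohortsim import CohortSpec, simulate_cohort

        records = simulate_cohort(CohortSpec(n=656, seed=1))
        cohort = [(r.meta, r.bc) for r in records]
        cuts = derive_cutoffs(cohort, percentile=10.0)
        flagged = sum(
            1 for meta, bc in cohort
            if bc.ma_hu < cuts.hypodensity(meta.sex))
        assert 0.08 <= flagged / len(cohort) <= 0.12

    def test_defaults_keep_reference_constants(self):
        cuts = Cutoffs()
        assert cuts.sarcopenia("male") == 55.0
        assert cuts.sarcopenia("female") == 39.0
        assert cuts.hypodensity("male") == 26.7
        assert cuts.hypodensity("female") == 23.1
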