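"""Body-composition indices from L3 masks, and their classification.

From the pooled muscle mask and the two fat masks of a single L3 slice:

* muscle area (cm^2) and skeletal muscle index SMI = area / height^2
  (cm^2/m^2)
* muscle attenuation MA = mean HU over the pooled muscle pixels
* visceral and subcutaneous fat indices, VAT/SAT area / height^2

Classification uses literature thresholds: sarcopenia below
55 cm^2/m^2 (men) / 39 (women); muscular hypodensity below the
sex-specific 10th percentile of the cohort's MA (26.7 HU for men and
23.1 for women in the reference cohort); obesity BMI > 30 and
underweight BMI < 18.5 kg/m^2.  All comparisons are strict, matching
the "below"/"above" wording the thresholds were defined with.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from compoct.groundtruth import ROIMaskSet
from compoct.phantom import HUSlice

__all__ = [
    "PatientMeta",
    "BodyComposition",
    "Cutoffs",
    "area_cm2",
    "compute_indices",
    "classify",
    "derive_cutoffs",
]

AAIPI_LEVELS = ("low", "low-int", "high-int", "high")


@dataclass(frozen=True)
class PatientMeta:
    """Anthropometric metadata for one patient."""

    sex: str
    height_m: float
    weight_kg: float
    age_years: float
    aaipi: str = "low-int"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male'/'female', got {self.sex!r}")
        if not 1.0 < self.height_m < 2.5:
            raise ValueError(f"implausible height {self.height_m} m")
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.aaipi not in AAIPI_LEVELS:
            raise ValueError(f"aaipi must be one of {AAIPI_LEVELS}")

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


@dataclass
class BodyComposition:
    """Derived indices plus classification flags (None = not yet set,
    for ``hypodense`` also 'undetermined' when MA is undefined)."""

    muscle_area_cm2: float
    smi: float
    ma_hu: float  # NaN when the muscle mask is empty
    vat_index: float
    sat_index: float
    sarcopenic: bool | None = None
    hypodense: bool | None = None
    obese: bool | None = None
    underweight: bool | None = None


@dataclass(frozen=True)
class Cutoffs:
    """Classification thresholds; defaults are the reference values."""

    sarcopenia_male: float = 55.0     # cm^2/m^2
    sarcopenia_female: float = 39.0
    hypodensity_male_hu: float = 26.7
    hypodensity_female_hu: float = 23.1
    obesity_bmi: float = 30.0
    underweight_bmi: float = 18.5
    percentile: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")

    def sarcopenia(self, sex: str) -> float:
        return self.sarcopenia_male if sex == "male" else self.sarcopenia_female

    def hypodensity(self, sex: str) -> float:
        return (self.hypodensity_male_hu if sex == "male"
                else self.hypodensity_female_hu)


def area_cm2(mask: np.ndarray, pixel_spacing_mm: tuple[float, float]) -> float:
    """Mask area in cm^2: pixel count x row spacing x col spacing / 100."""
    rs, cs = pixel_spacing_mm
    if rs <= 0 or cs <= 0:
        raise ValueError("pixel spacing must be positive")
    return float(np.count_nonzero(mask)) * rs * cs / 100.0


def compute_indices(slc: HUSlice, masks: ROIMaskSet,
                    meta: PatientMeta) -> BodyComposition:
    """Compute areas, SMI, MA and the fat indices for one patient.

    With an empty muscle mask, MA is undefined (NaN) and SMI is 0; a
    warning is emitted since this usually indicates a failed
    segmentation.
    """
    if masks.shape != slc.shape:
        raise ValueError("mask shape does not match slice")
    h2 = meta.height_m**2
    muscle = masks.muscle
    m_area = area_cm2(muscle, slc.pixel_spacing_mm)
    if m_area > 0:
        ma = float(slc.values[muscle].mean())
    else:
        warnings.warn("empty muscle mask: MA undefined, SMI set to 0",
                      stacklevel=2)
        ma = math.nan
    return BodyComposition(
        muscle_area_cm2=m_area,
        smi=m_area / h2,
        ma_hu=ma,
        vat_index=area_cm2(masks["VAT"], slc.pixel_spacing_mm) / h2,
        sat_index=area_cm2(masks["SAT"], slc.pixel_spacing_mm) / h2,
    )


def classify(bc: BodyComposition, meta: PatientMeta,
             cutoffs: Cutoffs | None = None) -> BodyComposition:
    """Set the sarcopenia / hypodensity / BMI flags (strict comparisons).

    ``hypodense`` is left ``None`` (undetermined) when MA is undefined.
    """
    cutoffs = cutoffs or Cutoffs()
    hypodense = None if math.isnan(bc.ma_hu) else bool(
        bc.ma_hu < cutoffs.hypodensity(meta.sex))
    return dataclasses.replace(
        bc,
        sarcopenic=bool(bc.smi < cutoffs.sarcopenia(meta.sex)),
        hypodense=hypodense,
        obese=bool(meta.bmi > cutoffs.obesity_bmi),
        underweight=bool(meta.bmi < cutoffs.underweight_bmi),
    )


def derive_cutoffs(cohort: Sequence[tuple[PatientMeta, BodyComposition]],
                   percentile: float = 10.0) -> Cutoffs:
    """Hypodensity cutoffs as the per-sex empirical MA percentile.

    Uses the linear-interpolation percentile definition.  Requires at
    least 10 patients of each sex; other cutoff fields keep their
    defaults so the reference constants remain available.
    """
    ma = {"male": [], "female": []}
    for meta, bc in cohort:
        if not math.isnan(bc.ma_hu):
            ma[meta.sex].append(bc.ma_hu)
    for sex, vals in ma.items():
        if len(vals) < 10:
            raise ValueError(
                f"need >= 10 {sex} patients with defined MA, got {len(vals)}")
    return Cutoffs(
        hypodensity_male_hu=float(np.percentile(ma["male"], percentile)),
        hypodensity_female_hu=float(np.percentile(ma["female"], percentile)),
        percentile=percentile,
    )
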