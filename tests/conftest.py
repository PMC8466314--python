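import numpy as np
import pytest

from compoct.bodycomp import PatientMeta
from compoct.groundtruth import make_ground_truth
from compoct.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=3, noise_sd_hu=0.0))


@pytest.fixture(scope="session")
def small_phantom_pairs():
    """Eight small identical-ish phantoms with ground truth, desk scale."""
    spec = PhantomSpec(image_size=64, pixel_spacing_mm=4.0,
                       target_muscle_area_cm2=100.0, seed=5)
    slc, labels = generate_phantom(spec)
    gt = make_ground_truth(slc, labels)
    return [(slc, gt)] * 8


@pytest.fixture
def meta_male():
    return PatientMeta(sex="male", height_m=1.79, weight_kg=80.0,
                       age_years=50.0)
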