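import numpy as np
import pytest

from petvol import PhantomConfig, ScalarImage, generate_cohort


def make_image(values, spacing=(1.0, 1.0, 1.0)):
    return ScalarImage(values=np.asarray(values, dtype=float), spacing=spacing)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """19-lesion cohort with no blur and no noise; identical plateau/background
    so every lesion has the same exact-recovery threshold band."""
    cfg = PhantomConfig(
        n_lesions=19,
        lesion_plateau_suv_range=(8.0, 8.0),
        psf_fwhm_mm=0.0,
        noise_sd_suv=0.0,
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions (PSF 5 mm, noiseless voxels), seed 3."""
    cfg = PhantomConfig(seed=3)
    return cfg, generate_cohort(cfg)
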