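"""Shared fixtures: optical configuration and cached focal patterns.

Focal-field computations are module-scoped because several tests probe
the same patterns; grids are 25 nm / 2.4 um (pupil 96 samples), fine
enough for sub-voxel FWHM interpolation yet fast on one CPU.
"""

import numpy as np
import pytest

from shadowseg import optics as op
from shadowseg import phantom as ph

EXTENT = (2400.0, 2400.0, 2400.0)
VOXEL = (25.0, 25.0, 25.0)
PUPIL_SAMPLES = 96


@pytest.fixture(scope="session")
def sted_config():
    return op.STEDConfig()


@pytest.fixture(scope="session")
def helical_patterns(sted_config):
    """Focal intensities of the m=1 and m=2 vortex depletion patterns."""
    out = {}
    for m in (1, 2):
        pupil = op.make_pupil(sted_config, op.PhaseMask("helical", helicity=m),
                              PUPIL_SAMPLES)
        out[m] = op.focal_intensity(pupil, EXTENT, VOXEL)
    return out


@pytest.fixture(scope="session")
def tophat_pattern(sted_config):
    pupil = op.make_pupil(sted_config, op.PhaseMask("tophat"), PUPIL_SAMPLES)
    return op.focal_intensity(pupil, EXTENT, VOXEL)


@pytest.fixture(scope="session")
def confocal(sted_config):
    """(excitation, pinhole-filtered detection) focal intensities."""
    return op.confocal_components(sted_config, PUPIL_SAMPLES, EXTENT, VOXEL)


@pytest.fixture(scope="session")
def combined_depletion(sted_config):
    return op.sted_depletion_pattern(sted_config, PUPIL_SAMPLES, EXTENT, VOXEL)


@pytest.fixture(scope="session")
def small_phantom_config():
    """6.4 x 6.4 x 3.2 um phantom: fast enough for pipeline tests while
    keeping the default composition (13% ECS, 1.7 spines/um)."""
    return ph.PhantomConfig(volume_extent_nm=(3200.0, 6400.0, 6400.0),
                            n_axons=6, n_dendrites=2, n_glia=2, seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return ph.generate_phantom(small_phantom_config)


@pytest.fixture(scope="session")
def default_phantom():
    """The full default 10 x 10 x 5 um phantom."""
    return ph.generate_phantom(ph.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def acquisition_psf(sted_config):
    """Isotropically calibrated effective PSF on the 50-nm imaging grid."""
    _, _, psf = op.calibrate_isotropic(sted_config, 130.0, PUPIL_SAMPLES,
                                       EXTENT, VOXEL)
    return psf.resampled((50.0, 50.0, 50.0))


@pytest.fixture(scope="session")
def phantom_suite(acquisition_psf):
    """Five seeded default phantoms imaged and segmented at default SNR.

    For each seed: ground truth, high-exposure (70 us) image, 10-us
    dwell split, and segmentations of high, restored-low and raw-low.
    """
    from shadowseg import acquisition as acq
    from shadowseg import restoration as res
    from shadowseg import segmentation as seg

    suite = []
    for pseed in range(5):
        phantom = ph.generate_phantom(ph.PhantomConfig(seed=pseed))
        high = acq.image_volume(ph.dye_density(phantom), acquisition_psf,
                                70.0, seed=pseed)
        pair = acq.split_dwell(high, 10.0)
        raw_restorer = res.RestorationModel(kind="vst_baseline",
                                            smoothing_scale=0.0)
        suite.append({
            "phantom": phantom,
            "high": high,
            "low": pair.low,
            "seg_high": seg.segment_pipeline(high),
            "seg_low": seg.segment_pipeline(pair.low),
            "seg_raw": seg.segment_pipeline(pair.low,
                                            restorer=raw_restorer),
        })
    return suite
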