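import dataclasses

import numpy as np
import pytest

from clustersense.params import AcquisitionParams, EmbryoSimParams, paper_preset


@pytest.fixture(scope="session")
def preset():
    """Calibrated (sim, acq) pair shared across tests."""
    return paper_preset()


@pytest.fixture(scope="session")
def sim(preset) -> EmbryoSimParams:
    return preset[0]


@pytest.fixture(scope="session")
def acq(preset) -> AcquisitionParams:
    return preset[1]


@pytest.fixture(scope="session")
def coarse_acq(acq) -> AcquisitionParams:
    """Coarser voxels for segmentation-scale fields (faster rendering)."""
    return dataclasses.replace(acq, voxel_xy_nm=200.0, voxel_z_nm=400.0,
                               psf_sigma_lateral_nm=260.0,
                               psf_sigma_axial_nm=450.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
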