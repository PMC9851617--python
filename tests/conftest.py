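import numpy as np
import pytest

from somatomap import (CohortSpec, MeshSpec, NoiseSpec, ProtocolSpec,
                       build_flat_patch_mesh, define_rois)


@pytest.fixture(scope="session")
def grid6():
    return build_flat_patch_mesh(6, 6, 1.0)


@pytest.fixture(scope="session")
def default_mesh_rois():
    spec = MeshSpec()
    return spec.build()


@pytest.fixture
def tiny_spec():
    """Small, fast cohort spec for pipeline-level tests."""
    return CohortSpec(
        groups={"controls": 2, "amputees": 2, "one_handers": 2},
        mesh=MeshSpec(n_medial=7, n_lateral=21, spacing=1.0,
                      hand_extent=6.0, face_extent=14.0, rsa_gap=2.0),
        protocol=ProtocolSpec(runs=2, n_volumes=130),
        noise=NoiseSpec(temporal_sd=0.3, ar1=0.2, smooth_fwhm=1.5),
        blob_centres={"forehead": 2.0, "nose": 5.0, "lips": 8.0,
                      "tongue": 11.0, "thumb": -3.0},
        blob_width=2.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
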