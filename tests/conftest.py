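import numpy as np
import pytest

from mexpt2 import (
    AcquisitionProtocol,
    PhantomSpec,
    Region,
    SearchSpace,
    TISSUE_PRESETS,
    TissueClassSpec,
    generate_phantom,
)

ADIPOSE_PARAMS = dict(A1=504.0, T2_1=45.0, A2=751.0, T2_2=191.0)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol.default()


@pytest.fixture(scope="session")
def tes(protocol):
    return protocol.effective_tes


@pytest.fixture(scope="session")
def space():
    return SearchSpace()


def fixed_class(label, mono_fraction, mono=(500.0, 100.0),
                bi=(504.0, 45.0, 751.0, 191.0), dispersion=None):
    """Tissue class with zero dispersion unless stated (exact truth per voxel)."""
    return TissueClassSpec(
        label=label, mono_fraction=mono_fraction,
        mono_A=mono[0], mono_T2=mono[1],
        bi_A1=bi[0], bi_T2_1=bi[1], bi_A2=bi[2], bi_T2_2=bi[3],
        dispersion=dispersion or {},
    )


def one_region_phantom(cls, protocol, height=4, width=4, sigma=0.0,
                       noise_model="gaussian", seed=0, grid=(12, 12)):
    spec = PhantomSpec(
        grid_shape=grid,
        regions=((cls, Region("rect", (2, 2, height, width))),),
        background_sigma=sigma,
        noise_model=noise_model,
        protocol=protocol,
        seed=seed,
    )
    return generate_phantom(spec)
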