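import numpy as np
import pytest

from mwfcoupling.phantom import PhantomRegionValues, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def uniform_wm_phantom():
    """Noiseless phantom whose WM core has a single MWF/T1 value, so the
    adjacent-WM weighted mean round-trips exactly."""
    spec = PhantomSpec(
        grid_shape=(20, 20, 8),
        n_regions=4,
        margin_voxels=2,
        ribbon_thickness_voxels=2,
        region_values=tuple(
            PhantomRegionValues(mwf_gm=0.06 + 0.01 * k, mwf_wm=0.12, t1_gm_ms=1400.0, t1_wm_ms=900.0)
            for k in range(4)
        ),
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()
    return spec, generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
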