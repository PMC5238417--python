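import numpy as np
import pytest

import optimammo as om


@pytest.fixture(scope="session")
def geom():
    return om.SlabGeometry(thickness=4.0)


@pytest.fixture(scope="session")
def props():
    return om.OpticalProperties(mua=0.05, musp=10.0, wavelength=785)


@pytest.fixture(scope="session")
def time_grid():
    # 10 ps binning out to 12 ns; resolves the kernel convolution well
    return np.arange(5.0, 12000.0, 10.0)


@pytest.fixture(scope="session")
def spectra():
    return om.load_extinction_table()


@pytest.fixture(scope="session")
def paper_like_cohort():
    spec = om.preset_catalog()["paper-like-cohort"]
    return om.generate_cohort(spec)


@pytest.fixture(scope="session")
def null_phantom():
    """Small homogeneous phantom (no lesion): fast null case for mapping."""
    spec = om.PhantomSpec(
        grid_shape=(20, 20),
        lesion_dc=om.CompositionDelta(0.0, 0.0, 0.0, 0.0, 0.0),
        counts_per_pixel=2e5,
        t_max_ps=8000.0,
        dt_ps=20.0,
        seed=11,
    )
    return om.generate_phantom_scan(spec)
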