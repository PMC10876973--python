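import warnings

import pytest

from aperspectra.branching import (BranchingParams, build_network, simulate,
                                   attach_inhibitory, sttc_matrix)


@pytest.fixture(scope="session")
def small_branching_raster():
    """One subcritical (m=0.98) raster shared by the mapping tests."""
    params = BranchingParams(N=300, m=0.98, lam0=1.0, lam_i=5.0)
    targets, pos = build_network(params, 11)
    raster = simulate(targets, params, 40.0, 12, positions=pos)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raster = attach_inhibitory(raster, params, 13)
    return raster


@pytest.fixture(scope="session")
def small_sttc_matrix(small_branching_raster):
    return sttc_matrix(small_branching_raster)


@pytest.fixture(scope="session")
def subcritical_net_2000():
    """Large (N=2000) m=0.98 raster + STTC + embedding for dyad work: a
    large presynaptic pool keeps shared-wiring artifacts small."""
    from aperspectra.mapping import embed_on_sphere

    params = BranchingParams(N=2000, m=0.98, lam0=1.0, lam_i=5.0)
    targets, pos = build_network(params, 3)
    raster = simulate(targets, params, 40.0, 4, positions=pos)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raster = attach_inhibitory(raster, params, 5)
        corr = sttc_matrix(raster)
    return raster, corr, embed_on_sphere(corr, 0)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield
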