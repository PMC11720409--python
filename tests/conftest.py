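import pytest

import crossprot as cp


@pytest.fixture(scope="session")
def small_study() -> cp.SimulatedStudy:
    """A compact three-assay study shared across test modules."""
    config = cp.SimulationConfig(
        n_samples=300, n_proteins=400, n_soma_reagents=500,
        n_olink_reagents=150, seed=7)
    return cp.simulate_study(config)


@pytest.fixture(scope="session")
def harmonized(small_study) -> dict:
    """Study-sample-only, log2 + z-scored matrices of the small study."""
    out = {}
    for plat, m in small_study.matrices.items():
        pm = small_study.plate_maps[plat]
        out[plat] = cp.log2_zscale(m.subset_samples(pm.study_samples()))
    return out
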