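"""Shared fixtures.

The expensive Monte-Carlo products (banana LUTs and the reduced-scale
benchmark pipeline runs) are session-scoped and shared across the suite;
all randomness is seeded.
"""

import pytest

from mdoi.banana import build_banana_lut
from mdoi.phantoms import dermis_properties, make_phantom
from mdoi.pipeline import benchmark_config, run_pipeline, table1_phantom

SEED = 20260926


@pytest.fixture(scope="session")
def dermis():
    return dermis_properties(0.0)


@pytest.fixture(scope="session")
def pigment():
    return dermis_properties(0.2)


@pytest.fixture(scope="session")
def small_phantom(dermis):
    """Homogeneous dermis block at the default geometry."""
    return make_phantom(bulk_props=dermis)


@pytest.fixture(scope="session")
def lut_small(dermis):
    """Cheap banana LUT for structural checks (1e5 photons total)."""
    return build_banana_lut(dermis, n_photons=50_000, n_reps=2, seed=SEED)


@pytest.fixture(scope="session")
def lut_big(dermis):
    """Production-scale LUT (5 reps x 2e5 = 1e6 photons) shared by the
    symmetry property and the benchmark pipeline runs."""
    return build_banana_lut(dermis, n_photons=200_000, n_reps=5, seed=SEED)


def _run_case(depth_mm, lut, n_photons=100_000, **phantom_kwargs):
    cfg = benchmark_config(depth_mm, n_photons=n_photons, mc_seed=SEED)
    ph = table1_phantom(depth_mm, **phantom_kwargs)
    return ph, run_pipeline(ph, cfg, lut=lut)


@pytest.fixture(scope="session")
def case_05mm(lut_big):
    """Reduced-scale benchmark: 0.5 mm-deep surface cap, 5x5 points,
    1e5 photons per point."""
    return _run_case(0.5, lut_big)


@pytest.fixture(scope="session")
def case_1mm(lut_big):
    return _run_case(1.0, lut_big)


@pytest.fixture(scope="session")
def case_3mm(lut_big):
    return _run_case(3.0, lut_big)


@pytest.fixture(scope="session")
def case_subsurface(lut_big):
    """Buried cylinder (1-3 mm) at reduced photon count; the qualitative
    blurring/centering regressions only need moderate statistics."""
    from mdoi.pipeline import PipelineConfig
    cfg = PipelineConfig(roa_side_mm=12.0, n_photons=30_000, mc_seed=SEED)
    ph = table1_phantom(3.0, subsurface=True, depth_top_mm=1.0)
    return ph, run_pipeline(ph, cfg, lut=lut_big)


@pytest.fixture(scope="session")
def case_3mm_small_roa(lut_big):
    """3 mm feature reconstructed with an under-sized 4 mm ROA."""
    from mdoi.pipeline import PipelineConfig
    cfg = PipelineConfig(roa_side_mm=4.0, n_photons=30_000, mc_seed=SEED)
    ph = table1_phantom(3.0)
    return ph, run_pipeline(ph, cfg, lut=lut_big)


@pytest.fixture(scope="session")
def case_null(lut_big):
    """Featureless phantom; the relative volume should be ~1 everywhere."""
    from mdoi.pipeline import PipelineConfig
    cfg = PipelineConfig(roa_side_mm=12.0, n_photons=30_000, mc_seed=SEED,
                         grid_points=(3, 3))
    ph = make_phantom(bulk_props=dermis_properties(0.0))
    return ph, run_pipeline(ph, cfg, lut=lut_big, evaluate=False)
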