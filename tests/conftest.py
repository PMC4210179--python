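"""Shared fixtures.

Heavy computations used by several acceptance checks (the energy-audit
subset, the transmittance-vs-LAI sweep and the low-wave H^A_sat surface)
are session-scoped so they run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from seacanopy.bands import SpectralBands, ZenithGrid
from seacanopy.experiment import (DEFAULT_RESOLUTION, REDUCED_RESOLUTION,
                                  audit_subset, compute_hasat_surface,
                                  default_materials, make_fixtures,
                                  make_plant_pool, transmittance_validation)
from seacanopy.lightfield import (Site, WaterIOPs, clear_sky_radiance,
                                  diurnal_zeniths, propagate_water_column,
                                  top_of_canopy_radiance)
from seacanopy.morphology import assemble_canopy, facetize
from seacanopy.saturation import Ek

SEED = 1


@pytest.fixture(scope="session")
def bands():
    return SpectralBands()


@pytest.fixture(scope="session")
def zgrid():
    return ZenithGrid()


@pytest.fixture(scope="session")
def site():
    return Site()


@pytest.fixture(scope="session")
def iops(bands, site):
    return WaterIOPs.reference(bands, depth=site.depth)


@pytest.fixture(scope="session")
def materials(bands):
    return default_materials(bands)


@pytest.fixture(scope="session")
def midday_rad(site, iops, bands, zgrid):
    _, zens = diurnal_zeniths(site.latitude, site.date, 12)
    return top_of_canopy_radiance(site, float(zens.min()), iops, bands, zgrid)


@pytest.fixture(scope="session")
def plant_pool():
    return make_plant_pool(SEED)


@pytest.fixture(scope="session")
def small_canopy(plant_pool):
    """LAI ~1.5 canopy facetized at reduced resolution (fast solves)."""
    scene = assemble_canopy(plant_pool, target_lai=1.5, seed=SEED)
    return facetize(scene, REDUCED_RESOLUTION.max_facet_area)


@pytest.fixture(scope="session")
def fixtures_set():
    return make_fixtures(SEED)


# ---- heavy session-scoped computations (acceptance-grade) -----------------

@pytest.fixture(scope="session")
def audit_results():
    """Energy audits: 5 LAI x 3 structures at default resolution."""
    return audit_subset(seed=SEED, n_structures=3,
                        resolution=DEFAULT_RESOLUTION)


@pytest.fixture(scope="session")
def transmittance_points():
    """~25 fixture canopies, midday, low wave, reduced facet resolution."""
    return transmittance_validation(seed=SEED, n_points=25,
                                    resolution=REDUCED_RESOLUTION)


@pytest.fixture(scope="session")
def path_tracer_comparison(bands, zgrid, materials):
    """Solver vs independent forward path tracer on the 50-facet scene.

    Returns (solver absorbed power, oracle absorbed power, oracle MC SE).
    """
    import numpy as np

    from oracles import path_trace_absorbed
    from seacanopy.bands import DirectionalRadiance
    from seacanopy.experiment import random_facet_scene
    from seacanopy.radiosity import solve_canopy

    scene = facetize(random_facet_scene(50, seed=11), 2e-4)
    rad = DirectionalRadiance(bands, zgrid,
                              np.full((zgrid.n_bins, bands.n), 0.5))
    sol = solve_canopy(scene, rad, materials, seed=2, n_az=16,
                       n_scatter=64, tol=1e-6, max_iters=40)
    oracle_abs, se = path_trace_absorbed(scene, rad, materials,
                                         n_photons=3000, seed=21)
    return sol.ledger["absorbed_by_surfaces"], oracle_abs, se


@pytest.fixture(scope="session")
def hasat_surface_low(fixtures_set, site, iops):
    """Low-wave H^A_sat surface at E_k = 50 over the full design grid."""
    return compute_hasat_surface(fixtures_set.canopies, site, iops,
                                 ek=Ek(50.0), wave_mode="low",
                                 resolution=REDUCED_RESOLUTION, seed=SEED)
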