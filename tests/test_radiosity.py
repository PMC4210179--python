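"""Geometric-optics transfer: direct illumination, scattering, energy audit."""

import numpy as np
import pytest

from seacanopy.bands import DirectionalRadiance, SpectralBands, ZenithGrid
from seacanopy.experiment import (REDUCED_RESOLUTION, default_materials,
                                  opaque_slab_scene, random_facet_scene,
                                  single_leaf_scene, substrate_only_scene)
from seacanopy.materials import MaterialLibrary
from seacanopy.morphology import (ROLE_LEAF, ROLE_SUBSTRATE, build_scene,
                                  facetize)
from seacanopy.radiosity import (direct_illumination, energy_audit,
                                 fit_exponential_transmittance, leaf_field,
                                 solve_canopy, solve_scattering,
                                 substrate_transmittance)

from oracles import path_trace_absorbed


def _uniform_radiance(bands, zgrid, level=1.0):
    return DirectionalRadiance(
        bands, zgrid, np.full((zgrid.n_bins, bands.n), level))


class TestDirectIllumination:
    def test_single_horizontal_facet_receives_pi_L(self, bands):
        """Uniform sky radiance L -> incident pi*L, refined quadrature."""
        zg = ZenithGrid(90)
        rad = _uniform_radiance(bands, zg, 2.0)
        scene = facetize(single_leaf_scene(leaf_area=4e-4), 5e-5)
        first, _ = direct_illumination(scene, rad, n_az=24)
        leaf = scene.role == ROLE_LEAF
        up = first[leaf, 0, :]
        assert np.allclose(up, 2.0 * np.pi, rtol=0.005)

    def test_facet_beneath_opaque_slab_gets_nothing(self, bands, zgrid):
        scene = facetize(opaque_slab_scene(), 2e-4)
        rad = _uniform_radiance(bands, zgrid)
        first, _ = direct_illumination(scene, rad, n_az=8)
        sub = scene.role == ROLE_SUBSTRATE
        assert np.all(first[sub] == 0.0)

    def test_doubling_radiance_doubles_incident(self, small_canopy, midday_rad):
        f1, tr = direct_illumination(small_canopy, midday_rad, n_az=8)
        f2, _ = direct_illumination(small_canopy, midday_rad.scaled(2.0),
                                    n_az=8, tracer=tr)
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_unfacetized_scene_rejected(self, plant_pool, midday_rad):
        from seacanopy.morphology import assemble_canopy
        scene = assemble_canopy(plant_pool, target_lai=0.5, seed=7)
        with pytest.raises(ValueError):
            direct_illumination(scene, midday_rad)


class TestSolveScattering:
    def test_black_canopy_equals_first_order(self, small_canopy, midday_rad,
                                             bands):
        mats = MaterialLibrary.black(bands)
        first, tr = direct_illumination(small_canopy, midday_rad, n_az=8)
        sol = solve_scattering(small_canopy, mats, first, midday_rad,
                               tracer=tr)
        assert np.array_equal(sol.incident, first)
        assert sol.iterations == 1

    def test_linearity_in_boundary_radiance(self, small_canopy, midday_rad,
                                            materials):
        sol1 = solve_canopy(small_canopy, midday_rad, materials, seed=5)
        sol2 = solve_canopy(small_canopy, midday_rad.scaled(0.5), materials,
                            seed=5)
        nz = sol1.incident > 0
        assert np.allclose(sol2.incident[nz], 0.5 * sol1.incident[nz],
                           rtol=1e-9)

    def test_path_tracer_oracle_on_random_scene(self, path_tracer_comparison):
        """Solver's absorbed power matches an independent forward path
        tracer on the 50-facet random scene within 2 MC standard errors."""
        solver_abs, oracle_abs, se = path_tracer_comparison
        # allow the solver's own small discretisation error on top of MC SE
        assert abs(solver_abs - oracle_abs) <= 2.0 * se + 0.02 * oracle_abs


class TestEnergyAudit:
    def test_substrate_only_closed_form(self, bands, zgrid, materials):
        """No occluders: incident = reflected-to-sky + absorbed exactly."""
        scene = facetize(substrate_only_scene(), 2e-4)
        rad = _uniform_radiance(bands, zgrid)
        closure, sol = energy_audit(scene, materials, rad, seed=0)
        assert closure < 1e-6
        assert substrate_transmittance(sol) == pytest.approx(100.0, abs=1e-6)

    def test_conservative_materials_absorb_nothing(self, small_canopy,
                                                   midday_rad, bands):
        """rho + tau = 1 everywhere: closure holds with ~zero absorption."""
        lib = MaterialLibrary(bands)
        # substrate is a closed floor (rho 1): nothing leaves downward
        lib.add(0, np.ones(bands.n), np.zeros(bands.n))
        for mid in (1, 2, 3):
            lib.add(mid, np.full(bands.n, 0.5), np.full(bands.n, 0.5))
        sol = solve_canopy(small_canopy, midday_rad, lib, seed=3,
                           max_iters=200, tol=1e-12)
        led = sol.ledger
        assert led["absorbed_by_surfaces"] <= 1e-9 * led["incident"]
        closure = abs(led["incident"] - led["exitant_to_sky"]
                      - led["absorbed_by_surfaces"]) / led["incident"]
        assert closure <= 0.02

    def test_periodic_translation_invariance(self, plant_pool, midday_rad,
                                             materials):
        """Shifting all plants by one tile (with wrap) changes nothing."""
        from seacanopy.morphology import PlacedPlant, assemble_canopy
        base = assemble_canopy(plant_pool, target_lai=1.0, seed=8)
        shifted_plants = [
            PlacedPlant(p.mesh, np.array([(p.position[0] + base.tile_x)
                                          % base.tile_x, p.position[1]]))
            for p in base.plants
        ]
        shifted = build_scene(shifted_plants, (base.tile_x, base.tile_y))
        fa = facetize(base, 2e-4)
        fb = facetize(shifted, 2e-4)
        sa = solve_canopy(fa, midday_rad, materials, seed=4)
        sb = solve_canopy(fb, midday_rad, materials, seed=4)
        pa = leaf_field(sa).par
        pb = leaf_field(sb).par
        assert pa.size == pb.size
        # identical geometry modulo the periodic wrap: same statistics
        assert np.mean(pa) == pytest.approx(np.mean(pb), rel=0.02)
        assert np.median(pa) == pytest.approx(np.median(pb), rel=0.05)

    def test_monotone_occlusion(self, plant_pool, midday_rad, materials):
        """More leaf area never increases substrate transmittance."""
        trans = []
        for lai in (0.5, 2.0):
            from seacanopy.morphology import assemble_canopy
            sc = facetize(assemble_canopy(plant_pool, target_lai=lai, seed=9),
                          2e-4)
            sol = solve_canopy(sc, midday_rad, materials, seed=9)
            trans.append(substrate_transmittance(sol))
        assert trans[1] < trans[0]

    def test_opaque_slab_transmits_almost_nothing(self, bands, zgrid,
                                                  materials):
        scene = facetize(opaque_slab_scene(), 2e-4)
        rad = _uniform_radiance(bands, zgrid)
        sol = solve_canopy(scene, rad, materials, seed=0)
        assert substrate_transmittance(sol) <= 1.0


class TestTransmittanceFit:
    def test_exact_recovery(self):
        lai = np.linspace(0.2, 8, 20)
        y = 100.0 * np.exp(-0.29 * lai)
        b, r2 = fit_exponential_transmittance(np.column_stack([lai, y]))
        assert b == pytest.approx(0.29, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_golden_section_oracle(self):
        rng = np.random.default_rng(5)
        lai = np.linspace(0.3, 7, 15)
        y = 100.0 * np.exp(-0.31 * lai) * (1 + rng.normal(0, 0.05, 15))

        def sse(b):
            return float(((y - 100 * np.exp(-b * lai)) ** 2).sum())

        lo, hi = 0.05, 1.0
        gr = (np.sqrt(5) - 1) / 2
        for _ in range(200):
            c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
            if sse(c) < sse(d):
                hi = d
            else:
                lo = c
        oracle_b = 0.5 * (lo + hi)
        b, _ = fit_exponential_transmittance(np.column_stack([lai, y]))
        assert b == pytest.approx(oracle_b, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_transmittance([(1.0, 50.0), (2.0, 30.0)])

    def test_fixture_canopy_transmittance_follows_decay_law(
            self, fixtures_set, midday_rad, materials):
        """LAI 3.15 canopy transmits ~100 exp(-0.29*3.15) percent +/- 5."""
        sc = facetize(fixtures_set.canopies[3.15],
                      REDUCED_RESOLUTION.max_facet_area)
        sol = solve_canopy(sc, midday_rad, materials, seed=1)
        t = substrate_transmittance(sol)
        assert t == pytest.approx(100.0 * np.exp(-0.29 * 3.15), abs=5.0)
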