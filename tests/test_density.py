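"""Density synthesis, Fourier machinery, two-state simulation, occupancy."""

import numpy as np
import pytest

from groundstate.density import (
    B_MIN,
    DensityMap,
    ReflectionSet,
    calc_density,
    calc_structure_factors,
    cell_volume,
    default_grid,
    difference_map,
    estimate_occupancy,
    event_map,
    map_to_sf,
    model_map,
    orth_matrix,
    refine_residue_b,
    sf_to_map,
    simulate_two_state,
    structure_factors_at,
)
from groundstate.ensemble import bound_only_model
from groundstate.metrics import residue_mask
from groundstate.model import StructureModel

from conftest import atom

CELL = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)


def single_atom(occ=1.0, b=20.0, pos=(10, 10, 10), element="C"):
    return StructureModel(
        atoms=[atom("X1", element, "LIG", "L", 1, list(pos), occ=occ, b=b, het=True)],
        cell=CELL,
    )


# ------------------------------------------------------------------ real-space route

@pytest.mark.parametrize("occ, expected", [(1.0, 6.0), (0.5, 3.0)])
def test_density_integral_is_occupancy_times_electrons(occ, expected):
    m = single_atom(occ=occ)
    rho = calc_density(m, default_grid(CELL, 1.5), 1.5)
    assert rho.integral() == pytest.approx(expected, rel=0.01)


def test_density_superposition():
    a = single_atom(pos=(8, 10, 10))
    b = single_atom(pos=(13, 11, 9), element="N")
    both = StructureModel(atoms=[a.atoms[0].copy(), b.atoms[0].copy()], cell=CELL)
    grid = default_grid(CELL, 1.5)
    rho = calc_density(both, grid, 1.5)
    parts = calc_density(a, grid, 1.5).values + calc_density(b, grid, 1.5).values
    np.testing.assert_allclose(rho.values, parts, atol=1e-12)


def test_grid_too_coarse_rejected():
    with pytest.raises(ValueError, match="too coarse"):
        calc_density(single_atom(), (10, 10, 10), 1.5)


def test_real_space_and_fourier_routes_agree():
    """The Gaussian sum and the analytic Debye-Waller transform are a DFT pair."""
    m = StructureModel(
        atoms=[
            atom("C1", "C", "LIG", "L", 1, [9, 10, 11], occ=0.7, b=18.0, het=True),
            atom("N1", "N", "LIG", "L", 1, [11.5, 10, 10], occ=0.7, b=25.0, het=True),
        ],
        cell=CELL,
    )
    grid = default_grid(CELL, 1.5)
    full = map_to_sf(calc_density(m, grid, 1.5), None)
    analytic = calc_structure_factors(m, 1.5)
    ia, ib = full.common_with(analytic)
    np.testing.assert_allclose(full.f[ia], analytic.f[ib], atol=2e-4)


# ------------------------------------------------------------------ Fourier pair

def test_constant_map_has_only_f000():
    rho = DensityMap(np.full((8, 8, 8), 2.5), CELL)
    refl = map_to_sf(rho, None)
    zero = np.all(refl.hkl == 0, axis=1)
    assert refl.amplitude[zero][0] == pytest.approx(2.5 * cell_volume(CELL))
    assert np.max(refl.amplitude[~zero]) < 1e-9


def test_fft_roundtrip_identity():
    rng = np.random.default_rng(3)
    grid = (12, 10, 8)
    refl = map_to_sf(DensityMap(rng.normal(size=grid), CELL), None)
    rho = sf_to_map(refl, grid)
    back = sf_to_map(map_to_sf(rho, None), grid)
    assert np.max(np.abs(back.values - rho.values)) < 1e-8


def test_parseval_identity():
    rng = np.random.default_rng(4)
    grid = (12, 12, 12)
    rho = sf_to_map(map_to_sf(DensityMap(rng.normal(size=grid), CELL), None), grid)
    refl = map_to_sf(rho, None)
    # hemisphere + implicit Friedel mates: double everything except F(000)
    zero = np.all(refl.hkl == 0, axis=1)
    sum_f2 = 2 * np.sum(refl.amplitude[~zero] ** 2) + np.sum(refl.amplitude[zero] ** 2)
    integral_rho2 = np.sum(rho.values**2) * rho.voxel_volume
    assert sum_f2 == pytest.approx(cell_volume(CELL) * integral_rho2, rel=1e-6)


def test_translation_shifts_phases_only():
    m = single_atom(pos=(8, 9, 10))
    delta = np.array([1.3, -0.7, 2.1])
    shifted = m.copy()
    shifted.atoms[0].pos = m.atoms[0].pos + delta
    f0 = calc_structure_factors(m, 2.0)
    f1 = calc_structure_factors(shifted, 2.0)
    np.testing.assert_allclose(f0.amplitude, f1.amplitude, rtol=1e-10)
    frac = np.linalg.inv(orth_matrix(CELL)) @ delta
    expected = np.degrees(2 * np.pi * (f0.hkl @ frac))
    dphi = (f1.phase - f0.phase - expected + 180) % 360 - 180
    strong = f0.amplitude > 1e-6 * f0.amplitude.max()
    assert np.max(np.abs(dphi[strong])) < 1e-6


def test_single_gaussian_amplitude_closed_form():
    """|F| of one Gaussian atom equals occ*Z*exp(-B' s^2/4) exactly."""
    occ, b = 0.37, 23.0
    m = single_atom(occ=occ, b=b, element="O")
    refl = calc_structure_factors(m, 1.8)
    inv_d = 1.0 / refl.d_spacing
    inv_d[~np.isfinite(inv_d)] = 0.0
    expected = occ * 8 * np.exp(-(b + B_MIN) * inv_d**2 / 4.0)
    np.testing.assert_allclose(refl.amplitude, expected, rtol=1e-10)


def test_two_point_atom_interference_oracle():
    """Two-atom |F| from the hand-written two-Gaussian transform."""
    a1 = atom("C1", "C", "LIG", "L", 1, [8.0, 10.0, 10.0], occ=0.5, b=15.0, het=True)
    a2 = atom("O1", "O", "LIG", "L", 1, [12.0, 11.0, 9.0], occ=0.5, b=30.0, het=True)
    m = StructureModel(atoms=[a1, a2], cell=CELL)
    refl = calc_structure_factors(m, 2.0)
    inv_d = 1.0 / refl.d_spacing
    inv_d[~np.isfinite(inv_d)] = 0.0
    f = np.zeros(len(refl), dtype=complex)
    for at, z in ((a1, 6), (a2, 8)):
        frac = at.pos / 20.0  # orthogonal cubic cell
        f += (
            at.occupancy
            * z
            * np.exp(-(at.b_factor + B_MIN) * inv_d**2 / 4.0)
            * np.exp(2j * np.pi * (refl.hkl @ frac))
        )
    np.testing.assert_allclose(refl.amplitude, np.abs(f), rtol=1e-9)


# ------------------------------------------------------------------ simulation

def test_simulation_boundary_occupancies(noiseless_scenario):
    sc = noiseless_scenario
    obs0 = simulate_two_state(sc.ground, sc.bound, 0.0, 1.5, 0.0, seed=1)
    obs1 = simulate_two_state(sc.ground, sc.bound, 1.0, 1.5, 0.0, seed=1)
    for obs, model in ((obs0, sc.ground), (obs1, sc.bound)):
        calc = calc_structure_factors(model, 1.5)
        ia, ib = obs.common_with(calc)
        assert len(ia) == len(obs)  # F(000) is absent from observed data
        np.testing.assert_allclose(obs.amplitude[ia], calc.amplitude[ib], rtol=1e-12)


def test_mixture_amplitudes_are_weighted_complex_sum(noiseless_scenario):
    sc = noiseless_scenario
    q = 0.31
    obs = simulate_two_state(sc.ground, sc.bound, q, 1.5, 0.0, seed=0)
    fg = structure_factors_at(sc.ground, obs.hkl)
    fb = structure_factors_at(sc.bound, obs.hkl)
    np.testing.assert_allclose(obs.amplitude, np.abs((1 - q) * fg + q * fb), rtol=1e-12)


def test_free_flags_cover_about_five_percent():
    sc_obs = simulate_two_state(single_atom(), single_atom(pos=(11, 10, 10)), 0.5, 1.2, 0.0, seed=5)
    frac = sc_obs.free_flag.mean()
    assert 0.02 < frac < 0.09


# ------------------------------------------------------------------ maps

def test_difference_map_self_consistency(noiseless_scenario):
    sc = noiseless_scenario
    obs = simulate_two_state(sc.ground, sc.ground, 0.0, 1.5, 0.0, seed=0)
    grid = default_grid(CELL[:3] + CELL[3:], 1.5)
    grid = default_grid(sc.ground.cell, 1.5)
    diff, total = difference_map(obs, sc.ground, grid)
    assert diff.values.std() < 1e-6 * total.values.std()


def test_positive_difference_density_at_omitted_ground_atoms(noiseless_scenario):
    """A ligand-only model leaves (1-q) of the ground state unexplained."""
    sc = noiseless_scenario
    grid = default_grid(sc.ground.cell, 1.5)
    bo = bound_only_model(sc.ensemble)
    diff, _ = difference_map(sc.observed, bo, grid)
    mask = residue_mask(sc.ground, sc.ground_residue, grid, 1.5)
    omitted = calc_density(
        StructureModel(
            atoms=[a.copy() for a in sc.ground.atoms if (a.chain, a.res_seq) == sc.ground_residue],
            cell=sc.ground.cell,
        ),
        grid,
        1.5,
    )
    assert np.mean(diff.values[mask]) > 3 * diff.sigma()
    # away from the (over-occupied) ligand, the difference density tracks the
    # omitted ground-state density closely
    away = mask & ~residue_mask(sc.bound, sc.ligand_residue, grid, 2.0)
    corr = np.corrcoef(diff.values[away], omitted.values[away])[0, 1]
    assert corr > 0.8


def test_normalized_maps_are_scale_invariant(noiseless_scenario):
    sc = noiseless_scenario
    grid = default_grid(sc.ground.cell, 1.5)
    obs10 = ReflectionSet(
        sc.observed.hkl, sc.observed.amplitude * 10, sc.observed.phase,
        sc.observed.cell, sc.observed.free_flag,
    )
    d1, t1 = difference_map(sc.observed, sc.bound, grid)
    d10, t10 = difference_map(obs10, sc.bound, grid)
    np.testing.assert_allclose(d10.values / d10.sigma(), d1.values / d1.sigma(), atol=1e-9)
    np.testing.assert_allclose(t10.values / t10.sigma(), t1.values / t1.sigma(), atol=1e-9)


def test_event_map_exact_cancellation(noiseless_scenario):
    sc = noiseless_scenario
    q = sc.spec.q_true
    grid = default_grid(sc.ground.cell, 1.5)
    g_map = model_map(sc.ground, grid, 1.5)
    b_map = model_map(sc.bound, grid, 1.5)
    obs_map = DensityMap((1 - q) * g_map.values + q * b_map.values, sc.ground.cell, "obs")
    ev = event_map(obs_map, g_map, bdc=1 - q)
    np.testing.assert_allclose(ev.values, b_map.values, atol=1e-10)
    assert ev.label == "event"


def test_event_map_bdc_zero_is_identity(noiseless_scenario):
    sc = noiseless_scenario
    grid = default_grid(sc.ground.cell, 1.5)
    g_map = model_map(sc.ground, grid, 1.5)
    ev = event_map(g_map, model_map(sc.bound, grid, 1.5), bdc=0.0)
    np.testing.assert_allclose(ev.values, g_map.values)


def test_event_map_grid_mismatch_rejected():
    a = DensityMap(np.zeros((8, 8, 8)), CELL)
    b = DensityMap(np.zeros((8, 8, 10)), CELL)
    with pytest.raises(ValueError, match="grid"):
        event_map(a, b, 0.5)


def test_noisy_event_map_beats_obs_map_at_ligand(scenario):
    """Subtracting the ground fraction reveals the bound state better than
    the raw observed map does (the whole point of the event map)."""
    sc = scenario
    q = sc.spec.q_true
    grid = default_grid(sc.ground.cell, 1.5)
    g_map = model_map(sc.ground, grid, 1.5)
    b_map = model_map(sc.bound, grid, 1.5)
    _, total = difference_map(sc.observed, sc.ensemble.model, grid)
    mask = residue_mask(sc.bound, sc.ligand_residue, grid, 2.0)
    ev = event_map(total, g_map, bdc=1 - q)

    def corr(m):
        return np.corrcoef(m.values[mask], b_map.values[mask])[0, 1]

    assert corr(ev) > corr(total)


# ------------------------------------------------------------------ occupancy

def test_noiseless_occupancy_recovery(noiseless_scenario):
    sc = noiseless_scenario
    est = estimate_occupancy(sc.observed, sc.ground, sc.bound)
    assert est.q_hat == pytest.approx(0.40, abs=0.01)


def test_occupancy_zero_for_pure_ground(noiseless_scenario):
    sc = noiseless_scenario
    obs = simulate_two_state(sc.ground, sc.bound, 0.0, 1.5, 0.0, seed=2)
    est = estimate_occupancy(obs, sc.ground, sc.bound)
    assert est.q_hat <= 0.01


def test_occupancy_unbiased_across_range_noiseless(noiseless_scenario):
    sc = noiseless_scenario
    for q in np.arange(0.1, 0.95, 0.2):
        obs = simulate_two_state(sc.ground, sc.bound, q, 1.5, 0.0, seed=3)
        est = estimate_occupancy(obs, sc.ground, sc.bound)
        assert est.q_hat == pytest.approx(q, abs=0.01)


def test_degenerate_states_warn_and_return_nan(noiseless_scenario):
    sc = noiseless_scenario
    obs = simulate_two_state(sc.ground, sc.ground, 0.5, 1.5, 0.0, seed=0)
    with pytest.warns(UserWarning, match="ill-posed|identically"):
        est = estimate_occupancy(obs, sc.ground, sc.ground)
    assert np.isnan(est.q_hat)


def test_b_inflation_absorbs_occupancy_error(scenario):
    """The B/occupancy trade-off: a ligand modelled at too high occupancy
    fits the amplitudes best with strongly inflated B factors; the correct
    ensemble needs no inflation."""
    sc = scenario
    bo = bound_only_model(sc.ensemble)
    db_bo, _ = refine_residue_b(sc.observed, bo, sc.ligand_residue)
    db_ens, _ = refine_residue_b(sc.observed, sc.ensemble.model, sc.ligand_residue)
    assert db_bo > 10.0
    assert abs(db_ens) <= 5.0


# ------------------------------------------------------------------ file formats

def test_hkl_text_roundtrip(tmp_path, noiseless_scenario):
    obs = noiseless_scenario.observed
    path = tmp_path / "obs.hkl"
    obs.write_hkl(str(path))
    back = ReflectionSet.read_hkl(str(path))
    np.testing.assert_array_equal(back.hkl, obs.hkl)
    # the table stores 6 decimals, so precision is absolute, not relative
    np.testing.assert_allclose(back.amplitude, obs.amplitude, atol=1e-5)
    np.testing.assert_array_equal(back.free_flag, obs.free_flag)
    assert np.all(np.isnan(back.phase))  # amplitude-only data stay amplitude-only


def test_mtz_roundtrip(tmp_path, noiseless_scenario):
    refl = calc_structure_factors(noiseless_scenario.ground, 2.0)
    path = tmp_path / "calc.mtz"
    refl.write_mtz(str(path))
    back = ReflectionSet.read_mtz(str(path))
    ia, ib = refl.common_with(back)
    assert len(ia) == len(refl)
    np.testing.assert_allclose(back.amplitude[ib], refl.amplitude[ia], rtol=1e-5)
    dphi = (back.phase[ib] - refl.phase[ia] + 180) % 360 - 180
    assert np.max(np.abs(dphi[refl.amplitude[ia] > 1e-4])) < 1e-2


def test_ccp4_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    rho = DensityMap(rng.normal(size=(10, 12, 14)), CELL, label="obs")
    path = tmp_path / "map.ccp4"
    rho.write_ccp4(str(path))
    back = DensityMap.read_ccp4(str(path))
    np.testing.assert_allclose(back.values, rho.values, atol=1e-5)
    assert back.cell == pytest.approx(rho.cell)
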