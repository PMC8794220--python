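"""Boltzmann inversion, averaging, minima, power-law repulsion, scoring."""

import numpy as np
import pytest

from florypot.errors import ConsistencyError, FitRangeError, InsufficientStatisticsError
from florypot.fragments import FragmentSet, filter_by_terminal_types
from florypot.io_structures import CoarseGrainLevel
from florypot.kde import EmpiricalDensity, cross_validate_bandwidth, empirical_density
from florypot.maxwell import MaxwellFit, fit_kuhn_length, maxwell_pdf
from florypot.potential import (
    PotentialCurve,
    StatisticalPotential,
    average_potential,
    boltzmann_inversion,
    default_grid,
    derive_potentials,
    derive_sequence_dependent,
    find_minima,
    fit_repulsive_power_law,
    score_structure,
)
from florypot.synthetic import (
    gaussian_well,
    generate_gaussian_chain,
    sample_reweighted_maxwell,
)


def _density_from_pdf(pdf_values, m, n=10**9, grid=None, level=CoarseGrainLevel.CA):
    grid = default_grid() if grid is None else grid
    return EmpiricalDensity(m=m, w=0.1, n=n, grid=grid, density=pdf_values,
                            level=level)


def _sp_from_curve(values, grid=None, spread=None, m_range=(70, 90)):
    grid = default_grid() if grid is None else grid
    return StatisticalPotential(
        level=None, grid=grid, per_m_curves={},
        average=np.asarray(values, float),
        spread=np.zeros_like(grid) if spread is None else spread,
        m_range=m_range, kind="flory_70_90",
    )


def test_inversion_of_reference_is_zero():
    b, m = 3.67, 70
    grid = default_grid()
    E = _density_from_pdf(maxwell_pdf(grid, b, m), m)
    ref = MaxwellFit(m=m, b=b, sigma_b=0.01, n=10**9, level=CoarseGrainLevel.CA)
    V = boltzmann_inversion(E, ref)
    defined = np.isfinite(V.values)
    assert defined.sum() > 100
    np.testing.assert_allclose(V.values[defined], 0.0, atol=1e-12)


def test_inversion_m_mismatch_raises():
    grid = default_grid()
    E = _density_from_pdf(maxwell_pdf(grid, 3.67, 70), 70)
    with pytest.raises(ConsistencyError):
        boltzmann_inversion(E, MaxwellFit(m=71, b=3.67, sigma_b=0.01, n=10))


def test_inversion_support_threshold_masks_sparse_regions():
    b, m = 3.67, 70
    grid = default_grid()
    E = _density_from_pdf(maxwell_pdf(grid, b, m), m, n=1000)
    ref = MaxwellFit(m=m, b=b, sigma_b=0.01, n=1000)
    V = boltzmann_inversion(E, ref)
    thr = 5.0 / (0.1 * 1000)
    assert np.all(np.isnan(V.values[maxwell_pdf(grid, b, m) < thr]))


def test_injected_well_recovered_after_gauge_fixing():
    """Known attractive well reweighting the reference is recovered to < 0.1 kBT RMS."""
    b, m, n = 3.67, 70, 100_000
    U = gaussian_well(depth=1.0, center=6.0, width=2.0)
    fs = sample_reweighted_maxwell(m, b, U, n, seed=31)
    w = cross_validate_bandwidth(fs, seed=1)
    E = empirical_density(fs, w)
    V = boltzmann_inversion(E, fit_kuhn_length(fs))
    defined = np.isfinite(V.values)
    u_true = U(V.grid[defined])
    v = V.values[defined] - V.values[defined].mean()
    u = u_true - u_true.mean()
    rms = np.sqrt(np.mean((v - u) ** 2))
    assert rms < 0.1


def test_average_identical_curves_zero_spread():
    grid = default_grid()
    vals = np.sin(grid)
    curves = {m: PotentialCurve(m=m, grid=grid, values=vals.copy())
              for m in range(70, 75)}
    sp = average_potential(curves, (70, 74))
    np.testing.assert_allclose(sp.average, vals)
    np.testing.assert_allclose(sp.spread, 0.0, atol=1e-15)


def test_average_two_opposite_curves_population_sd():
    grid = default_grid()
    curves = {
        1: PotentialCurve(m=1, grid=grid, values=np.ones_like(grid)),
        2: PotentialCurve(m=2, grid=grid, values=-np.ones_like(grid)),
    }
    sp = average_potential(curves, (1, 2))
    np.testing.assert_allclose(sp.average, 0.0, atol=1e-15)
    np.testing.assert_allclose(sp.spread, 1.0)  # population sd, not ddof=1


def test_average_restricted_to_common_support():
    grid = default_grid()
    v1 = np.ones_like(grid)
    v2 = np.ones_like(grid)
    v1[:50] = np.nan
    v2[-50:] = np.nan
    sp = average_potential(
        {1: PotentialCurve(1, grid, v1), 2: PotentialCurve(2, grid, v2)}, (1, 2)
    )
    assert np.isnan(sp.average[:50]).all() and np.isnan(sp.average[-50:]).all()
    assert np.isfinite(sp.average[50:-50]).all()


def test_spread_shrinks_with_sample_size():
    b, m_range = 3.67, (70, 74)
    U = gaussian_well(depth=1.0, center=10.0, width=2.0)

    def spread_at(n, seed0):
        sets = {
            m: sample_reweighted_maxwell(m, b, U, n, seed=seed0 + m)
            for m in range(m_range[0], m_range[1] + 1)
        }
        sp = derive_potentials(sets, 1.0, m_range, kind="flory_70_90")
        assert np.isfinite(sp.spread).any()
        return np.nanmean(sp.spread)

    assert spread_at(50_000, 100) < spread_at(4_000, 200)


def test_find_minima_parabola_vertex():
    grid = default_grid()
    sp = _sp_from_curve((grid - 5.0) ** 2)
    res = find_minima(sp)
    assert len(res.minima) == 1
    pos, depth = res.minima[0]
    assert pos == pytest.approx(5.0, abs=1e-9)
    assert depth == pytest.approx(0.0, abs=1e-9)


def test_find_minima_monotone_curve_empty():
    grid = default_grid()
    sp = _sp_from_curve(np.exp(-grid))
    assert find_minima(sp).minima == []


def test_find_minima_double_well():
    grid = default_grid()
    v = (
        -1.5 * np.exp(-0.5 * ((grid - 8.0) / 1.0) ** 2)
        - 0.7 * np.exp(-0.5 * ((grid - 16.0) / 1.5) ** 2)
    )
    res = find_minima(_sp_from_curve(v))
    positions = [p for p, _ in res.minima]
    assert len(positions) == 2
    assert positions[0] == pytest.approx(8.0, abs=0.1)
    assert positions[1] == pytest.approx(16.0, abs=0.1)
    assert res.minima[0][1] == pytest.approx(-1.5, abs=0.02)


def test_find_minima_suppresses_sub_spread_wiggles():
    grid = default_grid()
    v = 0.02 * np.cos(grid * 4.0)
    sp = _sp_from_curve(v, spread=np.full_like(grid, 0.5))
    assert find_minima(sp).minima == []


@pytest.mark.parametrize("prefactor,exponent", [(1.0, -6.0), (2.0, -3.0)])
def test_power_law_fit_exact(prefactor, exponent):
    grid = default_grid()
    v = np.full_like(grid, np.nan)
    window = (grid >= 2.0) & (grid <= 6.0)
    v[window] = prefactor * grid[window] ** exponent
    sp = _sp_from_curve(v)
    fit = fit_repulsive_power_law(sp, fit_range=(2.0, 6.0))
    assert fit.exponent == pytest.approx(exponent, abs=1e-9)
    assert fit.prefactor == pytest.approx(prefactor, rel=1e-9)


def test_power_law_default_window_stops_below_one_kbt():
    grid = default_grid()
    v = np.full_like(grid, np.nan)
    window = (grid >= 2.0) & (grid <= 20.0)
    v[window] = (grid[window] / 4.0) ** -6.0
    fit = fit_repulsive_power_law(_sp_from_curve(v))
    # V = (R/4)^-6 crosses 1 kBT at R = 4; the window ends at the first
    # grid point strictly below 1 kBT (4.1 on the 0.1 Å grid)
    assert fit.fit_range == (pytest.approx(2.0), pytest.approx(4.1))
    assert fit.exponent == pytest.approx(-6.0, abs=1e-9)


def test_power_law_rejects_nonpositive_values():
    grid = default_grid()
    v = 1.0 - grid / 10.0
    with pytest.raises(FitRangeError):
        fit_repulsive_power_law(_sp_from_curve(v), fit_range=(2.0, 15.0))


def test_seqdep_identity_when_filter_covers_everything():
    from florypot.fragments import collect_distances

    chains = [
        generate_gaussian_chain(400, seed=40 + i, aa_types=["ALA"] * 400)
        for i in range(12)
    ]
    sets = collect_distances(chains, (30, 33), CoarseGrainLevel.CA)
    restricted = {m: filter_by_terminal_types(sets[m], "ALA", "ALA") for m in sets}
    sp_all = derive_potentials(sets, 1.0, (30, 33), kind="broad_30_90")
    sp_pair = derive_sequence_dependent(restricted, 1.0, ("ALA", "ALA"),
                                        m_range=(30, 33), min_count_per_m=50)
    np.testing.assert_allclose(sp_pair.average, sp_all.average, equal_nan=True)


def test_seqdep_recovers_type_dependent_wells():
    """Pairs reweighted by distinct potentials separate in the fitted direction."""
    b, n = 3.67, 40_000
    m_range = (40, 42)
    attract = gaussian_well(depth=1.2, center=10.0, width=2.0)

    def repel(R):
        return -attract(R)

    def labelled(fs, aa):
        return FragmentSet(
            m=fs.m, level=fs.level, distances=fs.distances,
            terminal_types=np.tile([aa, aa], (fs.n, 1)),
        )

    cys = {
        m: labelled(sample_reweighted_maxwell(m, b, attract, n, seed=m), "CYS")
        for m in range(*m_range, 1)
    }
    glu = {
        m: labelled(sample_reweighted_maxwell(m, b, repel, n, seed=500 + m), "GLU")
        for m in range(*m_range, 1)
    }
    sp_cys = derive_sequence_dependent(cys, 0.8, ("CYS", "CYS"), m_range=m_range)
    sp_glu = derive_sequence_dependent(glu, 0.8, ("GLU", "GLU"), m_range=m_range)
    at_well = np.abs(sp_cys.grid - 10.0) < 1.0
    both = np.isfinite(sp_cys.average) & np.isfinite(sp_glu.average) & at_well
    assert both.any()
    # gauge: compare each to its own mean over the shared support
    shared = np.isfinite(sp_cys.average) & np.isfinite(sp_glu.average)
    v_cys = sp_cys.average - np.nanmean(sp_cys.average[shared])
    v_glu = sp_glu.average - np.nanmean(sp_glu.average[shared])
    assert v_cys[both].mean() < -0.5
    assert v_glu[both].mean() > 0.5


def test_seqdep_insufficient_statistics_names_pair():
    empty = {
        40: FragmentSet(m=40, level=CoarseGrainLevel.CA,
                        distances=np.array([5.0] * 3),
                        terminal_types=np.tile(["TRP", "TRP"], (3, 1)))
    }
    with pytest.raises(InsufficientStatisticsError, match="TRP"):
        derive_sequence_dependent(empty, 1.0, ("TRP", "TRP"),
                                  m_range=(30, 90), min_count_per_m=50)


def test_score_zero_potential_gives_zero():
    grid = default_grid()
    chain = generate_gaussian_chain(50, seed=1)
    sp = _sp_from_curve(np.zeros_like(grid), m_range=(1, 100))
    ts = score_structure(chain, sp, CoarseGrainLevel.CA)
    assert ts.v_tot == 0.0
    assert ts.v_tot == pytest.approx(sum(c[3] for c in ts.contributions))


def test_score_three_residue_chain_hand_summed():
    grid = default_grid()
    vals = np.full_like(grid, np.nan)
    vals[(grid >= 1.0) & (grid <= 15.0)] = 2.0
    curve = PotentialCurve(m=1, grid=grid, values=vals)
    sp = StatisticalPotential(
        level=None, grid=grid, per_m_curves={1: curve},
        average=vals, spread=np.zeros_like(grid), m_range=(1, 1),
        kind="flory_70_90",
    )
    chain = generate_gaussian_chain(3, seed=7)
    ts = score_structure(chain, sp, CoarseGrainLevel.CA)
    # two pairs at separation 1, each contributing exactly 2.0; the m=2 pair skipped
    assert ts.v_tot == pytest.approx(4.0)
    assert ts.n_skipped_pairs == 1


def test_score_matches_brute_force_double_loop():
    grid = default_grid()
    rng = np.random.default_rng(17)
    curves = {}
    for m in range(30, 50):
        vals = rng.normal(size=grid.size) * 0.3
        vals[:30] = np.nan  # undefined short-distance region
        curves[m] = PotentialCurve(m=m, grid=grid, values=vals)
    sp = StatisticalPotential(
        level=None, grid=grid, per_m_curves=curves,
        average=np.zeros_like(grid), spread=np.zeros_like(grid),
        m_range=(30, 49), kind="flory_70_90",
    )
    chain = generate_gaussian_chain(200, seed=23)
    ts = score_structure(chain, sp, CoarseGrainLevel.CA)
    X = chain.ca_array()
    total = 0.0
    n_pairs = 0
    for i in range(200):
        for j in range(i + 1, 200):
            m = j - i
            if m not in curves:
                continue
            d = float(np.linalg.norm(X[j] - X[i]))
            defined = np.isfinite(curves[m].values)
            total += float(
                np.interp(d, grid[defined], curves[m].values[defined])
            )
            n_pairs += 1
    assert ts.v_tot == pytest.approx(total, abs=1e-10)
    assert len(ts.contributions) == n_pairs


def test_potential_tsv_round_trip(tmp_path):
    grid = default_grid()
    v = np.exp(-((grid - 8) ** 2))
    sp = _sp_from_curve(v)
    sp.level = CoarseGrainLevel.CA
    from florypot.potential import potential_from_tsv, potential_to_tsv

    path = tmp_path / "pot.tsv"
    potential_to_tsv(sp, path, sidecar=tmp_path / "pot.json",
                     minima=find_minima(sp))
    back = potential_from_tsv(path)
    np.testing.assert_allclose(back.average, sp.average, rtol=1e-9)
    assert back.level == CoarseGrainLevel.CA
    assert back.m_range == sp.m_range
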