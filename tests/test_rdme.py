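"""Stochastic reaction-transport simulator: exactness and convergence."""

import numpy as np
import pytest

import hesnotch as hn
from hesnotch import ode_grid, rdme


TINY = 1e-12


def _linear_only(params):
    """Switch off everything upstream of Ngn2 so that n is a pure
    birth-death process (production alpha_n V, degradation mu_n)."""
    return params.replace(
        alpha_D=TINY, alpha_N=TINY, alpha_M=TINY, alpha_P=TINY, intervals={}
    )


class TestBuildNetwork:
    def test_origin_propensities(self, params):
        net = rdme.build_network(params, 50.0)
        props = net.propensities(np.zeros(6, dtype=np.int64))
        assert props[3] == pytest.approx(params.alpha_n * 50.0 * rdme.MOLECULES_PER_UM_UM3)
        mask = np.ones(11, dtype=bool)
        mask[3] = False
        assert np.allclose(props[mask], 0.0)

    def test_hill_propensities_vanish_at_large_protein(self, params):
        net = rdme.build_network(params, 50.0)
        counts = np.array([10, 10, 10, 10**9, 10, 10], dtype=np.int64)
        props = net.propensities(counts)
        assert props[1] < 1e-3  # repressed mRNA production
        assert props[3] < 1e-6  # repressed Ngn2 production

    def test_interior_transport_proportions(self, params, grid_10x10_zero):
        net = rdme.build_network(params, 50.0, grid_10x10_zero)
        interior = 5 * 10 + 5
        targets, qs, sink = net.q(interior)
        assert targets.size == 6
        assert np.allclose(qs, 1 / 6)
        assert sink == pytest.approx(0.0, abs=1e-12)

    def test_boundary_sink_completes_unity(self, params, grid_10x10_zero):
        net = rdme.build_network(params, 50.0, grid_10x10_zero)
        for k in (0, 9, 55):
            _, qs, sink = net.q(k)
            assert qs.sum() + sink == pytest.approx(1.0)

    def test_volume_must_be_positive(self, params):
        with pytest.raises(ValueError):
            rdme.build_network(params, 0.0)


class TestCountsToConcentration:
    def test_zero_and_linearity(self):
        assert rdme.counts_to_concentration(0, 50.0) == 0.0
        assert rdme.counts_to_concentration(200, 50.0) == pytest.approx(
            2 * rdme.counts_to_concentration(100, 50.0)
        )

    def test_reference_cell_count(self):
        # ~8104 molecules in a 50 um^3 cell is ~0.27 uM
        assert rdme.counts_to_concentration(8104, 50.0) == pytest.approx(0.269, abs=0.002)


class TestInitialCounts:
    def test_deterministic_and_integer(self, params, grid_10x10_zero):
        a = rdme.synthetic_initial_counts(grid_10x10_zero, 50.0, 4, params=params)
        b = rdme.synthetic_initial_counts(grid_10x10_zero, 50.0, 4, params=params)
        assert np.array_equal(a, b)
        assert a.dtype == np.int64
        assert a.min() >= 0
        assert np.all(a[:, 5] == 0)  # transport species starts empty

    def test_stochastic_rounding_preserves_expectation(self, params):
        big = hn.build_hex_lattice(30, 30, "zero")
        counts = rdme.synthetic_initial_counts(big, 50.0, 1, params=params)
        conc = ode_grid.synthetic_initial_conditions(big, None, 1, params=params)
        ref = ode_grid.homogeneous_stationary_state(params)
        expected = np.array([ref[s] / 2 for s in hn.SPECIES]) * 50.0 * rdme.MOLECULES_PER_UM_UM3
        assert np.allclose(counts[:, :5].mean(axis=0), expected, rtol=0.08)


class TestSsaSimulate:
    def test_seeded_determinism(self, params):
        lat = hn.build_hex_lattice(3, 3, "periodic")
        net = rdme.build_network(params, 5.0, lat)
        init = rdme.synthetic_initial_counts(lat, 5.0, 1, params=params)
        t1 = rdme.ssa_simulate(lat, net, init.copy(), 100.0, seed=9)
        t2 = rdme.ssa_simulate(lat, net, init.copy(), 100.0, seed=9)
        t3 = rdme.ssa_simulate(lat, net, init.copy(), 100.0, seed=10)
        assert np.array_equal(t1.X, t2.X)
        assert not np.array_equal(t1.X, t3.X)

    def test_counts_stay_non_negative_integers(self, params):
        lat = hn.build_hex_lattice(3, 3, "zero")
        net = rdme.build_network(params, 2.0, lat)
        init = rdme.synthetic_initial_counts(lat, 2.0, 2, params=params)
        traj = rdme.ssa_simulate(lat, net, init, 300.0, seed=5, output_dt=5.0)
        assert traj.X.min() >= 0
        assert np.issubdtype(traj.X.dtype, np.integer)

    def test_causal_activation_order_from_empty_state(self, params):
        # starting from nothing, constitutive Ngn2 must appear before Dll1,
        # which precedes the transported signal and the downstream chain
        lat = hn.build_hex_lattice(2, 2, "periodic")
        net = rdme.build_network(params, 1.0, lat)
        init = np.zeros((4, 6), dtype=np.int64)
        traj = rdme.ssa_simulate(lat, net, init, 400.0, seed=3, output_dt=0.5)
        totals = traj.X.sum(axis=1)  # per time, per species

        def first_seen(idx):
            nz = np.nonzero(totals[:, idx])[0]
            return traj.t[nz[0]] if nz.size else np.inf

        t_n = first_seen(4)
        t_D = first_seen(0)
        t_Din = first_seen(5)
        t_N = first_seen(1)
        t_M = first_seen(2)
        t_P = first_seen(3)
        assert t_n <= t_D <= t_Din <= t_N <= t_M <= t_P < np.inf

    def test_transport_conserves_signal_molecules(self, params):
        # with all other channels switched off, every transport event moves
        # exactly one D_in molecule into one Notch molecule of a neighbour
        lat = hn.build_hex_lattice(1, 2, "periodic")
        p = params.replace(
            alpha_D=TINY, alpha_M=TINY, alpha_P=TINY, alpha_n=TINY,
            mu_D=TINY, mu_N=TINY, mu_M=TINY, mu_P=TINY, mu_n=TINY, intervals={},
        )
        net = rdme.build_network(p, 10.0, lat)
        init = np.zeros((2, 6), dtype=np.int64)
        init[0, 5] = 500
        traj = rdme.ssa_simulate(lat, net, init, 5.0, seed=1, output_dt=0.1)
        # D_in drains from voxel 0 exclusively into N of voxel 1
        assert np.all(traj.X[:, 0, 5] + traj.X[:, 1, 1] == 500)
        assert np.all(traj.X[:, 0, 1] == 0)
        assert traj.X[-1, 0, 5] < 500

    def test_invalid_initial_counts(self, params, two_cell):
        net = rdme.build_network(params, 1.0, two_cell)
        with pytest.raises(ValueError):
            rdme.ssa_simulate(two_cell, net, np.zeros((2, 6)), 10.0, seed=1)
        bad = np.zeros((2, 6), dtype=np.int64)
        bad[0, 0] = -1
        with pytest.raises(ValueError):
            rdme.ssa_simulate(two_cell, net, bad, 10.0, seed=1)


class TestBirthDeathExactness:
    def test_stationary_moments_match_closed_form(self, params):
        # single voxel, linear channels only: n is a birth-death process
        # with Poisson stationary law (mean = variance = alpha_n V / mu_n)
        lat = hn.build_hex_lattice(1, 1, "zero")
        p = _linear_only(params)
        V = 2.0
        net = rdme.build_network(p, V, lat)
        init = np.zeros((1, 6), dtype=np.int64)
        target = p.alpha_n * V * rdme.MOLECULES_PER_UM_UM3 / p.mu_n
        traj = rdme.ssa_simulate(lat, net, init, 30_000.0, seed=8, output_dt=1.0)
        burn = traj.t > 300.0
        samples = traj.X[burn, 0, 4].astype(float)
        tau = 1.0 / p.mu_n  # autocorrelation time of the OU-like process
        n_eff = samples.size * 1.0 / (2 * tau)
        mean_err = 3 * np.sqrt(target / n_eff)
        assert samples.mean() == pytest.approx(target, abs=mean_err)
        var_err = 3 * target * np.sqrt(2 / n_eff)
        assert samples.var() == pytest.approx(target, abs=var_err)


class TestSystemSizeConvergence:
    def test_mean_trajectory_approaches_ode_with_volume(self, params):
        # the per-cell concentration process converges to the deterministic
        # dynamics as the voxel volume grows
        lat = hn.build_hex_lattice(3, 3, "zero")
        conc0 = ode_grid.synthetic_initial_conditions(lat, None, 6, params=params)
        traj_ode = ode_grid.simulate_ode(lat, params, conc0, 400.0, output_dt=10.0)
        ode_mean = traj_ode.species("P").mean(axis=1)

        errors = []
        for V in (1.0, 10.0, 50.0):
            net = rdme.build_network(params, V, lat)
            runs = []
            for rep in range(2):
                mols = conc0 * V * rdme.MOLECULES_PER_UM_UM3
                init = np.zeros((9, 6), dtype=np.int64)
                init[:, :5] = np.round(mols).astype(np.int64)
                traj = rdme.ssa_simulate(lat, net, init, 400.0, seed=100 + rep, output_dt=10.0)
                runs.append(traj.concentrations("P").mean(axis=1))
            stoch_mean = np.mean(runs, axis=0)
            errors.append(np.sqrt(np.mean((stoch_mean - ode_mean) ** 2)))
        assert errors[0] > errors[1] > errors[2]


class TestVolumeScan:
    def test_seeded_reproducibility_and_spread_trend(self, params):
        lat = hn.build_hex_lattice(4, 4, "zero")
        out1 = rdme.volume_scan(lat, params, [1.0, 50.0], replicates=1, seed=5, t_end=1500.0)
        out2 = rdme.volume_scan(lat, params, [1.0, 50.0], replicates=1, seed=5, t_end=1500.0)
        for a, b in zip(out1, out2):
            assert np.allclose(
                np.concatenate(a["stationary_states"]),
                np.concatenate(b["stationary_states"]),
            )
        # smaller voxel volume means larger relative spread within the
        # high-expression class
        rel = [
            entry["bimodal"].top_diameter / max(entry["bimodal"].top_mean, 1e-12)
            for entry in out1
        ]
        assert rel[0] > rel[1]

    def test_invalid_arguments(self, params, two_cell):
        with pytest.raises(ValueError):
            rdme.volume_scan(two_cell, params, [1.0], replicates=0, seed=1)
        with pytest.raises(ValueError):
            rdme.volume_scan(two_cell, params, [-1.0], replicates=1, seed=1)
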