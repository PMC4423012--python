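import numpy as np
import pytest

from erfate import (
    ModelParameters,
    constant_stress,
    integrate,
    resting_state,
    simulate_cell,
    simulate_ensemble,
    to_reactions,
    washout,
)
from erfate.model import CellState
from erfate.ssa import spawn_seeds


def random_counts(params, rng):
    e_tot, a_tot, p_tot = params.pool_counts()
    n = params.n_steps
    chain = rng.multinomial(p_tot, np.ones(n + 1) / (n + 1))[:n]
    return np.concatenate(
        ([rng.integers(0, e_tot + 1), rng.integers(0, a_tot + 1)], chain)
    ).astype(np.int64)


class TestReactionSet:
    def test_reaction_count_matches_ode_terms(self, params):
        rs = to_reactions(params)
        assert rs.n_reactions == 4 + 2 * params.n_steps

    def test_drift_identity_recovers_rhs(self, params):
        # sum(stoich * propensity)/Omega must equal the ODE right-hand side
        # evaluated at the concentrations counts/Omega
        from erfate.model import _rhs_vec

        rs = to_reactions(params)
        rng = np.random.default_rng(2)
        for _ in range(50):
            c = random_counts(params, rng)
            S = rng.uniform(0, 10)
            drift = rs.drift(c, S)
            ode = _rhs_vec(c / params.Omega, S, params)
            assert np.max(np.abs(drift - ode)) < 1e-12

    def test_propensities_nonnegative(self, params):
        rs = to_reactions(params)
        rng = np.random.default_rng(3)
        for _ in range(1000):
            a = rs.propensity_vector(random_counts(params, rng), rng.uniform(0, 10))
            assert np.all(a >= 0)

    def test_small_omega_warns(self, params):
        with pytest.warns(UserWarning, match="Omega"):
            to_reactions(params.replace(Omega=5))


class TestSimulateCell:
    def test_seed_determinism(self, params):
        proto = constant_stress(5.0, 60.0)
        a = simulate_cell(params, proto, seed=11)
        b = simulate_cell(params, proto, seed=11)
        c = simulate_cell(params, proto, seed=12)
        assert np.array_equal(a.y, b.y)
        assert not np.array_equal(a.y, c.y)

    def test_counts_are_integer_and_conserved(self, params):
        traj = simulate_cell(params, constant_stress(8.0, 120.0), seed=4)
        counts = traj.y * params.Omega
        assert np.allclose(counts, np.rint(counts))
        e_tot, a_tot, p_tot = params.pool_counts()
        assert np.all(counts[:, 0] >= 0) and np.all(counts[:, 0] <= e_tot)
        assert np.all(counts[:, 1] >= 0) and np.all(counts[:, 1] <= a_tot)
        assert np.all(counts[:, 2:].sum(axis=1) <= p_tot)

    def test_single_cell_switch_sharper_than_population_mean(self, params):
        # at high stress most cells complete the 20%->80% apoptosis switch,
        # and each cell's rise is sharper than the ensemble-mean rise (which
        # is smeared by cell-to-cell activation-time spread)
        ens = simulate_ensemble(params, constant_stress(5.0, 240.0), n_cells=15, master_seed=5)

        def width(apo):
            hi = np.flatnonzero(apo > 0.8 * params.APO_T)
            if not hi.size:
                return None
            lo = np.flatnonzero(apo[: hi[0]] < 0.2 * params.APO_T)
            return None if not lo.size else float(hi[0] - lo[-1])

        widths = [w for w in (width(tr.APO_act) for tr in ens.trajectories) if w is not None]
        assert len(widths) >= 8  # most cells switch at S0 = 5
        mean_apo = np.mean([tr.APO_act for tr in ens.trajectories], axis=0)
        pop_width = width(mean_apo / mean_apo.max() * params.APO_T)
        assert pop_width is not None
        assert np.median(widths) < pop_width

    def test_washout_protocol_respected(self, params):
        traj = simulate_cell(params, washout(10.0, 20.0, 60.0), seed=6)
        i = np.searchsorted(traj.t, 20.0)
        # after washout the sensor relaxes to zero
        assert traj.ERSS[i + 15 :].max() < traj.ERSS[:i].max()
        assert traj.ERSS[-1] < 0.05


class TestLargeOmega:
    def test_mean_approaches_deterministic(self, params):
        # law of large numbers: at Omega = 10^4 a single cell already tracks
        # the ODE solution closely at low stress (full convergence suite runs
        # in the acceptance tests)
        proto = constant_stress(1.0, 120.0)
        det = integrate(params, proto, dt_out=5.0)
        big = params.replace(Omega=10000)
        mean = np.mean(
            [simulate_cell(big, proto, seed=s, dt_out=5.0).y for s in (1, 2, 3)], axis=0
        )
        assert np.max(np.abs(mean - det.y)) < 0.03


class TestEnsemble:
    def test_master_seed_reproducibility(self, params):
        proto = constant_stress(5.0, 60.0)
        a = simulate_ensemble(params, proto, n_cells=5, master_seed=9)
        b = simulate_ensemble(params, proto, n_cells=5, master_seed=9)
        assert np.array_equal(a.seeds, b.seeds)
        for x, y in zip(a.trajectories, b.trajectories):
            assert np.array_equal(x.y, y.y)

    def test_single_cell_ensemble_reduces_to_simulate_cell(self, params):
        proto = constant_stress(5.0, 60.0)
        ens = simulate_ensemble(params, proto, n_cells=1, master_seed=9)
        solo = simulate_cell(params, proto, seed=int(spawn_seeds(9, 1)[0]))
        assert np.array_equal(ens.trajectories[0].y, solo.y)

    def test_seed_spawning_is_stable(self):
        # documented scheme: SeedSequence(master).generate_state(n) % 2**31
        expected = np.random.SeedSequence(123).generate_state(4) % (2**31)
        assert np.array_equal(spawn_seeds(123, 4), expected.astype(np.int64))

    def test_extrinsic_variability_changes_cells_not_determinism(self, params):
        proto = constant_stress(5.0, 60.0)
        a = simulate_ensemble(params, proto, n_cells=4, master_seed=1, extrinsic_sigma=0.3)
        b = simulate_ensemble(params, proto, n_cells=4, master_seed=1, extrinsic_sigma=0.3)
        for x, y in zip(a.trajectories, b.trajectories):
            assert np.array_equal(x.y, y.y)
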