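"""Tests of the lattice-gas automaton operators: exclusion, conservation,
initial conditions, and the random-walk law of migration."""

import numpy as np
import pytest

from gogrow.lgca import (
    LatticeConfig,
    ModelParams,
    averaged_density,
    empty_state,
    init_disk_state,
    propagation_step,
    reaction_step,
    reorientation_step,
    run,
    step,
)
from gogrow.switching import SwitchParams

from conftest import make_params


def disk_node_count(radius, size=100):
    """Brute-force count of integer lattice points within Euclidean distance
    ``radius`` of the center node — the oracle for the disk builder."""
    c = size // 2
    count = 0
    for i in range(size):
        for j in range(size):
            if (i - c) ** 2 + (j - c) ** 2 <= radius**2:
                count += 1
    return count


class TestInitDisk:
    def test_single_node_disk(self, rng):
        cfg = LatticeConfig(21, 21, 8, 4)
        state = init_disk_state(cfg, 0, 1.0, rng)
        assert state.n_total == 2
        assert state.node_counts()[10, 10] == 2
        assert state.n_rest == 1 and state.n_move == 1

    def test_zero_probability_gives_empty_lattice(self, rng):
        cfg = LatticeConfig(50, 50, 8, 4)
        assert init_disk_state(cfg, 10, 0.0, rng).n_total == 0

    def test_full_disk_cell_count_matches_geometry(self, rng):
        cfg = LatticeConfig(100, 100, 8, 4)
        state = init_disk_state(cfg, 10, 1.0, rng)
        assert state.n_total == 2 * disk_node_count(10)

    def test_occupancy_probability_is_respected(self, rng):
        cfg = LatticeConfig(100, 100, 8, 4)
        n_nodes = disk_node_count(10)
        counts = [
            init_disk_state(cfg, 10, 0.25, rng).n_total / 2 for _ in range(50)
        ]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 0.25 * n_nodes) < 4 * se + 1e-9

    def test_overlapping_disk_rejected(self, rng):
        cfg = LatticeConfig(15, 15, 8, 4)
        with pytest.raises(ValueError):
            init_disk_state(cfg, 10, 1.0, rng)

    def test_denser_channel_occupancy(self, rng):
        cfg = LatticeConfig(30, 30, 8, 4)
        state = init_disk_state(cfg, 5, 1.0, rng, n_rest=3, n_vel=2)
        counts = state.node_counts()
        assert set(np.unique(counts)) <= {0, 5}
        assert state.n_rest == 3 * (counts == 5).sum()


class TestReaction:
    def test_pure_switching_conserves_count(self, rng, small_lattice):
        params = make_params(0.0, 0.5, r_b=0.0, r_d=0.0, lattice=small_lattice)
        state = init_disk_state(small_lattice, 5, 1.0, rng)
        n0 = state.n_total
        out = reaction_step(state, params, rng)
        assert out.n_total == n0

    def test_neutral_switch_rest_fraction_half(self, rng):
        # kappa=0: each cell resting with prob 1/2; low density avoids blocking
        cfg = LatticeConfig(50, 50, 8, 4)
        params = make_params(0.0, 0.5, r_b=0.0, r_d=0.0, lattice=cfg)
        state = init_disk_state(cfg, 20, 0.5, rng)
        out = reaction_step(state, params, rng)
        n = out.n_total
        assert abs(out.n_rest - 0.5 * n) < 4 * np.sqrt(n * 0.25)

    def test_certain_death_empties_lattice(self, rng, small_lattice):
        params = make_params(1.0, 0.5, r_b=0.0, r_d=1.0, lattice=small_lattice)
        state = init_disk_state(small_lattice, 5, 1.0, rng)
        assert reaction_step(state, params, rng).n_total == 0

    def test_birth_saturates_rest_channels(self, rng):
        """3 resting cells, r_b=1: exactly one birth fits the last free rest
        channel; a steep switch keeps everyone resting (brute-force capacity
        oracle: min(attempts, free) = min(3, 1) = 1)."""
        cfg = LatticeConfig(1, 1, 8, 4)
        # r_s ~= 1 above theta: all cells want the resting phenotype
        params = ModelParams(
            r_b=1.0, r_d=0.0, switch=SwitchParams(500.0, 0.01), lattice=cfg
        )
        state = empty_state(cfg)
        state.occupancy[0, 0, 4:7] = True
        out = reaction_step(state, params, rng)
        assert out.n_rest == 4
        assert out.n_total == 4

    def test_capacity_never_exceeded(self, rng, small_lattice):
        params = make_params(4.0, 0.2, r_b=0.5, r_d=0.01, lattice=small_lattice)
        state = init_disk_state(small_lattice, 5, 1.0, rng, n_rest=4, n_vel=4)
        for _ in range(30):
            state = reaction_step(state, params, rng)
            counts = state.node_counts()
            assert counts.max() <= small_lattice.K
            assert state.occupancy.dtype == bool


class TestReorientation:
    def test_conserves_per_node_counts(self, rng, small_lattice):
        state = init_disk_state(small_lattice, 8, 1.0, rng)
        before = state.occupancy[:, :, :4].sum(axis=2)
        out = reorientation_step(state, rng)
        assert np.array_equal(out.occupancy[:, :, :4].sum(axis=2), before)
        # rest channels untouched
        assert np.array_equal(out.occupancy[:, :, 4:], state.occupancy[:, :, 4:])

    def test_single_cell_uniform_over_channels(self, rng):
        cfg = LatticeConfig(1, 1, 8, 4)
        state = empty_state(cfg)
        state.occupancy[0, 0, 0] = True
        hits = np.zeros(4)
        n_draws = 40000
        for _ in range(n_draws):
            out = reorientation_step(state, rng)
            hits[np.argmax(out.occupancy[0, 0, :4])] += 1
        # each channel frequency 1/4 within 4 sigma of binomial noise
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert np.all(np.abs(hits / n_draws - 0.25) < 4 * se)


class TestPropagation:
    def test_empty_stays_empty(self, small_lattice):
        out = propagation_step(empty_state(small_lattice))
        assert out.n_total == 0

    def test_east_moving_cell_shifts_by_one(self):
        cfg = LatticeConfig(10, 10, 8, 4)
        state = empty_state(cfg)
        state.occupancy[5, 9, 0] = True  # east channel at the right edge
        out = propagation_step(state)
        assert out.occupancy[5, 0, 0]  # periodic wrap
        assert out.n_total == 1

    def test_translation_periodicity(self, rng):
        cfg = LatticeConfig(5, 5, 8, 4)
        state = empty_state(cfg)
        state.occupancy[:, :, :4] = rng.random((5, 5, 4)) < 0.4  # velocity-only
        out = state
        for _ in range(5):
            out = propagation_step(out)
        assert np.array_equal(out.occupancy, state.occupancy)


class TestStepAndRun:
    def test_count_invariant_without_birth_death(self, rng, small_lattice):
        params = make_params(2.0, 0.4, r_b=0.0, r_d=0.0, lattice=small_lattice)
        state = init_disk_state(small_lattice, 6, 1.0, rng)
        n0 = state.n_total
        for _ in range(100):
            state = step(state, params, rng)
        assert state.n_total == n0

    def test_seeded_trajectory_is_reproducible(self, small_lattice):
        params = make_params(4.4, 0.75, lattice=small_lattice, seed=42)
        finals = []
        for _ in range(2):
            rng = params.rng()
            state = init_disk_state(small_lattice, 6, 0.5, rng)
            result = run(state, params, 50, rng=rng)
            finals.append(result.final_state.occupancy.copy())
        assert np.array_equal(finals[0], finals[1])

    def test_zero_steps_single_record(self, rng, small_lattice):
        params = make_params(1.0, 0.5, lattice=small_lattice)
        state = init_disk_state(small_lattice, 5, 1.0, rng)
        result = run(state, params, 0, rng=rng)
        assert len(result.records) == 1
        assert not result.extinct

    def test_empty_start_flags_extinction(self, rng, small_lattice):
        params = make_params(1.0, 0.5, lattice=small_lattice)
        result = run(empty_state(small_lattice), params, 10, rng=rng)
        assert result.extinct
        assert len(result.records) == 1

    def test_extinction_terminates_early(self, rng, small_lattice):
        params = make_params(1.0, 0.5, r_b=0.0, r_d=0.5, lattice=small_lattice)
        state = init_disk_state(small_lattice, 3, 1.0, rng)
        result = run(state, params, 10000, record_every=100, rng=rng)
        assert result.extinct
        assert result.final_state.time < 10000
        assert result.records["n_total"].iloc[-1] == 0

    def test_mean_squared_displacement_is_linear(self):
        """A lone migratory cell performs an unbiased 4-neighbour random
        walk: E|x_t - x_0|^2 = t (unit steps, independent directions)."""
        cfg = LatticeConfig(41, 41, 8, 4)
        # below theta the saturated attractive switch gives r_s == 0
        # exactly, so the lone cell never rests
        params = ModelParams(
            r_b=0.0, r_d=0.0, switch=SwitchParams(1e4, 0.5), lattice=cfg
        )
        t_steps, n_rep = 16, 1200
        rng = np.random.default_rng(2024)
        sq = np.empty(n_rep)
        for r in range(n_rep):
            state = empty_state(cfg)
            state.occupancy[20, 20, 0] = True
            disp = np.zeros(2)
            prev = np.array([20, 20])
            s = state
            for _ in range(t_steps):
                s = step(s, params, rng)
                pos = np.argwhere(s.occupancy)[0][:2]
                d = pos - prev
                # undo periodic wrap (single unit steps only)
                d = (d + 20) % 41 - 20
                disp += d
                prev = pos
            sq[r] = disp @ disp
        msd = sq.mean()
        se = sq.std(ddof=1) / np.sqrt(n_rep)
        assert abs(msd - t_steps) < 3 * se


class TestObservables:
    def test_averaged_density_limits(self, small_lattice):
        state = empty_state(small_lattice)
        assert averaged_density(state) == 0.0
        state.occupancy[:] = True
        assert averaged_density(state) == 1.0

    def test_averaged_density_arithmetic(self, rng):
        cfg = LatticeConfig(100, 100, 8, 4)
        state = empty_state(cfg)
        flat = state.occupancy.reshape(-1)
        flat[rng.choice(flat.size, size=628, replace=False)] = True
        assert averaged_density(state) == pytest.approx(628 / 80000)

    def test_record_identity(self, rng, small_lattice):
        params = make_params(4.0, 0.75, lattice=small_lattice)
        state = init_disk_state(small_lattice, 5, 0.8, rng)
        result = run(state, params, 20, rng=rng)
        rec = result.records
        assert (rec["n_total"] == rec["n_rest"] + rec["n_move"]).all()
        assert ((rec["rho_avg"] >= 0) & (rec["rho_avg"] <= 1)).all()


class TestModelParamValidation:
    def test_probability_bounds(self, small_lattice):
        with pytest.raises(ValueError):
            ModelParams(r_b=1.5, r_d=0.0, switch=SwitchParams(1, 0.5), lattice=small_lattice)

    def test_warns_outside_recommended_range(self, small_lattice):
        with pytest.warns(UserWarning):
            ModelParams(r_b=0.1, r_d=0.9, switch=SwitchParams(1, 0.5), lattice=small_lattice)

    def test_lattice_invariants(self):
        with pytest.raises(ValueError):
            LatticeConfig(10, 10, K=3, b=4)
        with pytest.raises(ValueError):
            LatticeConfig(0, 10, K=8, b=4)
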