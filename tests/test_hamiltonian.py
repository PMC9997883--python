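"""Energy-function oracle tests for the reference CPM implementation."""
import numpy as np
import pytest

from evocpm.hamiltonian import (
    attempt_copy,
    cell_perimeter,
    delta_h_act,
    delta_h_physical,
    gm_act,
    mcs_step,
    metropolis_accept,
    total_hamiltonian,
)
from evocpm.lattice import (
    Genotype,
    LatticeState,
    PhysicalParams,
    empty_state,
    moore_neighbors,
)


def brute_force_unlike_pairs(state):
    """Count unordered Moore pairs with different cell ids, by enumeration."""
    w, h = state.width, state.height
    pairs = set()
    for x in range(w):
        for y in range(h):
            for q in moore_neighbors((x, y), state):
                if state.identity[x, y] != state.identity[q]:
                    pairs.add(frozenset([(x, y), q]))
    return len(pairs)


class TestTotalHamiltonian:
    def test_all_background_grid_has_zero_energy(self, small_params):
        assert total_hamiltonian(empty_state(10, 10), small_params) == 0.0

    def test_cell_at_target_volume_and_perimeter_pays_adhesion_only(self):
        # 5x5 square cell: V = 25, Moore perimeter = 4*5 + 4*5 + 4*3 = sides+corners
        state = empty_state(20, 20)
        state.identity[5:10, 5:10] = 1
        state.cell_kind[1] = 1
        v = 25
        per = cell_perimeter(state, 1)
        params = PhysicalParams(
            target_volume=[0, v, 0], lambda_volume=[0, 30, 0],
            target_perimeter=[0, per, 0], lambda_perimeter=[0, 2, 0],
            adhesion=[[0, 20, 0], [20, 0, 0], [0, 0, 0]],
        )
        expected_adhesion = 20 * brute_force_unlike_pairs(state)
        assert total_hamiltonian(state, params) == pytest.approx(expected_adhesion)

    def test_2x2_block_adhesion_counted_once_per_unordered_pair(self):
        state = empty_state(20, 20)
        state.identity[8:10, 8:10] = 1
        state.cell_kind[1] = 1
        params = PhysicalParams(
            target_volume=[0, 4, 0], lambda_volume=[0, 0, 0],
            target_perimeter=[0, 0, 0], lambda_perimeter=[0, 0, 0],
            adhesion=[[0, 20, 0], [20, 0, 0], [0, 0, 0]],
        )
        n_pairs = brute_force_unlike_pairs(state)
        # a 2x2 block: each pixel touches 5 outside neighbours -> 20 pairs
        assert n_pairs == 20
        assert total_hamiltonian(state, params) == pytest.approx(20 * n_pairs)


class TestDeltaHPhysical:
    def test_volume_term_for_cell_below_target(self):
        # V = 499, V* = 500, lambda_V = 30; gaining a pixel: 0 - 30*(-1)^2
        state = empty_state(40, 40)
        offs = np.argwhere(np.ones((25, 20)))  # 500 pixels
        state.identity[offs[:, 0] + 5, offs[:, 1] + 5] = 1
        state.identity[5, 5] = 0  # now 499
        state.cell_kind[1] = 1
        params = PhysicalParams(
            target_volume=[0, 500, 0], lambda_volume=[0, 30, 0],
            target_perimeter=[0, 0, 0], lambda_perimeter=[0, 0, 0],
            adhesion=np.zeros((3, 3)),
        )
        dh = delta_h_physical(state, (6, 6), (5, 5), params)
        assert dh == pytest.approx(-30.0)

    def test_volume_term_for_cell_at_target(self):
        state = empty_state(40, 40)
        offs = np.argwhere(np.ones((25, 20)))
        state.identity[offs[:, 0] + 5, offs[:, 1] + 5] = 1
        state.cell_kind[1] = 1
        params = PhysicalParams(
            target_volume=[0, 500, 0], lambda_volume=[0, 30, 0],
            target_perimeter=[0, 0, 0], lambda_perimeter=[0, 0, 0],
            adhesion=np.zeros((3, 3)),
        )
        dh = delta_h_physical(state, (10, 10), (4, 10), params)
        assert dh == pytest.approx(30.0)

    def test_same_cell_copy_rejected(self, toy_lattices, small_params):
        state = toy_lattices["single_square"]
        with pytest.raises(ValueError):
            delta_h_physical(state, (2, 2), (2, 3), small_params)

    def test_matches_brute_force_energy_difference(self, small_params, rng):
        """Defining property: local delta H == H(after) - H(before)."""
        for _ in range(200):
            w = h = int(rng.integers(8, 16))
            ids = rng.integers(0, 4, size=(w, h)).astype(np.int32)
            state = LatticeState(
                ids, np.zeros((w, h)), np.array([0, 1, 2, 1], dtype=np.int8)
            )
            source, target = _random_unlike_pair(state, rng)
            if source is None:
                continue
            h_before = total_hamiltonian(state, small_params)
            dh = delta_h_physical(state, source, target, small_params)
            after = state.copy()
            after.identity[target] = state.identity[source]
            h_after = total_hamiltonian(after, small_params)
            assert dh == pytest.approx(h_after - h_before, rel=1e-9, abs=1e-9)


def _random_unlike_pair(state, rng):
    for _ in range(200):
        s = (int(rng.integers(state.width)), int(rng.integers(state.height)))
        t = moore_neighbors(s, state)[int(rng.integers(8))]
        if state.identity[s] != state.identity[t]:
            return s, t
    return None, None


class TestGmAct:
    def _active_state(self, acts):
        state = empty_state(8, 8)
        state.identity[2:5, 2:5] = 1
        state.cell_kind[1] = 1
        state.activity[2:5, 2:5] = acts
        return state

    def test_uniform_activity_is_its_own_geometric_mean(self):
        state = self._active_state(7.0)
        assert gm_act(state, (3, 3)) == pytest.approx(7.0)

    def test_single_zero_activity_zeroes_the_mean(self):
        state = self._active_state(7.0)
        state.activity[2, 2] = 0.0
        assert gm_act(state, (3, 3)) == 0.0

    def test_two_pixel_cell_geometric_mean(self):
        state = empty_state(8, 8)
        state.identity[3, 3] = state.identity[3, 4] = 1
        state.cell_kind[1] = 1
        state.activity[3, 3] = 4.0
        state.activity[3, 4] = 16.0
        assert gm_act(state, (3, 3)) == pytest.approx(8.0)

    def test_background_pixel_has_zero_gm(self):
        state = self._active_state(5.0)
        assert gm_act(state, (0, 0)) == 0.0

    def test_other_cells_pixels_excluded(self):
        state = self._active_state(4.0)
        state.identity[5, 2:5] = 2
        state.cell_kind[2] = 1
        state.activity[5, 2:5] = 100.0  # must not contaminate cell 1's GM
        assert gm_act(state, (4, 3)) == pytest.approx(4.0)


class TestDeltaHAct:
    def _state_with_gms(self):
        state = empty_state(10, 10)
        state.identity[2:5, 2:5] = 1
        state.cell_kind[1] = 1
        return state

    def test_equal_geometric_means_give_zero(self):
        state = empty_state(10, 10)
        state.identity[2:5, 2:5] = 1
        state.identity[2:5, 5:8] = 2
        state.cell_kind[1] = state.cell_kind[2] = 1
        state.activity[2:5, 2:8] = 5.0
        g = Genotype(10, 100)
        assert delta_h_act(state, (3, 4), (3, 5), g) == pytest.approx(0.0)

    def test_evolved_parameters_give_minus_lambda_act(self):
        # lambda_act=1165, max_act=50, GM(s)=50, GM(t)=0 -> -1165
        state = self._state_with_gms()
        state.activity[2:5, 2:5] = 50.0
        g = Genotype(50, 1165)
        assert delta_h_act(state, (3, 3), (3, 5), g) == pytest.approx(-1165.0)

    def test_retraction_into_more_active_region_is_penalised(self):
        # lambda_act=1000, max_act=50, GM(s)=25, GM(t)=50 -> +500
        state = empty_state(12, 12)
        state.identity[2:5, 2:5] = 1
        state.identity[2:5, 6:9] = 2
        state.cell_kind[1] = state.cell_kind[2] = 1
        state.activity[2:5, 2:5] = 25.0
        state.activity[2:5, 6:9] = 50.0
        g = Genotype(50, 1000)
        # source in cell 1 (GM 25), target in cell 2 (GM 50); not adjacent is
        # fine for the energy formula, which only reads the two neighbourhoods
        assert delta_h_act(state, (3, 3), (3, 7), g) == pytest.approx(500.0)

    def test_disabled_feedback_contributes_nothing(self):
        state = self._state_with_gms()
        state.activity[2:5, 2:5] = 50.0
        assert delta_h_act(state, (3, 3), (3, 6), None) == 0.0


class TestMetropolisAndSteps:
    def test_negative_delta_h_always_accepted(self, rng):
        assert all(metropolis_accept(-1e-9, 20.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 20.0, rng) for _ in range(100))

    def test_acceptance_frequency_matches_boltzmann_factor(self, rng):
        """delta H = 20 at T = 20 accepts with probability exp(-1)."""
        n = 100_000
        acc = sum(metropolis_accept(20.0, 20.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(np.exp(-1.0), abs=0.006)

    def test_same_cell_attempt_is_a_noop(self, small_params, rng):
        state = empty_state(6, 6)
        state.identity[:, :] = 1  # single cell covers the torus: all no-ops
        state.cell_kind[1] = 1
        before = state.identity.copy()
        for _ in range(50):
            assert not attempt_copy(state, rng, small_params)
        assert np.array_equal(state.identity, before)

    def test_mcs_conserves_pixel_count_and_decays_activity(self, small_params, rng):
        state = empty_state(12, 12)
        state.identity[4:9, 4:9] = 1
        state.cell_kind[1] = 1
        state.activity[4:9, 4:9] = 3.0
        g = Genotype(3, 10)
        n_total = state.width * state.height
        for step in range(4):
            mcs_step(state, rng, small_params, g)
            assert np.count_nonzero(state.identity >= 0) == n_total
            # activity stays within [0, max_act]; the post-decay maximum is
            # max_act - 1 (fresh gains start at max_act, then decay by 1)
            assert np.all(state.activity >= 0)
            assert state.activity.max() <= g.max_act - 1
            # the cell interior, never stolen, decays 3 -> 2 -> 1 -> 0 -> 0
            # unless regained (which resets it to a fresher value)
            interior = state.activity[6, 6]
            assert interior == max(3.0 - (step + 1), 0.0) or interior > 0

    def test_gained_pixel_activity_decays_from_max_act(self, rng):
        # quiet parameters: no adhesion/constraint noise, deterministic gain
        params = PhysicalParams(
            target_volume=[0, 9, 0], lambda_volume=[0, 100, 0],
            target_perimeter=[0, 0, 0], lambda_perimeter=[0, 0, 0],
            adhesion=np.zeros((3, 3)),
        )
        state = empty_state(8, 8)
        state.identity[2:5, 2:5] = 1
        state.cell_kind[1] = 1
        g = Genotype(4, 10)
        mcs_step(state, rng, params, g)
        gained = (state.identity == 1) & (state.activity > 0)
        if gained.any():
            # after m further MCS the activity is max_act - 1 - m, floored
            a0 = state.activity[gained].max()
            assert a0 <= g.max_act - 1
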