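import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from batchalloc import (
    AllocationProblem,
    AllocationState,
    InfeasibleAllocationError,
    allocate_batch,
    forced_treatments,
    never_chosen_treatments,
    next_treatment,
    preallocate,
    sba_allocate,
    seed_pair,
)
from conftest import problems


def make_state(t_star, b_star, k=1, Lambda=None, seed=0):
    T = len(t_star)
    state = AllocationState.initial(
        np.array(t_star), np.array(b_star), np.random.default_rng(seed)
    )
    state.k = k
    if Lambda is not None:
        state.Lambda = np.array(Lambda, dtype=int)
    return state


class TestForcedTreatments:
    def test_counts_equal_to_remaining_batches(self):
        # 2 batches left, counts [1,2,2]: the two 2s must be in both
        state = make_state([1, 2, 2], [3, 3, 3], k=2)
        assert forced_treatments(state) == {1, 2}

    def test_empty_when_counts_small(self):
        state = make_state([1, 1, 1], [1] * 10, k=1)
        assert forced_treatments(state) == set()

    def test_overflow_raises(self):
        state = make_state([3, 3], [1, 3, 2], k=1)
        with pytest.raises(InfeasibleAllocationError):
            forced_treatments(state)

    def test_single_forced_fits_capacity_one(self):
        state = make_state([3, 1], [1, 3, 3], k=1)
        assert forced_treatments(state) == {0}


class TestNeverChosen:
    def test_before_any_batch_all_available(self):
        state = make_state([1, 2, 0, 1], [2, 2], k=1)
        assert never_chosen_treatments(state) == {0, 1, 3}

    def test_after_first_batch(self):
        state = make_state([1, 1, 1, 1], [2, 2], k=2)
        state.Lambda[np.ix_([0, 1], [0, 1])] = 1
        assert never_chosen_treatments(state) == {2, 3}

    def test_all_chosen_gives_empty(self):
        state = make_state([1, 1], [1, 1], k=2)
        state.Lambda[:] = [[1, 0], [0, 1]]
        assert never_chosen_treatments(state) == set()


class TestSeedPair:
    def test_unique_minimum(self):
        L = [[0, 2, 0], [2, 0, 1], [0, 1, 0]]
        state = make_state([1, 1, 1], [2], Lambda=L)
        assert seed_pair(state, {0, 1, 2}) == (0, 2)

    def test_all_tied_is_uniform(self):
        state = make_state([1, 1, 1], [2] * 3)
        seen = set()
        for _ in range(200):
            seen.add(seed_pair(state, {0, 1, 2}))
        assert seen == {(0, 1), (0, 2), (1, 2)}

    def test_fewer_than_two_candidates(self):
        state = make_state([1, 1], [2])
        with pytest.raises(InfeasibleAllocationError):
            seed_pair(state, {0})

    def test_diagonal_excluded(self):
        # high replication but zero co-occurrence: diagonal must not count
        L = [[5, 0], [0, 5]]
        state = make_state([1, 1], [2], Lambda=L)
        assert seed_pair(state, {0, 1}) == (0, 1)


class TestNextTreatment:
    def test_lowest_column_sum(self):
        L = [[0, 3, 1], [3, 0, 0], [1, 0, 0]]
        state = make_state([1, 1, 1], [2], Lambda=L)
        assert next_treatment(state, {0}, {1, 2}) == 2

    def test_tie_is_uniform(self):
        L = [[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 0], [2, 2, 0, 0]]
        state = make_state([1] * 4, [3], Lambda=L)
        seen = {next_treatment(state, {0, 1}, {2, 3}) for _ in range(100)}
        assert seen == {2, 3}

    def test_singleton_candidate(self):
        state = make_state([1, 1], [2])
        assert next_treatment(state, {0}, {1}) == 1


class TestAllocateBatch:
    def test_forced_then_fill(self):
        # synthetic state: treatment 0 must be in both remaining batches
        state = make_state([2, 1], [2, 1], k=1)
        allocate_batch(state)
        assert state.N[0].tolist() == [1, 1]
        allocate_batch(state)
        assert state.N[1].tolist() == [1, 0]
        assert state.t_star.tolist() == [0, 0]

    def test_full_symmetry_first_batch_uniform(self):
        counts = {}
        for seed in range(300):
            state = make_state([1] * 5, [3, 1, 1], seed=seed)
            allocate_batch(state)
            counts[tuple(np.flatnonzero(state.N[0]))] = (
                counts.get(tuple(np.flatnonzero(state.N[0])), 0) + 1
            )
        assert len(counts) == 10  # all C(5,3) subsets occur

    def test_updates_deferred_until_batch_complete(self):
        state = make_state([1, 1, 1, 1], [2, 2], k=1)
        allocate_batch(state)
        chosen = np.flatnonzero(state.N[0])
        assert state.Lambda[chosen[0], chosen[1]] == 1
        assert state.Lambda.sum() == 4  # 2 diagonal + 2 off-diagonal
        assert state.k == 2


class TestSbaAllocate:
    def test_unique_feasible_allocation(self):
        p = AllocationProblem(["a", "b"], [2, 2], [2, 2])
        alloc = sba_allocate(p, 0)
        assert alloc.incidence.tolist() == [[1, 1], [1, 1]]

    def test_determinism(self, setting_a):
        a = sba_allocate(setting_a, 42)
        b = sba_allocate(setting_a, 42)
        assert np.array_equal(a.incidence, b.incidence)
        assert a.d_score == b.d_score

    def test_distinct_seeds_vary(self, setting_a):
        mats = {sba_allocate(setting_a, s).incidence.tobytes() for s in range(20)}
        assert len(mats) > 1

    def test_batch_rows_sum_to_capacity(self, setting_a):
        alloc = sba_allocate(setting_a, 7)
        assert alloc.incidence.sum(axis=1).tolist() == [3] * 10

    @given(problems(), st.integers(0, 5))
    def test_completion_and_consistency(self, problem, seed):
        """Column sums equal t, row sums equal b, remainder is binary,
        and the final concurrence identity Lambda == N^T N holds."""
        pre = preallocate(problem)
        alloc = sba_allocate(problem, seed)
        N = alloc.incidence
        assert N.sum(axis=0).tolist() == problem.t.tolist()
        assert N.sum(axis=1).tolist() == problem.b.tolist()
        remainder = N - pre.N_star
        assert set(np.unique(remainder)) <= {0, 1}

    def test_final_concurrence_identity(self, setting_a):
        pre = preallocate(setting_a)
        rng = np.random.default_rng(3)
        state = AllocationState.initial(pre.t_star, pre.b_star, rng)
        for _ in range(setting_a.n_batches):
            allocate_batch(state)
        assert np.array_equal(state.Lambda, state.N.T @ state.N)
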