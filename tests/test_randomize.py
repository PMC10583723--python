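import numpy as np
import pandas as pd
import pytest

from batchalloc import (
    AllocationProblem,
    ManifestMismatchError,
    all_subsets_incidence,
    assign_subjects,
    d_criterion,
    incidence_from_plan,
    make_processing_plan,
    order_within_batches,
    permute_batches,
    read_incidence,
    read_manifest,
    sba_allocate,
    validate_manifest,
    write_incidence,
)


@pytest.fixture
def setting_a_manifest(setting_a):
    rows = []
    for lab, count in zip(setting_a.treatment_labels, setting_a.t):
        for j in range(count):
            rows.append({"sample_id": f"{lab}_s{j + 1}", "treatment": lab})
    return pd.DataFrame(rows)


class TestManifest:
    def test_read_and_validate(self, tmp_path, setting_a, setting_a_manifest):
        path = tmp_path / "m.csv"
        setting_a_manifest.to_csv(path, index=False)
        df = read_manifest(path)
        validate_manifest(df, setting_a)

    def test_missing_sample_detected(self, setting_a, setting_a_manifest):
        with pytest.raises(ManifestMismatchError):
            validate_manifest(setting_a_manifest.iloc[:-1], setting_a)

    def test_duplicate_ids_rejected(self, tmp_path, setting_a_manifest):
        dup = pd.concat([setting_a_manifest, setting_a_manifest.iloc[[0]]])
        path = tmp_path / "m.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(ManifestMismatchError, match="duplicate"):
            read_manifest(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        pd.DataFrame({"sample_id": ["s1"]}).to_csv(path, index=False)
        with pytest.raises(ManifestMismatchError, match="missing"):
            read_manifest(path)


class TestPermuteBatches:
    def test_score_invariant(self, setting_a):
        N = sba_allocate(setting_a, 1).incidence
        assert d_criterion(permute_batches(N, 5)) == d_criterion(N)

    def test_multiset_of_rows_preserved(self):
        N = all_subsets_incidence(5, 3)
        P = permute_batches(N, 0)
        assert sorted(map(tuple, N.tolist())) == sorted(map(tuple, P.tolist()))

    def test_single_batch_identity(self):
        N = np.array([[2, 1]])
        assert np.array_equal(permute_batches(N, 3), N)

    def test_deterministic(self, setting_a):
        N = sba_allocate(setting_a, 1).incidence
        assert np.array_equal(permute_batches(N, 8), permute_batches(N, 8))


class TestAssignSubjects:
    def test_plan_matches_incidence(self, setting_a, setting_a_manifest):
        N = sba_allocate(setting_a, 2).incidence
        plan = assign_subjects(N, setting_a_manifest, setting_a.treatment_labels, 0)
        assert len(plan) == 30
        assert np.array_equal(
            incidence_from_plan(plan, setting_a.treatment_labels), N
        )

    def test_positions_are_contiguous(self, setting_a, setting_a_manifest):
        N = sba_allocate(setting_a, 2).incidence
        plan = assign_subjects(N, setting_a_manifest, setting_a.treatment_labels, 0)
        for _, grp in plan.groupby("batch"):
            assert sorted(grp["position"]) == list(range(1, len(grp) + 1))

    def test_mismatch_raises(self, setting_a, setting_a_manifest):
        N = sba_allocate(setting_a, 2).incidence
        with pytest.raises(ManifestMismatchError):
            assign_subjects(
                N, setting_a_manifest.iloc[:-1], setting_a.treatment_labels, 0
            )

    def test_forced_assignment_single_sample_each(self):
        p = AllocationProblem(["x", "y"], [1, 1], [2])
        manifest = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "treatment": ["x", "y"]}
        )
        plan = assign_subjects(np.array([[1, 1]]), manifest, p.treatment_labels, 0)
        assert set(plan["sample_id"]) == {"s1", "s2"}


class TestOrderWithinBatches:
    def test_compositions_unchanged(self, setting_a, setting_a_manifest):
        N = sba_allocate(setting_a, 2).incidence
        plan = assign_subjects(N, setting_a_manifest, setting_a.treatment_labels, 0)
        shuffled = order_within_batches(plan, 1)
        assert np.array_equal(
            incidence_from_plan(shuffled, setting_a.treatment_labels), N
        )
        assert set(shuffled["sample_id"]) == set(plan["sample_id"])

    def test_batch_of_size_one_unchanged(self):
        plan = pd.DataFrame(
            {"sample_id": ["s1"], "treatment": ["x"], "batch": [1], "position": [1]}
        )
        out = order_within_batches(plan, 0)
        assert out["position"].tolist() == [1]

    def test_deterministic(self, setting_a, setting_a_manifest):
        N = sba_allocate(setting_a, 2).incidence
        plan = assign_subjects(N, setting_a_manifest, setting_a.treatment_labels, 0)
        a = order_within_batches(plan, 9)
        b = order_within_batches(plan, 9)
        pd.testing.assert_frame_equal(a, b)


class TestEndToEnd:
    def test_plan_conserves_samples_and_score(self, setting_a, setting_a_manifest):
        plan, provenance = make_processing_plan(
            setting_a, setting_a_manifest, seed=3, best_of=20
        )
        assert sorted(plan["sample_id"]) == sorted(setting_a_manifest["sample_id"])
        derived = incidence_from_plan(plan, setting_a.treatment_labels)
        assert d_criterion(derived) == provenance["d_score"]
        assert provenance["algorithm"] == "sba"

    def test_incidence_csv_roundtrip(self, tmp_path, setting_a):
        N = sba_allocate(setting_a, 4).incidence
        path = tmp_path / "inc.csv"
        write_incidence(path, N, setting_a.treatment_labels)
        M, labels = read_incidence(path)
        assert labels == list(setting_a.treatment_labels)
        assert np.array_equal(M, N)
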