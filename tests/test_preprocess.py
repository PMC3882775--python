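"""Compression Steps 1-4, bookkeeping, and exact expansion."""

import numpy as np
import pytest

from cmcs import (
    BinaryModeMatrix,
    CompressionRecord,
    CutSet,
    InterventionProblem,
    SynthSpec,
    brute_force_cmcs,
    dedup_and_desupset_targets,
    drop_unused_reactions,
    expand_solutions,
    find_essential_reactions,
    generate_problem,
    merge_duplicate_columns,
    preprocess,
    remove_essential,
)

NAMES = tuple(f"R{i}" for i in range(1, 9))


def empty_desired():
    return BinaryModeMatrix(np.zeros((0, 8), dtype=np.uint8), NAMES)


class TestStep1DropUnused:
    def test_all_zero_target_column_is_dropped(self, target_toy):
        prob = InterventionProblem(targets=target_toy, desired=empty_desired())
        reduced, dropped = drop_unused_reactions(prob)
        assert "R6" in dropped
        assert "R6" not in reduced.reaction_names

    def test_all_columns_active_is_identity(self):
        t = BinaryModeMatrix(np.eye(3, dtype=np.uint8), ("a", "b", "c"))
        d = BinaryModeMatrix(np.zeros((0, 3), dtype=np.uint8), ("a", "b", "c"))
        prob = InterventionProblem(targets=t, desired=d)
        reduced, dropped = drop_unused_reactions(prob)
        assert dropped == []
        assert reduced.reaction_names == ("a", "b", "c")

    def test_empty_target_set_drops_everything(self, desired_toy, empty_matrix):
        prob = InterventionProblem(targets=empty_matrix, desired=desired_toy, n=3)
        reduced, dropped = drop_unused_reactions(prob)
        assert len(dropped) == 8
        assert reduced.n_reactions == 0
        # every desired mode now survives any cut
        assert reduced.always_surviving == 5
        assert reduced.desired.n_modes == 0


class TestStep2Essential:
    def test_printed_example_n3(self, desired_toy, empty_matrix):
        prob = InterventionProblem(targets=empty_matrix, desired=desired_toy, n=3)
        assert find_essential_reactions(prob) == ["R1", "R7"]

    def test_n_equals_D_makes_every_active_reaction_essential(
        self, desired_toy, empty_matrix
    ):
        prob = InterventionProblem(targets=empty_matrix, desired=desired_toy, n=5)
        assert find_essential_reactions(prob) == [
            "R1", "R2", "R3", "R5", "R6", "R7",
        ]

    def test_n1_gives_no_essentials(self, desired_toy, empty_matrix):
        prob = InterventionProblem(targets=empty_matrix, desired=desired_toy, n=1)
        assert find_essential_reactions(prob) == []

    def test_essential_set_grows_with_n(self, desired_toy, empty_matrix):
        previous: set[str] = set()
        for n in range(0, 6):
            prob = InterventionProblem(
                targets=empty_matrix, desired=desired_toy, n=n
            )
            current = set(find_essential_reactions(prob))
            assert previous <= current
            previous = current

    def test_multiplicity_weighted_column_sums(self):
        d = BinaryModeMatrix(
            np.array([[1, 0], [0, 1]], dtype=np.uint8),
            ("a", "b"),
            np.array([4, 1]),
        )
        t = BinaryModeMatrix(np.ones((1, 2), dtype=np.uint8), ("a", "b"))
        prob = InterventionProblem(targets=t, desired=d, n=2)
        # deleting a leaves weight 1 < 2 -> essential; deleting b leaves 4
        assert find_essential_reactions(prob) == ["a"]


class TestRemoveEssential:
    def test_residual_desired_rows_become_singletons(
        self, desired_toy, empty_matrix
    ):
        prob = InterventionProblem(targets=empty_matrix, desired=desired_toy, n=3)
        reduced, removed = remove_essential(prob, ["R1", "R7"])
        assert removed == ["R1", "R7"]
        assert reduced.desired.entries.shape == (5, 6)
        sup = reduced.desired.supports()
        assert sup[3] == frozenset({"R2"})
        assert sup[4] == frozenset({"R3"})

    def test_no_essentials_is_identity(self, combined_toy):
        reduced, removed = remove_essential(combined_toy, [])
        assert removed == []
        assert reduced is combined_toy

    def test_target_supported_only_by_essentials_flags_infeasible(self):
        t = BinaryModeMatrix(np.array([[1, 0]], dtype=np.uint8), ("a", "b"))
        d = BinaryModeMatrix(np.array([[1, 1]], dtype=np.uint8), ("a", "b"))
        prob = InterventionProblem(targets=t, desired=d, n=1)
        reduced, _ = remove_essential(prob, ["a"])
        assert reduced.infeasible
        assert "essential" in reduced.infeasible_reason


class TestStep3Dedup:
    def test_printed_superset_rows_removed(self, target_toy):
        reduced, removed, kept = dedup_and_desupset_targets(target_toy)
        assert dict(removed) == {1: "superset", 3: "superset", 4: "superset"}
        assert kept == [0, 2, 5]
        assert reduced.n_modes == 3

    def test_antichain_is_identity(self):
        t = BinaryModeMatrix(np.eye(4, dtype=np.uint8), ("a", "b", "c", "d"))
        reduced, removed, kept = dedup_and_desupset_targets(t)
        assert removed == []
        assert kept == [0, 1, 2, 3]

    def test_duplicates_collapse_with_reason(self):
        t = BinaryModeMatrix(
            np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8), ("a", "b")
        )
        reduced, removed, kept = dedup_and_desupset_targets(t)
        assert removed == [(1, "duplicate")]
        assert kept == [0, 2]

    def test_result_is_an_antichain(self):
        rng = np.random.default_rng(7)
        t = BinaryModeMatrix(
            (rng.random((15, 8)) < 0.4).astype(np.uint8), NAMES
        )
        keep = np.flatnonzero(t.entries.any(axis=1))
        t = t.select_rows(keep)
        reduced, _, _ = dedup_and_desupset_targets(t)
        sups = reduced.supports()
        for i, a in enumerate(sups):
            for j, b in enumerate(sups):
                assert i == j or not a <= b


class TestStep4Merge:
    def test_residual_columns_merge_into_group_of_three(self, target_toy):
        reduced, _, _ = dedup_and_desupset_targets(target_toy)
        prob = InterventionProblem(targets=reduced, desired=empty_desired())
        prob, _ = drop_unused_reactions(prob)
        merged_prob, groups = merge_duplicate_columns(prob)
        assert [g["members"] for g in groups] == [["R1", "R3", "R8"]]
        assert "R3" not in merged_prob.reaction_names
        assert "R1" in merged_prob.reaction_names

    def test_all_distinct_columns_is_identity(self):
        t = BinaryModeMatrix(np.eye(3, dtype=np.uint8), ("a", "b", "c"))
        prob = InterventionProblem(
            targets=t,
            desired=BinaryModeMatrix(np.zeros((0, 3), dtype=np.uint8), ("a", "b", "c")),
        )
        merged, groups = merge_duplicate_columns(prob)
        assert groups == []
        assert merged.reaction_names == ("a", "b", "c")

    def test_columns_must_match_in_both_sets(self):
        # identical within T but different within D: no merge
        t = BinaryModeMatrix(np.array([[1, 1]], dtype=np.uint8), ("a", "b"))
        d = BinaryModeMatrix(np.array([[1, 0]], dtype=np.uint8), ("a", "b"))
        prob = InterventionProblem(targets=t, desired=d, n=0)
        merged, groups = merge_duplicate_columns(prob)
        assert groups == []
        assert merged.reaction_names == ("a", "b")


class TestPreprocessPipeline:
    def test_combined_toy_record(self, combined_toy):
        compressed, record = preprocess(combined_toy)
        assert record.essential == ["R1", "R7"]
        assert {r for r, why in record.removed_target_rows if why == "superset"}
        removed_ids = {r for r, _ in record.removed_target_rows}
        assert removed_ids >= {1, 3, 4}
        assert not record.infeasible

    def test_already_minimal_problem_has_empty_record(self):
        t = BinaryModeMatrix(np.eye(3, dtype=np.uint8), ("a", "b", "c"))
        d = BinaryModeMatrix(np.zeros((0, 3), dtype=np.uint8), ("a", "b", "c"))
        compressed, record = preprocess(InterventionProblem(targets=t, desired=d))
        assert record.dropped_unused == []
        assert record.essential == []
        assert record.removed_target_rows == []
        assert record.merged_columns == []

    def test_desired_duplicates_fold_into_multiplicity(self):
        d = BinaryModeMatrix(
            np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8), ("a", "b")
        )
        t = BinaryModeMatrix(np.array([[1, 1]], dtype=np.uint8), ("a", "b"))
        compressed, _ = preprocess(InterventionProblem(targets=t, desired=d, n=1))
        assert compressed.desired.total_weight == 3

    def test_infeasible_n_propagates(self, desired_toy, target_toy):
        prob = InterventionProblem(
            targets=target_toy, desired=desired_toy, n=6
        )
        compressed, record = preprocess(prob)
        assert record.infeasible

    def test_record_survives_json_round_trip(self, combined_toy):
        _, record = preprocess(combined_toy)
        back = CompressionRecord.from_dict(record.to_dict())
        assert back.to_dict() == record.to_dict()


class TestExpandSolutions:
    def test_single_group_expands_to_singletons(self):
        record = CompressionRecord(
            merged_columns=[{"representative": "R1", "members": ["R1", "R3", "R8"]}]
        )
        out = expand_solutions([CutSet.of(["R1"])], record)
        assert out == [CutSet.of(["R1"]), CutSet.of(["R3"]), CutSet.of(["R8"])]

    def test_empty_record_is_identity(self):
        cuts = [CutSet.of(["a"]), CutSet.of(["b", "c"])]
        assert expand_solutions(cuts, CompressionRecord()) == cuts

    def test_unknown_member_reference_errors(self):
        record = CompressionRecord(
            merged_columns=[{"representative": "R1", "members": ["R1", "R3"]}]
        )
        with pytest.raises(KeyError, match="R3"):
            expand_solutions([CutSet.of(["R3"])], record)

    def test_expansion_count_is_product_of_group_sizes(self):
        record = CompressionRecord(
            merged_columns=[
                {"representative": "g1", "members": ["g1", "m1", "m2"]},
                {"representative": "g2", "members": ["g2", "m3"]},
            ]
        )
        out = expand_solutions([CutSet.of(["g1", "g2", "other"])], record)
        assert len(out) == 3 * 2
        assert all(len(cs) == 3 for cs in out)


class TestSolutionPreservation:
    @pytest.mark.parametrize("seed", range(30))
    def test_compress_solve_expand_equals_direct_solve(self, seed):
        rng = np.random.default_rng(seed)
        n_desired = int(rng.integers(0, 7))
        spec = SynthSpec(
            reactions=int(rng.integers(4, 11)),
            n_targets=int(rng.integers(1, 13)),
            n_desired=n_desired,
            density=float(rng.uniform(0.2, 0.6)),
            n=int(rng.integers(0, n_desired + 1)),
            seed=seed + 1000,
        )
        problem = generate_problem(spec)
        direct = brute_force_cmcs(problem)
        compressed, record = preprocess(problem)
        if record.infeasible:
            assert direct == []
            return
        via_compression = expand_solutions(
            brute_force_cmcs(compressed), record
        )
        assert via_compression == direct
        # essential reactions never appear in any solution
        for cs in direct:
            assert not set(cs) & set(record.essential)
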