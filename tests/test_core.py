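"""Unit tests for the FAM core operations."""

import numpy as np
import pandas as pd
import pytest

import famrank as fr
from famrank.errors import ConfigError, DataError, MissingDataError, OutOfBoundsError


def frame_of(rows):
    return pd.DataFrame(rows, columns=["condition_id", "criterion_id", "replicate_id", "value"])


class TestComputeBounds:
    def test_min_max_of_values(self):
        recs = frame_of([("c1", "tpc", 1, 2.0), ("c1", "tpc", 2, 5.0), ("c2", "tpc", 1, 9.0)])
        b = fr.compute_bounds(recs, "tpc")
        assert (b.a, b.b) == (2.0, 9.0)

    def test_singleton(self):
        b = fr.compute_bounds(frame_of([("c1", "tac", 1, 4.0)]), "tac")
        assert (b.a, b.b) == (4.0, 4.0)
        assert b.degenerate

    def test_pooled_over_conditions_matches_flat_scan(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"c{i}", "rehydration", r, float(v))
            for i in range(27)
            for r, v in enumerate(rng.normal(250, 30, 3), 1)
        ]
        recs = frame_of(rows)
        flat = [v for *_, v in rows]
        b = fr.compute_bounds(recs, "rehydration")
        assert b.a == min(flat) and b.b == max(flat)

    def test_missing_criterion_is_an_error_naming_it(self):
        with pytest.raises(MissingDataError, match="tfc"):
            fr.compute_bounds(frame_of([("c1", "tpc", 1, 1.0)]), "tfc")


class TestFuzzyScale:
    bounds = fr.ScaleBounds("x", 2.0, 9.0)

    def test_endpoints(self):
        assert fr.fuzzy_scale(9.0, self.bounds, "benefit") == 10.0
        assert fr.fuzzy_scale(2.0, self.bounds, "benefit") == 0.0
        assert fr.fuzzy_scale(2.0, self.bounds, "cost") == 10.0
        assert fr.fuzzy_scale(9.0, self.bounds, "cost") == 0.0

    def test_midpoint_is_5_either_direction(self):
        mid = (2.0 + 9.0) / 2
        assert fr.fuzzy_scale(mid, self.bounds, "benefit") == pytest.approx(5.0, abs=1e-9)
        assert fr.fuzzy_scale(mid, self.bounds, "cost") == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_bounds_give_neutral_score_with_warning(self):
        flat = fr.ScaleBounds("x", 4.0, 4.0)
        with pytest.warns(UserWarning, match="constant"):
            assert fr.fuzzy_scale(4.0, flat) == 5.0

    def test_out_of_bounds_value_rejected(self):
        with pytest.raises(OutOfBoundsError):
            fr.fuzzy_scale(9.5, self.bounds)

    def test_array_input(self):
        out = fr.fuzzy_scale(np.array([2.0, 5.5, 9.0]), self.bounds)
        np.testing.assert_allclose(out, [0.0, 5.0, 10.0], atol=1e-9)


class TestGradeMemberships:
    def test_apexes_hold_full_membership(self):
        np.testing.assert_array_equal(fr.grade_memberships(10.0), [1, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(fr.grade_memberships(0.0), [0, 0, 0, 0, 0, 1])

    def test_interpolation_between_apexes(self):
        np.testing.assert_allclose(
            fr.grade_memberships(9.0), [0.5, 0.5, 0, 0, 0, 0], atol=1e-12
        )
        np.testing.assert_allclose(
            fr.grade_memberships(3.0), [0, 0, 0, 0.5, 0.5, 0], atol=1e-12
        )

    def test_score_outside_scale_rejected(self):
        with pytest.raises(OutOfBoundsError):
            fr.grade_memberships(10.5)
        with pytest.raises(OutOfBoundsError):
            fr.grade_memberships(-0.1)

    def test_custom_grade_set(self):
        gs = fr.GradeSet(labels=("good", "bad"), apexes=(10.0, 0.0))
        np.testing.assert_allclose(gs.memberships(2.5), [0.25, 0.75], atol=1e-12)

    def test_invalid_grade_sets_rejected(self):
        with pytest.raises(ConfigError):
            fr.GradeSet(apexes=(10.0, 8.0, 8.0, 4.0, 2.0, 0.0))  # not decreasing
        with pytest.raises(ConfigError):
            fr.GradeSet(apexes=(12.0, 8.0, 6.0, 4.0, 2.0, 0.0))  # outside [0, 10]


class TestWeighting:
    def test_sensory_panelist_share(self):
        crit = fr.CriterionSpec("flavor", "sensory", 10.0, "benefit", 30)
        assert fr.per_datum_weight(crit, 30) == pytest.approx(1 / 3, abs=1e-12)

    def test_instrumental_replicate_share(self):
        crit = fr.CriterionSpec("tac", "bioactive", 20.0, "benefit", 3)
        assert fr.per_datum_weight(crit, 3) == pytest.approx(20 / 3, abs=1e-12)

    def test_zero_weight_criterion(self):
        crit = fr.CriterionSpec("x", "physical", 0.0)
        assert fr.per_datum_weight(crit, 5) == 0.0

    def test_no_data_is_an_error(self):
        with pytest.raises(DataError):
            fr.per_datum_weight(fr.CriterionSpec("x", "physical", 1.0), 0)


class TestIndexScore:
    def test_scaling(self):
        s = fr.index_score([1, 0, 0, 0, 0, 0], 15.0)
        np.testing.assert_array_equal(s.masses, [15, 0, 0, 0, 0, 0])
        assert s.total_weight == 15.0

    def test_split_membership(self):
        s = fr.index_score([0.5, 0.5, 0, 0, 0, 0], 1 / 3)
        np.testing.assert_allclose(s.masses[:2], [1 / 6, 1 / 6], atol=1e-12)

    def test_zero_weight_gives_zero_vector(self):
        assert fr.index_score([0, 1, 0, 0, 0, 0], 0.0).masses.sum() == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigError):
            fr.index_score([1, 0, 0, 0, 0, 0], -1.0)


class TestAggregate:
    def test_complete_condition_totals_100(self, criteria):
        scores = []
        rng = np.random.default_rng(0)
        for crit in criteria:
            n = crit.expected_n
            for _ in range(n):
                mu = fr.grade_memberships(float(rng.uniform(0, 10)))
                scores.append(fr.index_score(mu, crit.weight / n))
        assert len(scores) == 108
        total = fr.aggregate(scores)
        assert total.total_weight == pytest.approx(100.0, abs=1e-9)
        assert total.masses.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_score_identity_and_order_independence(self):
        a = fr.index_score([1, 0, 0, 0, 0, 0], 5.0)
        b = fr.index_score([0, 1, 0, 0, 0, 0], 7.0)
        np.testing.assert_array_equal(fr.aggregate([a]).masses, a.masses)
        np.testing.assert_allclose(
            fr.aggregate([a, b]).masses, fr.aggregate([b, a]).masses, atol=1e-12
        )

    def test_empty_collection_rejected(self):
        with pytest.raises(DataError):
            fr.aggregate([])


class TestDefuzzify:
    def test_single_grade_centroids(self):
        all_a = fr.IndexScore(np.array([100.0, 0, 0, 0, 0, 0]), 100.0)
        all_f = fr.IndexScore(np.array([0, 0, 0, 0, 0, 100.0]), 100.0)
        assert fr.defuzzify(all_a) == 10.0
        assert fr.defuzzify(all_f) == 0.0

    def test_uniform_mass_gives_midscale(self):
        s = fr.IndexScore(np.full(6, 100 / 6), 100.0)
        assert fr.defuzzify(s) == pytest.approx(5.0, abs=1e-9)

    def test_split_mass(self):
        s = fr.IndexScore(np.array([50.0, 50.0, 0, 0, 0, 0]), 100.0)
        assert fr.defuzzify(s) == pytest.approx(9.0, abs=1e-9)

    def test_zero_weight_rejected(self):
        with pytest.raises(DataError):
            fr.defuzzify(fr.IndexScore(np.zeros(6), 0.0))


class TestRankConditions:
    def test_ranks_are_a_permutation(self, criteria):
        ranking = fr.rank_conditions(fr.simulate(seed=3), criteria)
        assert len(ranking.table) == 27
        assert sorted(ranking.table["rank"]) == list(range(1, 28))
        assert ranking.table["overall_index"].between(0, 10).all()

    def test_missing_cell_is_fatal_and_named(self, small_dataset, criteria):
        broken = small_dataset[
            ~((small_dataset.condition_id == "c2") & (small_dataset.criterion_id == "tac"))
        ]
        with pytest.raises(MissingDataError, match=r"c2.*tac"):
            fr.rank_conditions(broken, criteria)

    def test_hardness_sign_flip_symmetry(self, small_dataset, criteria):
        """Negating all hardness values while flipping its direction flag
        leaves the ranking unchanged (forward and reverse transforms mirror)."""
        base = fr.rank_conditions(small_dataset, criteria)
        flipped_data = small_dataset.copy()
        mask = flipped_data.criterion_id == "hardness"
        flipped_data.loc[mask, "value"] *= -1
        flipped_criteria = [
            fr.CriterionSpec(c.id, c.group, c.weight, "benefit", c.expected_n)
            if c.id == "hardness"
            else c
            for c in criteria
        ]
        flipped = fr.rank_conditions(flipped_data, flipped_criteria)
        merged = base.table.merge(flipped.table, on="condition_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["overall_index_a"], merged["overall_index_b"], atol=1e-9
        )

    def test_ties_share_rank_and_are_flagged(self, criteria):
        # identical conditions -> identical indices -> competition ranking
        rows = []
        for cond in ("x", "y", "z"):
            for crit in criteria:
                for rep in range(1, crit.expected_n + 1):
                    v = 5.0 if cond in ("x", "y") else float(rep)
                    rows.append((cond, crit.id, rep, v))
        frame = pd.DataFrame(rows, columns=["condition_id", "criterion_id", "replicate_id", "value"])
        ranking = fr.rank_conditions(frame, criteria)
        tbl = ranking.table.set_index("condition_id")
        assert tbl.loc["x", "rank"] == tbl.loc["y", "rank"]
        assert bool(tbl.loc["x", "tie_flag"]) and bool(tbl.loc["y", "tie_flag"])
        # tied block ordered by condition_id
        tied = ranking.table[ranking.table.tie_flag]["condition_id"].tolist()
        assert tied == sorted(tied)

    def test_unknown_criterion_in_data_rejected(self, small_dataset, criteria):
        bad = pd.concat(
            [small_dataset, frame_of([("c1", "mystery", 1, 1.0)])], ignore_index=True
        )
        with pytest.raises(ConfigError, match="mystery"):
            fr.rank_conditions(bad, criteria)

    def test_weights_must_sum_to_100_unless_disabled(self, small_dataset, criteria):
        doubled = [
            fr.CriterionSpec(c.id, c.group, 2 * c.weight, c.direction, c.expected_n)
            for c in criteria
        ]
        with pytest.raises(ConfigError, match="sum to 100"):
            fr.rank_conditions(small_dataset, doubled)
        fr.rank_conditions(small_dataset, doubled, check_weights=False)  # no raise
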