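"""Census arithmetic, reference stability, normalization and fold changes."""

import numpy as np
import pandas as pd
import pytest

import morscreen as ms
from morscreen.data_model import ExpressionMatrix, ValidationError
from morscreen import preprocess as prep

from conftest import toy_cq, toy_meta


def cohort_from_foc(foc_control, foc_case, n_control=28, n_case=22,
                    cutoff=34.0):
    """Build a cohort whose single assay is detected in exactly the given
    number of samples per group."""
    row = ([25.0] * foc_control + [None] * (n_control - foc_control)
           + [25.0] * foc_case + [None] * (n_case - foc_case))
    cq = toy_cq([row], samples=[f"s{i}" for i in range(n_control + n_case)])
    meta = toy_meta(["control"] * n_control + ["case"] * n_case,
                    samples=[f"s{i}" for i in range(n_control + n_case)])
    return ms.join_metadata(cq, meta)


class TestCensus:
    @pytest.mark.parametrize("foc_c,foc_a,label", [
        (19, 17, "A"),     # abundant-stratum thresholds at 28/22
        (28, 22, "A"),
        (18, 17, "B"),     # one count short on the control side
        (19, 16, "B"),
        (3, 3, "B"),
        (2, 10, "excluded"),   # below the min-FOC filter in one group
        (10, 2, "excluded"),
        (0, 0, "undetected"),
    ])
    def test_set_assignment(self, foc_c, foc_a, label):
        cohort = cohort_from_foc(foc_c, foc_a)
        census = ms.detection_census(cohort)
        assert census.table["set_label"].iloc[0] == label
        assert census.table["foc_control"].iloc[0] == foc_c
        assert census.table["foc_case"].iloc[0] == foc_a

    def test_percent_is_floor(self):
        assert ms.detection_percent(441, 1178) == 37
        assert ms.detection_percent(0, 10) == 0
        assert ms.detection_percent(10, 10) == 100

    def test_partition_covers_panel(self, joined):
        census = ms.detection_census(joined)
        s = census.summary
        n_undet = int((census.table["set_label"] == "undetected").sum())
        assert s.n_set_a + s.n_set_b + s.n_excluded + n_undet == s.panel_size
        assert s.n_detected + s.n_undetected == s.panel_size

    def test_invariant_to_sample_order(self, joined):
        census = ms.detection_census(joined)
        order = list(reversed(joined.cq.sample_ids))
        flipped = ms.Cohort(joined.cq.subset_samples(order),
                            ms.CohortMetadata(joined.meta.table.loc[order]))
        census2 = ms.detection_census(flipped)
        assert census.table.equals(census2.table)

    def test_thresholds_scale_with_group_size(self):
        # at 14/11 samples the abundant thresholds halve (ceil of fractions)
        cohort = cohort_from_foc(10, 9, n_control=14, n_case=11)
        census = ms.detection_census(cohort)
        assert census.table["set_label"].iloc[0] == "A"


class TestSelectReferences:
    def make_cohort(self, rows, n_c=4, n_a=4):
        samples = [f"s{i}" for i in range(n_c + n_a)]
        cq = toy_cq(rows, samples=samples,
                    assays=[f"cand{i+1}" for i in range(len(rows))])
        meta = toy_meta(["control"] * n_c + ["case"] * n_a, samples=samples)
        return ms.join_metadata(cq, meta)

    def test_constant_candidate_has_stability_zero_and_ranks_first(self):
        cohort = self.make_cohort([
            [20.0] * 8,
            [20.0, 21.0, 20.5, 19.5, 22.0, 21.5, 20.0, 19.0],
        ])
        table = ms.select_references(cohort, n_refs=1)
        assert table.index[0] == "cand1"
        assert table.loc["cand1", "stability"] == 0.0

    def test_group_biased_candidate_ranks_last(self):
        """Oracle: explicit variance decomposition on two candidates.

        cand1: pure noise, no group effect; cand2: same noise pattern plus a
        1-cycle group shift.  The decomposition gives cand1 stability
        sqrt(0 + var), cand2 sqrt(0.25 + var): the unbiased one wins.
        """
        noise = [20.0, 20.4, 19.8, 20.2, 20.1, 19.9, 20.3, 19.7]
        biased = [v + (1.0 if i >= 4 else 0.0) for i, v in enumerate(noise)]
        cohort = self.make_cohort([noise, biased])
        table = ms.select_references(cohort, n_refs=1)
        assert table.index[0] == "cand1"
        # oracle values
        x = np.array(noise)
        var_within = (x[:4].var(ddof=1) + x[4:].var(ddof=1)) / 2
        bias_sq = ((x[:4].mean() - x.mean()) ** 2
                   + (x[4:].mean() - x.mean()) ** 2) / 2
        assert table.loc["cand1", "stability"] == pytest.approx(
            np.sqrt(bias_sq + var_within))
        y = np.array(biased)
        bias2 = ((y[:4].mean() - y.mean()) ** 2
                 + (y[4:].mean() - y.mean()) ** 2) / 2
        w2 = (y[:4].var(ddof=1) + y[4:].var(ddof=1)) / 2
        assert table.loc["cand2", "stability"] == pytest.approx(
            np.sqrt(bias2 + w2))

    def test_tie_breaks_by_assay_id(self):
        cohort = self.make_cohort([[20.0] * 8, [21.0] * 8])
        table = ms.select_references(cohort, n_refs=2)
        assert list(table.index[:2]) == ["cand1", "cand2"]

    def test_no_fully_detected_assay_is_an_error(self):
        rows = [[None, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0, 25.0]]
        cohort = self.make_cohort(rows)
        with pytest.raises(ValidationError, match="reference"):
            ms.select_references(cohort)

    def test_candidates_restricted_to_fully_detected(self):
        rows = [[20.0] * 8,
                [20.0] * 7 + [None]]  # would be perfectly stable but has a hole
        cohort = self.make_cohort(rows)
        table = ms.select_references(cohort, n_refs=1)
        assert "cand2" not in table.index


class TestNormalize:
    def test_hand_arithmetic(self):
        cq = toy_cq([[20.0], [22.0], [25.0]], assays=["r1", "r2", "t"])
        expr = ms.normalize(cq, ["r1", "r2"])
        assert expr.values.loc["t", "s1"] == 4.0
        assert expr.values.loc["r1", "s1"] == -1.0

    def test_dcq_zero_means_relative_expression_one(self):
        cq = toy_cq([[21.0], [21.0]], assays=["r1", "t"])
        expr = ms.normalize(cq, ["r1"])
        lin = expr.as_scale("rel_linear")
        assert lin.values.loc["t", "s1"] == 1.0

    def test_per_sample_shift_invariance(self):
        base = toy_cq([[20.0, 21.0], [22.0, 23.0], [25.0, 30.0]],
                      assays=["r1", "r2", "t"])
        shifted = toy_cq([[23.0, 20.5], [25.0, 22.5], [28.0, 29.5]],
                         assays=["r1", "r2", "t"])  # +3 on s1, -0.5 on s2
        e1 = ms.normalize(base, ["r1", "r2"])
        e2 = ms.normalize(shifted, ["r1", "r2"])
        assert e1.values.equals(e2.values)

    def test_missing_target_stays_missing(self):
        cq = toy_cq([[20.0], [None]], assays=["r1", "t"])
        expr = ms.normalize(cq, ["r1"])
        assert np.isnan(expr.values.loc["t", "s1"])

    def test_strict_mode_rejects_missing_reference(self):
        cq = toy_cq([[20.0, None], [22.0, 22.0], [25.0, 25.0]],
                    assays=["r1", "r2", "t"])
        with pytest.raises(ValidationError, match="r1"):
            ms.normalize(cq, ["r1", "r2"], strict=True)
        # lenient mode falls back to the available reference
        expr = ms.normalize(cq, ["r1", "r2"], strict=False)
        assert expr.values.loc["t", "s2"] == 3.0

    def test_undetected_wells_masked(self):
        cq = toy_cq([[20.0], [35.5]], assays=["r1", "t"], cutoff=34.0)
        expr = ms.normalize(cq, ["r1"])
        assert np.isnan(expr.values.loc["t", "s1"])


class TestFoldChanges:
    def run(self, control_vals, case_vals, threshold=1.5):
        vals = pd.DataFrame(
            [list(control_vals) + list(case_vals)], index=["t"],
            columns=[f"s{i}" for i in range(len(control_vals) + len(case_vals))])
        expr = ExpressionMatrix(vals, "delta_cq")
        group = pd.Series(["control"] * len(control_vals)
                          + ["case"] * len(case_vals), index=vals.columns)
        return ms.fold_changes(expr, group, "control", "case", threshold)

    def test_no_change_is_flat_with_p_one(self):
        fc = self.run([1.0, 1.0], [1.0, 1.0])
        row = fc.table.loc["t"]
        assert row["fold_change"] == 1.0
        assert row["call"] == "flat"
        assert row["p_value"] == 1.0

    def test_one_cycle_drop_doubles_expression(self):
        fc = self.run([2.0, 2.0], [1.0, 1.0])
        assert fc.table.loc["t", "fold_change"] == 2.0
        assert fc.table.loc["t", "call"] == "up"

    def test_boundary_fold_change(self):
        # mean dCq 4.0 vs 3.415 => FC = 2**0.585 = 1.50004, just above 1.5
        fc = self.run([4.0, 4.0], [3.415, 3.415])
        assert fc.table.loc["t", "fold_change"] == pytest.approx(
            2 ** 0.585, rel=1e-12)
        assert fc.table.loc["t", "call"] == "up"
        # exactly at the threshold counts as up (FC >= threshold)
        dd = np.log2(1.5)
        fc2 = self.run([4.0, 4.0], [4.0 - dd, 4.0 - dd])
        assert fc2.table.loc["t", "call"] == "up"
        # clearly below the threshold stays flat
        fc3 = self.run([4.0, 4.0], [3.43, 3.43])
        assert fc3.table.loc["t", "call"] == "flat"

    def test_down_call_symmetric(self):
        fc = self.run([1.0, 1.0], [2.0, 2.0])
        assert fc.table.loc["t", "fold_change"] == 0.5
        assert fc.table.loc["t", "call"] == "down"

    def test_volcano_counts_match_brute_force(self, joined):
        census = ms.detection_census(joined)
        refs = ms.select_references(joined, 2)
        expr = ms.normalize(joined.cq, list(refs.index[refs["selected"]]),
                            strict=False)
        members = census.set_members("A") + census.set_members("B")
        fc = ms.fold_changes(expr.values.loc[members], joined.group,
                             "control", "case", 1.5)
        counts = fc.counts()
        t = fc.table
        assert counts["up"] == int((t["fold_change"] >= 1.5).sum())
        assert counts["down"] == int((t["fold_change"] <= 1 / 1.5).sum())
        assert counts["up"] + counts["down"] + counts["flat"] == len(t)


class TestSubstituteMissing:
    def test_group_mean_fills_hole(self):
        vals = pd.DataFrame([[0.5, 1.5, 1.0, 3.0, np.nan]], index=["t"],
                            columns=[f"s{i}" for i in range(5)])
        group = pd.Series(["control", "control", "case", "case", "case"],
                          index=vals.columns)
        out = ms.substitute_missing(ExpressionMatrix(vals), group)
        assert out.values.loc["t", "s4"] == 2.0

    def test_identity_without_missing(self):
        vals = pd.DataFrame([[0.5, 1.5, 1.0, 3.0]], index=["t"],
                            columns=[f"s{i}" for i in range(4)])
        group = pd.Series(["control", "control", "case", "case"],
                          index=vals.columns)
        out = ms.substitute_missing(ExpressionMatrix(vals), group)
        assert out.values.equals(vals)

    def test_group_means_unchanged(self, joined):
        census = ms.detection_census(joined)
        refs = ms.select_references(joined, 2)
        expr = ms.normalize(joined.cq, list(refs.index[refs["selected"]]),
                            strict=False)
        members = census.set_members("A")
        sub = ms.substitute_missing(
            ExpressionMatrix(expr.values.loc[members]), joined.group)
        for lab in ("control", "case"):
            cols = joined.group.index[joined.group == lab]
            before = expr.values.loc[members, cols].mean(axis=1, skipna=True)
            after = sub.values.loc[members, cols].mean(axis=1)
            assert np.allclose(before, after)

    def test_empty_group_named_in_error(self):
        vals = pd.DataFrame([[np.nan, np.nan, 1.0, 3.0]], index=["badmarker"],
                            columns=[f"s{i}" for i in range(4)])
        group = pd.Series(["control", "control", "case", "case"],
                          index=vals.columns)
        with pytest.raises(ValidationError, match="badmarker"):
            ms.substitute_missing(ExpressionMatrix(vals), group)
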