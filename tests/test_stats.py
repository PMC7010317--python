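"""Group statistics: Fisher/FDR oracles, ANOVA cross-checks, reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from blebquant import (
    ContingencyTable,
    blebbing_table,
    fa_group_test,
    fisher_pairwise_fdr,
    spreading_sample_size,
    write_report,
)

from conftest import bh_step_up, fisher_two_sided_enumeration


class TestBlebbingTable:
    def test_single_group_frequency(self):
        df = pd.DataFrame({"group": ["a"] * 10, "blebbing": [True] * 3 + [False] * 7})
        table = blebbing_table(df)
        assert table.counts.tolist() == [[3, 7]]
        assert table.frequencies[0] == pytest.approx(0.30)

    def test_group_order_preserved(self):
        df = pd.DataFrame(
            {"group": ["z", "a", "z", "m"], "blebbing": [True, False, False, True]}
        )
        table = blebbing_table(df, group_order=["m", "z", "a"])
        assert table.groups == ["m", "z", "a"]
        assert table.counts.tolist() == [[1, 0], [1, 1], [0, 1]]

    def test_empty_group_raises_with_name(self):
        df = pd.DataFrame({"group": ["a"] * 3, "blebbing": [True] * 3})
        with pytest.raises(ValueError, match="ghost"):
            blebbing_table(df, group_order=["a", "ghost"])

    def test_counts_match_generator_tallies(self, scene_batch):
        rows = []
        for g, scene in zip(("wt", "wt", "ko", "ko"), scene_batch[:4]):
            for bleb in scene.truth.blebbing_labels:
                rows.append({"group": g, "blebbing": bleb})
        df = pd.DataFrame(rows)
        table = blebbing_table(df)
        expected = df.groupby("group", sort=False)["blebbing"].agg(["sum", "count"])
        for g, row in zip(table.groups, table.counts):
            assert row[0] == expected.loc[g, "sum"]
            assert row.sum() == expected.loc[g, "count"]


class TestFisherPairwise:
    def test_known_two_sided_p_from_enumeration(self):
        table = ContingencyTable(groups=["a", "b"], counts=[[3, 1], [1, 3]])
        results, _ = fisher_pairwise_fdr(table)
        assert results[0].p_raw == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_rows_give_p_one(self):
        table = ContingencyTable(groups=["a", "b"], counts=[[5, 5], [5, 5]])
        results, _ = fisher_pairwise_fdr(table)
        assert results[0].p_raw == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_for_small_margins(self):
        """Point-probability two-sided p equals full enumeration to 1e-12."""
        rng = np.random.default_rng(0)
        tables = [
            [[a, b], [c, d]]
            for a, b, c, d in rng.integers(0, 11, size=(200, 4))
            if (a + b) > 0 and (c + d) > 0 and (a + b + c + d) > 0
        ]
        tables += [[[0, 10], [10, 0]], [[10, 10], [10, 10]], [[1, 0], [0, 1]]]
        for t in tables:
            ct = ContingencyTable(groups=["x", "y"], counts=t)
            got = fisher_pairwise_fdr(ct)[0][0].p_raw
            assert got == pytest.approx(fisher_two_sided_enumeration(t), abs=1e-12)

    def test_bh_adjustment_matches_step_up_formula(self):
        table = ContingencyTable(
            groups=list("abcd"),
            counts=[[30, 70], [45, 55], [60, 40], [75, 25]],
        )
        results, matrix = fisher_pairwise_fdr(table)
        raw = np.array([r.p_raw for r in results])
        expected = bh_step_up(raw)
        np.testing.assert_allclose([r.p_adjusted for r in results], expected, atol=1e-12)
        for r in results:
            assert r.p_raw <= r.p_adjusted <= 1.0

    def test_hand_computed_bh_case(self):
        # raw (0.01, 0.02, 0.03, 0.04) over 4 pairs -> all adjusted to 0.04
        np.testing.assert_allclose(
            bh_step_up([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matrix_symmetric_with_unit_diagonal(self):
        table = ContingencyTable(
            groups=list("abc"), counts=[[10, 30], [20, 20], [30, 10]]
        )
        _, matrix = fisher_pairwise_fdr(table)
        np.testing.assert_allclose(matrix.values, matrix.values.T)
        np.testing.assert_allclose(np.diag(matrix.values), 1.0)

    def test_zero_total_pair_raises(self):
        table = ContingencyTable(groups=["a", "b"], counts=[[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="zero total"):
            fisher_pairwise_fdr(table)

    def test_null_calibration_single_pair(self):
        """Type-I error of the unadjusted single-pair test near nominal 0.05."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.binomial(100, 0.5)
            b = rng.binomial(100, 0.5)
            ct = ContingencyTable(groups=["g1", "g2"], counts=[[a, 100 - a], [b, 100 - b]])
            if fisher_pairwise_fdr(ct)[0][0].p_raw < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


def _balanced_null(rng, n=100, scale=30):
    rows = []
    for a in ("wt", "ko"):
        for b in ("vehicle", "treated"):
            counts = rng.poisson(scale, n) + 5
            rows += [{"a": a, "b": b, "fa_count": c} for c in counts]
    return pd.DataFrame(rows)


class TestFaGroupTest:
    def test_interaction_type_i_error_calibrated(self):
        """Null 2x2 designs reject the interaction near the nominal rate."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            res = fa_group_test(_balanced_null(rng, n=25), "a", "b")
            if res["interaction_p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_shifted_group_detected_by_tukey(self):
        """A 2x mean shift in one design cell is flagged in >= 90% of runs."""
        rng = np.random.default_rng(11)
        hits = 0
        runs = 100
        for _ in range(runs):
            df = _balanced_null(rng, n=100)
            shift = (df["a"] == "ko") & (df["b"] == "treated")
            df.loc[shift, "fa_count"] *= 2
            res = fa_group_test(df, "a", "b")
            flagged = {
                frozenset(r.pair)
                for r in res["tukey"]
                if r.extra.get("reject")
            }
            target = {
                frozenset({"ko/treated", other})
                for other in ("wt/vehicle", "wt/treated", "ko/vehicle")
            }
            if target <= flagged:
                hits += 1
        assert hits >= 90

    def test_degenerate_identical_values_report_no_variance(self):
        df = pd.DataFrame(
            {
                "a": ["wt", "wt", "ko", "ko"] * 5,
                "b": ["v", "t", "v", "t"] * 5,
                "fa_count": [10] * 20,
            }
        )
        res = fa_group_test(df, "a", "b")
        assert res["no_variance"] is True
        assert all(r.p_adjusted == 1.0 for r in res["tukey"] + res["rank"])

    def test_empty_design_cell_raises(self):
        df = pd.DataFrame(
            {"a": ["wt", "wt", "ko"], "b": ["v", "t", "v"], "fa_count": [5, 6, 7]}
        )
        with pytest.raises(ValueError, match="empty design cell"):
            fa_group_test(df, "a", "b")

    def test_anova_main_effect_agrees_with_permutation_oracle(self):
        """Parametric p within 0.02 of a 10,000-draw permutation p."""
        rng = np.random.default_rng(3)
        df = _balanced_null(rng, n=50)
        res = fa_group_test(df, "a", "b")
        p_param = float(res["anova"].loc["C(_a)", "PR(>F)"])
        y = np.log10(df["fa_count"].to_numpy(dtype=float))
        cells = (df["a"] + "/" + df["b"]).to_numpy()
        _, cell_idx = np.unique(cells, return_inverse=True)
        a_of_cell = np.array([0, 0, 1, 1])  # ko/t, ko/v, wt/t, wt/v
        f_obs = _f_main(y, cell_idx, a_of_cell)
        draws = np.empty(10_000)
        for i in range(10_000):
            draws[i] = _f_main(rng.permutation(y), cell_idx, a_of_cell)
        p_perm = float((draws >= f_obs).mean())
        assert abs(p_param - p_perm) <= 0.02

    def test_rank_alternative_present_with_bh(self):
        rng = np.random.default_rng(5)
        res = fa_group_test(_balanced_null(rng, n=30), "a", "b")
        assert len(res["rank"]) == 6
        raw = [r.p_raw for r in res["rank"]]
        np.testing.assert_allclose(
            [r.p_adjusted for r in res["rank"]], bh_step_up(raw), atol=1e-12
        )


def _f_main(y, cell_idx, a_of_cell):
    """Balanced two-way main-effect F computed from cell means directly."""
    n_cells = 4
    ns = np.bincount(cell_idx, minlength=n_cells)
    sums = np.bincount(cell_idx, weights=y, minlength=n_cells)
    cell_means = sums / ns
    grand = y.mean()
    n_per = ns[0]
    a_means = np.array(
        [cell_means[a_of_cell == 0].mean(), cell_means[a_of_cell == 1].mean()]
    )
    b_of_cell = np.array([0, 1, 0, 1])
    b_means = np.array(
        [cell_means[b_of_cell == 0].mean(), cell_means[b_of_cell == 1].mean()]
    )
    ss_a = 2 * n_per * np.sum((a_means - grand) ** 2)
    fitted = cell_means[cell_idx]
    sse = np.sum((y - fitted) ** 2)
    return (ss_a / 1.0) / (sse / (y.size - n_cells))


class TestSpreadingSampleSize:
    def test_study_design_totals_seventy_two(self):
        assert spreading_sample_size(8, 3, 3) == 72

    def test_minimal_design(self):
        assert spreading_sample_size(1, 1, 1) == 1

    @pytest.mark.parametrize("a,b,c", [(2, 3, 4), (5, 1, 7), (8, 3, 3)])
    def test_equals_nested_loop_enumeration(self, a, b, c):
        total = sum(1 for _ in itertools.product(range(a), range(b), range(c)))
        assert spreading_sample_size(a, b, c) == total

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            spreading_sample_size(0, 3, 3)


class TestWriteReport:
    def test_rerun_is_byte_identical(self, tmp_path):
        table = ContingencyTable(groups=["a", "b"], counts=[[3, 7], [6, 4]])
        _, matrix = fisher_pairwise_fdr(table)
        df = pd.DataFrame({"cell_id": [1, 2], "fa_count": [5, 6]})
        for d in ("one", "two"):
            write_report(
                tmp_path / d,
                features=df,
                contingency=table,
                p_matrix=matrix,
                manifest={"seed": 1, "fa_upper_cutoff": 99.01},
            )
        for name in ("cell_features.csv", "group_frequencies.csv",
                     "fisher_fdr_matrix.csv", "manifest.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_manifest_records_realized_cutoff(self, tmp_path):
        import json

        from blebquant import apply_fa_cutoffs

        df = pd.DataFrame({"cell_id": range(100), "fa_count": range(1, 101)})
        res = apply_fa_cutoffs(df)
        write_report(tmp_path, manifest={"fa_upper_cutoff": res.upper_cutoff})
        saved = json.loads((tmp_path / "manifest.json").read_text())
        assert saved["fa_upper_cutoff"] == pytest.approx(99.01)
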