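"""Group statistics, positional profiles and the classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from topoland.group_stats_classify import (
    ablation_suite,
    assemble_feature_table,
    compare_groups,
    fisher_exact_2x2,
    positional_profile,
    stars,
    train_evaluate_classifier,
)


class TestStars:
    @pytest.mark.parametrize(
        "p,symbol",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.05, "#"), (0.5, "#")],
    )
    def test_threshold_scheme(self, p, symbol):
        assert stars(p) == symbol


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, size=200)
        labels = ["a"] * 100 + ["b"] * 100
        res = compare_groups(values, labels)
        assert res.test == "kruskal_wallis"
        assert res.p_value > 0.05
        assert res.stars == "#"

    def test_two_sd_shift_overwhelmingly_significant(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        labels = ["a"] * 100 + ["b"] * 100
        res = compare_groups(values, labels)
        assert res.p_value < 0.001
        assert res.stars == "***"
        assert res.direction == "b"

    def test_boolean_column_routes_to_fisher(self):
        values = [True] * 20 + [False] * 10 + [True] * 10 + [False] * 20
        labels = ["a"] * 30 + ["b"] * 30
        res = compare_groups(values, labels)
        assert res.test == "fisher_exact"
        assert res.statistic == pytest.approx(4.0)  # odds ratio of [[20,10],[10,20]]
        assert res.direction == "a"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_missing_values_dropped(self):
        values = pd.Series([1.0, 2.0, np.nan, 3.0, 4.0, 5.0, np.nan, 6.0])
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        res = compare_groups(values, labels)
        assert res.test == "kruskal_wallis"

    def test_kruskal_null_pvalues_uniform(self):
        # Calibration: p-values under the null pass a KS uniformity check.
        rng = np.random.default_rng(42)
        pvalues = []
        for _ in range(1000):
            values = rng.normal(0, 1, size=100)
            labels = ["a"] * 50 + ["b"] * 50
            pvalues.append(compare_groups(values, labels).p_value)
        assert kstest(pvalues, "uniform").pvalue > 0.01


def _oracle_fisher_p(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided exact test."""
    r1, c1 = a + b, a + c
    N = a + b + c + d
    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    return float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_oracle_agreement_on_fixed_table(self):
        odds, p = fisher_exact_2x2([[20, 10], [10, 20]])
        assert odds == pytest.approx(4.0)
        assert p == pytest.approx(_oracle_fisher_p(20, 10, 10, 20), rel=1e-9)

    def test_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(_oracle_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12)


class TestAssembleFeatureTable:
    def _frames(self):
        seq = pd.DataFrame({"gravy": [0.1, 0.2]}, index=["P1", "P2"])
        struct = pd.DataFrame({"rco": [0.3]}, index=["P1"])
        return {"sequence": seq, "structure": struct}

    def test_missing_structure_masks_cells_keeps_row(self):
        labels = pd.Series(["cytoplasmome", "secretome"], index=["P1", "P2"])
        table = assemble_feature_table(self._frames(), labels)
        assert len(table) == 2
        assert np.isnan(table.loc["P2", "rco"])
        assert table.loc["P2", "group"] == "secretome"

    def test_complete_inputs_have_no_masked_cells(self):
        frames = {"a": pd.DataFrame({"x": [1.0, 2.0]}, index=["P1", "P2"])}
        labels = pd.Series(["g1", "g2"], index=["P1", "P2"])
        table = assemble_feature_table(frames, labels)
        assert not table.isna().any().any()

    def test_duplicate_accession_rejected(self):
        frames = {"a": pd.DataFrame({"x": [1.0, 2.0]}, index=["P1", "P1"])}
        labels = pd.Series(["g"], index=["P1"])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(frames, labels)

    def test_feature_name_collision_rejected(self):
        frames = {
            "a": pd.DataFrame({"x": [1.0]}, index=["P1"]),
            "b": pd.DataFrame({"x": [2.0]}, index=["P1"]),
        }
        labels = pd.Series(["g"], index=["P1"])
        with pytest.raises(ValueError, match="collision"):
            assemble_feature_table(frames, labels)


class TestPositionalProfile:
    def test_constant_tracks_flat_profile(self):
        tracks = {f"P{i}": [0.5] * 100 for i in range(10)}
        membership = {f"P{i}": i < 5 for i in range(10)}
        profile = positional_profile(tracks, membership, n_positions=20)
        assert np.allclose(profile["mean_interactor"], 0.5)
        assert np.allclose(profile["mean_non_interactor"], 0.5)

    def test_constant_group_difference(self):
        tracks = {f"A{i}": [0.8] * 50 for i in range(5)} | {
            f"B{i}": [0.2] * 50 for i in range(5)
        }
        membership = {acc: acc.startswith("A") for acc in tracks}
        profile = positional_profile(tracks, membership, n_positions=30)
        assert np.allclose(profile["difference"], 0.6)

    def test_short_protein_drops_out(self):
        tracks = {"P1": [1.0] * 50, "P2": [0.0] * 90, "P3": [0.0] * 90}
        membership = {"P1": True, "P2": True, "P3": False}
        profile = positional_profile(tracks, membership, n_positions=90)
        assert profile.loc[50, "n_interactor"] == 2
        assert profile.loc[51, "n_interactor"] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            positional_profile({"P1": [1.0] * 10}, {"P1": True})


def _toy_table(n=60, n_features=5, separation=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["cytoplasmome"] * (n // 2) + ["secretome"] * (n // 2))
    X = rng.normal(0, 1, size=(n, n_features))
    X[y == "secretome", 0] += separation
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    table["group"] = y
    return table


class TestClassifier:
    def test_wide_margin_feature_gives_perfect_auc(self):
        table = _toy_table(separation=8.0)
        report = train_evaluate_classifier(table, n_repeats=2, seed=0)
        assert report.auc == pytest.approx(1.0)
        assert report.selected_features[0][0] == "f0"

    def test_permuted_labels_give_chance_auc(self):
        # A single permutation at moderate n carries spurious-AUC noise of a
        # few percent, so the null expectation is asserted on the mean over
        # several independent permutations.
        rng = np.random.default_rng(1)
        table = _toy_table(n=400, separation=4.0, seed=1)
        aucs = []
        for k in range(5):
            permuted = table.copy()
            permuted["group"] = rng.permutation(permuted["group"].to_numpy())
            aucs.append(train_evaluate_classifier(permuted, n_repeats=2, seed=k).auc)
        assert 0.45 < np.mean(aucs) < 0.55

    def test_noise_features_give_majority_class_accuracy(self):
        table = _toy_table(n=200, separation=0.0, seed=2)
        report = train_evaluate_classifier(table, n_repeats=3, seed=2)
        assert abs(report.accuracy - 0.5) < 0.1  # balanced classes

    def test_single_class_rejected(self):
        table = _toy_table()
        table["group"] = "cytoplasmome"
        with pytest.raises(ValueError):
            train_evaluate_classifier(table)

    def test_point_estimates_inside_cis(self):
        table = _toy_table(n=120, separation=1.5, seed=3)
        report = train_evaluate_classifier(table, n_repeats=2, seed=3)
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        assert report.accuracy_ci[0] <= report.accuracy <= report.accuracy_ci[1]

    def test_bit_identical_under_fixed_seed(self):
        table = _toy_table(n=120, separation=1.0, seed=4)
        a = train_evaluate_classifier(table, n_repeats=2, seed=7)
        b = train_evaluate_classifier(table, n_repeats=2, seed=7)
        assert a == b

    def test_leakage_canary_with_permuted_labels(self):
        # A feature equal to the ORIGINAL labels carries no information about
        # permuted labels; any pipeline leaking test-fold information through
        # imputation/selection would inflate this AUC toward 1.
        rng = np.random.default_rng(9)
        table = _toy_table(n=400, separation=0.0, seed=9)
        table["canary"] = (table["group"] == "secretome").astype(float)
        table["group"] = rng.permutation(table["group"].to_numpy())
        report = train_evaluate_classifier(table, n_repeats=3, seed=9)
        assert 0.4 < report.auc < 0.6


class TestAblationSuite:
    def _table_with_disorder(self, disorder_informative, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        y = np.array(["cytoplasmome"] * 100 + ["secretome"] * 100)
        table = pd.DataFrame(
            {
                "gravy": rng.normal(0, 1, n) + (y == "cytoplasmome") * 1.5,
                "rco": rng.normal(0, 1, n) + (y == "secretome") * 1.0,
                "idrs_per_100": rng.normal(0, 1, n)
                + (y == "secretome") * (1.5 if disorder_informative else 0.0),
                "idr_coverage": rng.normal(0, 1, n)
                + (y == "secretome") * (1.0 if disorder_informative else 0.0),
            }
        )
        table["group"] = y
        return table

    def test_three_labeled_reports(self):
        reports = ablation_suite(self._table_with_disorder(True), n_repeats=2)
        assert [r.label for r in reports] == ["all_features", "non_disorder", "disorder_only"]

    def test_all_features_at_least_as_good_as_disorder_only(self):
        reports = ablation_suite(self._table_with_disorder(True), n_repeats=2)
        by_label = {r.label: r for r in reports}
        assert by_label["all_features"].auc >= by_label["disorder_only"].auc - 1e-9

    def test_noise_disorder_features_score_at_chance(self):
        reports = ablation_suite(self._table_with_disorder(False), n_repeats=3)
        by_label = {r.label: r for r in reports}
        assert 0.4 < by_label["disorder_only"].auc < 0.6

    def test_table_without_disorder_features_rejected(self):
        table = _toy_table()
        with pytest.raises(ValueError, match="disorder"):
            ablation_suite(table)
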