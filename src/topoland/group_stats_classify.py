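"""Group comparisons, positional profiles and the topology-group classifier.

Numeric features are compared between topology groups with the
Kruskal–Wallis rank test (midranks, tie-corrected); boolean features with
Fisher's exact test on the 2×2 group × flag table.  Raw p-values map to the
conventional star scheme (*** p < 0.001, ** p < 0.01, * p < 0.05, # p >=
0.05); no multiplicity correction is applied by default.

The cytoplasmome-vs-secretome classifier is a seeded, repeated stratified
cross-validation around an L1-regularised logistic regression with
within-fold median imputation and standardisation.  The L1 penalty acts as
embedded feature selection: the non-zero coefficients of the final model are
reported as the informative subset.  The ablation suite runs the same CV
splits on all features, the non-disorder features and the disorder features
alone, so the three reports are directly (pairwise) comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: Feature-manifest family tag for the disorder parameters (the ablation axis).
DISORDER_FEATURES = (
    "idrs_per_100",
    "idr_coverage",
    "is_idp",
    "disorder_mean",
    "n_short_idrs",
    "n_long_idrs",
    "longest_idr",
    "has_nterm_idr",
)


def stars(p: float) -> str:
    for threshold, symbol in STAR_THRESHOLDS:
        if p < threshold:
            return symbol
    return "#"


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2×2 count table."""
    odds, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(odds), float(p)


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    groups: tuple
    test: str
    statistic: float
    p_value: float
    stars: str
    direction: str  # group with the higher median / proportion


def compare_groups(
    feature_values: pd.Series | Sequence,
    group_labels: Sequence,
    feature_name: str = "feature",
) -> GroupComparisonResult:
    """Compare one feature across groups; route by dtype.

    Boolean columns go to Fisher's exact test (2 groups; chi-square for more),
    numeric columns to Kruskal–Wallis.  Missing values are dropped pairwise.
    Raw p-values are reported; the star scheme reflects them directly.
    """
    values = pd.Series(feature_values).reset_index(drop=True)
    labels = pd.Series(group_labels).reset_index(drop=True)
    mask = values.notna()
    values, labels = values[mask], labels[mask]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    split = [values[labels == g] for g in groups]
    for g, v in zip(groups, split):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    is_boolean = values.dtype == bool or set(values.unique()) <= {0, 1, True, False}
    if is_boolean:
        counts = np.array([[int(v.sum()), int(len(v) - v.sum())] for v in split])
        if len(groups) == 2:
            statistic, p = fisher_exact_2x2(counts)
            test = "fisher_exact"
        else:
            statistic, p, *_ = stats.chi2_contingency(counts)[:2]
            test = "chi2"
        proportions = [v.mean() for v in split]
        direction = groups[int(np.argmax(proportions))]
    else:
        statistic, p = stats.kruskal(*split)
        test = "kruskal_wallis"
        medians = [v.median() for v in split]
        direction = groups[int(np.argmax(medians))]
    return GroupComparisonResult(
        feature=feature_name,
        groups=tuple(groups),
        test=test,
        statistic=float(statistic),
        p_value=float(p),
        stars=stars(float(p)),
        direction=direction,
    )


def compare_feature_table(
    table: pd.DataFrame, group_column: str = "group"
) -> pd.DataFrame:
    """Run :func:`compare_groups` on every feature column of a table."""
    rows = []
    for col in table.columns:
        if col == group_column:
            continue
        res = compare_groups(table[col], table[group_column], feature_name=col)
        rows.append(
            {
                "feature": res.feature,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "stars": res.stars,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Feature table assembly


def assemble_feature_table(
    frames: Mapping[str, pd.DataFrame], group_labels: pd.Series
) -> pd.DataFrame:
    """Outer-join per-module feature frames on accession and attach group labels.

    Proteins missing a whole input (no structure, no abundance row) keep
    their row with the corresponding cells masked as NaN.  Duplicate
    accessions within a frame and feature-name collisions across frames are
    errors.
    """
    combined = None
    seen_columns: set[str] = set()
    for name, frame in frames.items():
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"{name}: duplicate accessions {sorted(set(dupes))[:5]}")
        clash = seen_columns & set(frame.columns)
        if clash:
            raise ValueError(f"{name}: feature name collision {sorted(clash)}")
        seen_columns |= set(frame.columns)
        combined = frame if combined is None else combined.join(frame, how="outer")
    if combined is None:
        raise ValueError("no feature frames given")
    if group_labels.index.duplicated().any():
        raise ValueError("duplicate accessions in group labels")
    combined = combined.loc[combined.index.intersection(group_labels.index)]
    combined["group"] = group_labels.loc[combined.index]
    return combined


# ---------------------------------------------------------------------------
# Positional N-terminal profiles


def positional_profile(
    tracks: Mapping[str, Sequence[float]],
    membership: Mapping[str, bool],
    n_positions: int = 90,
) -> pd.DataFrame:
    """Mean per-position score over the first ``n_positions`` mature residues.

    ``membership`` flags each accession as interactor (True) or
    non-interactor.  At each position the mean is over the proteins long
    enough to reach it; shorter proteins simply drop out.  A Mann–Whitney
    test per position compares the two groups.
    """
    group_names = {True: "interactor", False: "non_interactor"}
    values: dict[str, list[np.ndarray]] = {g: [] for g in group_names.values()}
    for acc, track in tracks.items():
        if acc not in membership:
            continue
        values[group_names[bool(membership[acc])]].append(np.asarray(track, dtype=float))
    for g, tr in values.items():
        if not tr:
            raise ValueError(f"empty group {g!r}")
    rows = []
    for p in range(1, n_positions + 1):
        at_p = {g: np.array([t[p - 1] for t in tr if len(t) >= p]) for g, tr in values.items()}
        row = {"position": p}
        for g, v in at_p.items():
            row[f"mean_{g}"] = float(v.mean()) if v.size else float("nan")
            row[f"n_{g}"] = int(v.size)
        if all(v.size >= 2 for v in at_p.values()):
            u, p_val = stats.mannwhitneyu(
                at_p["interactor"], at_p["non_interactor"], alternative="two-sided"
            )
            row["p_value"] = float(p_val)
        else:
            row["p_value"] = float("nan")
        row["difference"] = row["mean_interactor"] - row["mean_non_interactor"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


# ---------------------------------------------------------------------------
# Classifier


@dataclass(frozen=True)
class ClassifierReport:
    label: str
    auc: float
    auc_ci: tuple
    accuracy: float
    accuracy_ci: tuple
    precision_per_class: Mapping[str, float]
    precision_ci: Mapping[str, tuple]
    selected_features: tuple = field(default_factory=tuple)
    n_proteins: int = 0

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "precision_per_class": dict(self.precision_per_class),
            "precision_ci": {k: list(v) for k, v in self.precision_ci.items()},
            "selected_features": [[f, w] for f, w in self.selected_features],
            "n_proteins": self.n_proteins,
        }


def _make_pipeline(seed: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            (
                "model",
                LogisticRegression(
                    l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=2000, random_state=seed
                ),
            ),
        ]
    )


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000) -> tuple:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))


def train_evaluate_classifier(
    feature_table: pd.DataFrame,
    feature_subset: Sequence[str] | None = None,
    group_column: str = "group",
    positive_class: str = "secretome",
    n_splits: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    label: str = "all_features",
) -> ClassifierReport:
    """Repeated stratified CV of the binary topology-group classifier.

    Imputation, scaling and the L1-penalised fit all happen inside each
    training fold, so no test-fold information leaks into preprocessing.
    Metrics are averaged over folds with seeded percentile-bootstrap 95% CIs;
    the run is deterministic given ``seed``.
    """
    y_labels = feature_table[group_column]
    classes = sorted(y_labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    negative_class = [c for c in classes if c != positive_class][0]
    features = [c for c in feature_table.columns if c != group_column]
    if feature_subset is not None:
        missing = set(feature_subset) - set(features)
        if missing:
            raise ValueError(f"unknown features {sorted(missing)}")
        features = list(feature_subset)
    X = feature_table[features].astype(float).to_numpy()
    y = (y_labels == positive_class).astype(int).to_numpy()

    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    aucs, accs = [], []
    precisions = {positive_class: [], negative_class: []}
    for train_idx, test_idx in cv.split(X, y):
        pipe = _make_pipeline(seed)
        pipe.fit(X[train_idx], y[train_idx])
        prob = pipe.predict_proba(X[test_idx])[:, 1]
        pred = (prob >= 0.5).astype(int)
        aucs.append(roc_auc_score(y[test_idx], prob))
        accs.append(accuracy_score(y[test_idx], pred))
        precisions[positive_class].append(precision_score(y[test_idx], pred, pos_label=1, zero_division=0))
        precisions[negative_class].append(precision_score(y[test_idx], pred, pos_label=0, zero_division=0))

    rng = np.random.default_rng(seed)
    aucs, accs = np.array(aucs), np.array(accs)
    prec_point = {k: float(np.mean(v)) for k, v in precisions.items()}
    prec_ci = {k: _bootstrap_ci(np.array(v), rng) for k, v in precisions.items()}

    final = _make_pipeline(seed)
    final.fit(X, y)
    coefs = final.named_steps["model"].coef_.ravel()
    selected = tuple(
        (features[i], float(coefs[i]))
        for i in np.argsort(-np.abs(coefs))
        if coefs[i] != 0.0
    )
    return ClassifierReport(
        label=label,
        auc=float(aucs.mean()),
        auc_ci=_bootstrap_ci(aucs, rng),
        accuracy=float(accs.mean()),
        accuracy_ci=_bootstrap_ci(accs, rng),
        precision_per_class=prec_point,
        precision_ci=prec_ci,
        selected_features=selected,
        n_proteins=len(y),
    )


def ablation_suite(
    feature_table: pd.DataFrame,
    disorder_features: Sequence[str] = DISORDER_FEATURES,
    group_column: str = "group",
    seed: int = 0,
    n_splits: int = 10,
    n_repeats: int = 10,
) -> list[ClassifierReport]:
    """Three paired classifier runs: all features, non-disorder, disorder only.

    The CV splits are identical across the three runs (same seed and data
    order), so AUC differences reflect the feature families, not fold noise.
    """
    all_features = [c for c in feature_table.columns if c != group_column]
    disorder = [c for c in all_features if c in set(disorder_features)]
    if not disorder:
        raise ValueError("no disorder-tagged features in table")
    non_disorder = [c for c in all_features if c not in set(disorder_features)]
    runs = [
        ("all_features", all_features),
        ("non_disorder", non_disorder),
        ("disorder_only", disorder),
    ]
    return [
        train_evaluate_classifier(
            feature_table,
            feature_subset=subset,
            group_column=group_column,
            seed=seed,
            n_splits=n_splits,
            n_repeats=n_repeats,
            label=label,
        )
        for label, subset in runs
    ]
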