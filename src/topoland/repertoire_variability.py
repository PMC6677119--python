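"""Fold-repertoire census and abundance variability.

The census compares the structural fold repertoires of topology groups:
which folds are unique to a group versus shared, rare (1–3 occurrences in
the whole proteome) versus frequent (>= 4), the SCOP-class composition of
each group's repertoire, its *popular* folds (>= 3% of the group's fold
instances) and how many folds each protein carries.

The variability score (VS) summarises how much a protein's abundance moves
across growth conditions: the standard deviation of log2 abundance, which is
zero for constant rows and invariant under global rescaling.  Proteins are
binned into very-low / low / moderate / high variability classes, by
quartiles or explicit cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("topoland")

RARE_MAX_OCCURRENCES = 3  # rare: 1-3 copies proteome-wide; frequent: >= 4
POPULAR_FOLD_FRACTION = 0.03  # >= 3% of a group's fold instances
SOLUBLE_FOLD_CLASSES = ("a", "b", "c", "d")
VARIABILITY_CLASSES = ("very_low", "low", "moderate", "high")


@dataclass(frozen=True)
class FoldCensus:
    """Per-fold and per-group summaries of the fold repertoire."""

    folds: pd.DataFrame  # index fold_id; total, per-group counts, status, rarity, scop_class
    group_class_fractions: pd.DataFrame  # group × SCOP class, over distinct folds
    popular_folds: Mapping[str, tuple]
    group_instance_counts: Mapping[str, int]


def fold_census(
    fold_table: pd.DataFrame,
    group_of: Mapping[str, str],
    soluble_only: bool = True,
    rare_max: int = RARE_MAX_OCCURRENCES,
    popular_fraction: float = POPULAR_FOLD_FRACTION,
) -> FoldCensus:
    """Census a fold table (accession, fold_id, scop_class rows) across groups.

    ``group_of`` maps accession to its topology group.  With ``soluble_only``
    class-f (membrane / cell-surface) folds are excluded.  Status is
    unique-to-<group> when every occurrence lies in one group, else shared;
    rarity is by total proteome occurrence count.  Class composition counts
    each distinct fold once per group (repertoire view); popular folds are
    instance-weighted within the group.
    """
    df = fold_table.copy()
    unassigned = sorted(set(df["accession"]) - set(group_of))
    if unassigned:
        logger.warning("fold census: %d proteins without group assignment excluded", len(unassigned))
        df = df[df["accession"].isin(group_of)]
    if soluble_only:
        df = df[df["scop_class"] != "f"]
    if df.empty:
        raise ValueError("no fold instances left to census")
    df = df.assign(group=df["accession"].map(group_of))

    groups = sorted(df["group"].unique())
    per_group = df.pivot_table(index="fold_id", columns="group", aggfunc="size", fill_value=0)
    per_group = per_group.reindex(columns=groups, fill_value=0)
    total = per_group.sum(axis=1)
    scop = df.groupby("fold_id")["scop_class"].first()

    status = []
    for fold_id in per_group.index:
        nonzero = [g for g in groups if per_group.loc[fold_id, g] > 0]
        status.append(f"unique-to-{nonzero[0]}" if len(nonzero) == 1 else "shared")
    folds = per_group.copy()
    folds["total"] = total
    folds["scop_class"] = scop
    folds["status"] = status
    folds["rarity"] = np.where(total <= rare_max, "rare", "frequent")

    # Repertoire-view class composition: each distinct fold once per group.
    rows = {}
    for g in groups:
        present = folds[folds[g] > 0]
        counts = present["scop_class"].value_counts()
        n = len(present)
        rows[g] = {c: counts.get(c, 0) / n for c in SOLUBLE_FOLD_CLASSES}
    class_fractions = pd.DataFrame(rows).T

    popular = {}
    instance_counts = {}
    for g in groups:
        n_instances = int(per_group[g].sum())
        instance_counts[g] = n_instances
        share = per_group[g] / n_instances
        popular[g] = tuple(sorted(share[share >= popular_fraction].index))

    return FoldCensus(
        folds=folds,
        group_class_fractions=class_fractions,
        popular_folds=popular,
        group_instance_counts=instance_counts,
    )


@dataclass(frozen=True)
class FoldsPerProtein:
    n_fold_fraction: float  # fraction of proteins with >= 2 domain records
    mean_folds_all: float
    mean_folds_nfold: float


def folds_per_protein(fold_table: pd.DataFrame, accessions: Sequence[str]) -> FoldsPerProtein:
    """Domain multiplicity for one group of proteins.

    Duplicate identical domain rows count as separate domains (repeats are
    real domains).  Proteins in ``accessions`` without any fold record count
    as zero-domain proteins in the all-protein mean.
    """
    if len(accessions) == 0:
        raise ValueError("empty group")
    counts = fold_table[fold_table["accession"].isin(accessions)].groupby("accession").size()
    counts = counts.reindex(accessions, fill_value=0)
    nfold = counts[counts >= 2]
    return FoldsPerProtein(
        n_fold_fraction=float((counts >= 2).mean()),
        mean_folds_all=float(counts.mean()),
        mean_folds_nfold=float(nfold.mean()) if len(nfold) else float("nan"),
    )


def variability_score(abundance: pd.DataFrame, mode: str = "log_sd") -> pd.Series:
    """Per-protein abundance variability across conditions.

    ``log_sd`` (default): standard deviation of log2 abundance — scale-free
    under multiplicative noise, zero for constant rows.  ``cv``: coefficient
    of variation of the raw abundances, provided as an alternative.
    """
    values = abundance.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    if (values <= 0).any():
        raise ValueError("abundances must be positive")
    if mode == "log_sd":
        vs = np.log2(values).std(axis=1, ddof=1)
    elif mode == "cv":
        vs = values.std(axis=1, ddof=1) / values.mean(axis=1)
    else:
        raise ValueError(f"unknown VS mode {mode!r}")
    return pd.Series(vs, index=abundance.index, name="VS")


def bin_variability(vs_values: pd.Series, cutoffs: Sequence[float] | None = None) -> pd.Series:
    """Assign very_low / low / moderate / high variability classes.

    Without explicit ``cutoffs`` the three quartile boundaries are used.
    A value exactly at a boundary goes to the lower class, so an all-equal
    input lands entirely in ``very_low``.
    """
    vs = pd.Series(vs_values)
    if cutoffs is None:
        if len(vs) < 4:
            raise ValueError("quartile mode needs >= 4 values")
        cutoffs = np.quantile(vs.to_numpy(), [0.25, 0.5, 0.75])
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) != 3 or np.any(np.diff(cutoffs) < 0):
        raise ValueError("cutoffs must be 3 non-decreasing values")
    # number of cutoffs strictly below the value -> class index (ties go low)
    idx = (vs.to_numpy()[:, None] > cutoffs[None, :]).sum(axis=1)
    return pd.Series([VARIABILITY_CLASSES[i] for i in idx], index=vs.index, name="vs_class")
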