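"""Sequential comparator pipelines: impute undetermined wells, then test.

Three imputation strategies are implemented, matching common qPCR practice:

* **LOD** -- impute every undetermined well at the limit of detection on the
  raw scale, then apply MOD normalization to the completed matrix.
* **MNV+1** -- on the MOD-normalized (expressed-only) matrix, impute each
  target's undetermined wells by the target's maximum normalized value plus
  one cycle, preserving their "worst observed" status as ties.
* **KNN** -- on the normalized matrix, impute a well by the mean of the
  expressed values, at that sample, of the k nearest targets under a
  Euclidean distance computed over pairwise-complete samples and rescaled to
  full length.

Testing is per target: a pooled-variance two-sample t-test (Welch optional)
or the tie-corrected Wilcoxon rank-sum test, followed by BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CqDataset
from .inference import bh_adjust
from .normalization import mod_normalize

__all__ = [
    "ImputedMatrix",
    "impute_lod",
    "impute_mnv1",
    "impute_knn",
    "sequential_test",
    "sequential_pipeline",
]


@dataclass
class ImputedMatrix:
    """Normalized matrix with censored cells filled by some strategy."""

    values: pd.DataFrame  # targets x samples
    method: str
    k: int | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("imputed matrix still contains absent values")


def impute_lod(dataset: CqDataset, common_only: bool = False,
               normalization: str = "mod") -> ImputedMatrix:
    """LOD strategy: censored wells take the LOD value on the raw scale, then
    the completed matrix is normalized.

    ``normalization="mod"`` applies the two-pass modified global mean;
    ``"refgenes"`` subtracts, per sample, the mean completed Cq of the
    flagged reference genes (classical delta-Cq against reference genes).
    """
    mask = dataset.censored_matrix()
    filled = dataset.cq_matrix().where(~mask, dataset.lod)
    if normalization == "refgenes":
        is_ref = dataset.targets["is_reference"].astype(bool)
        if not is_ref.any():
            raise ValueError("refgenes normalization needs flagged reference genes")
        factors = filled.loc[is_ref[is_ref].index].mean(axis=0)
        normalized = filled.sub(factors, axis=1)
    elif normalization == "mod":
        normalized, _ = mod_normalize(dataset, common_only=common_only,
                                      imputed_values=filled)
    else:
        raise ValueError("normalization must be 'mod' or 'refgenes'")
    # absent (missing) wells may remain NaN; only censored cells are required
    if normalized.isna().any().any():
        normalized = normalized.fillna(normalized.mean(axis=1))
    return ImputedMatrix(normalized, "LOD")


def impute_mnv1(normalized: pd.DataFrame) -> ImputedMatrix:
    """MNV+1 strategy on an already-normalized matrix with NaN at
    undetermined wells: each target's NaNs become its max expressed
    normalized value plus 1 (tied by construction)."""
    values = normalized.copy()
    has_gap = values.isna().any(axis=1)
    for tid in values.index[has_gap]:
        row = values.loc[tid]
        if row.isna().all():
            raise ValueError(
                f"target {tid!r} has no expressed value; remove it before MNV+1"
            )
        values.loc[tid] = row.fillna(row.max() + 1.0)
    return ImputedMatrix(values, "MNV+1")


def impute_knn(normalized: pd.DataFrame, k: int = 10) -> ImputedMatrix:
    """KNN strategy: impute cell (i, j) by the mean expressed value at sample
    j among the k targets nearest to i.

    Distances are Euclidean over samples where both targets are expressed,
    rescaled by sqrt(total / shared) to full length (the standard
    missing-data KNN-imputation metric).  If fewer than k neighbors are
    expressed at sample j, all available ones are used with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(normalized) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} targets, got {len(normalized)}")
    V = normalized.to_numpy(float)
    I, J = V.shape
    present = ~np.isnan(V)
    values = normalized.copy()
    short_cells: dict = {}
    for i in np.flatnonzero(~present.all(axis=1)):
        # scaled pairwise-complete distances from target i to all others
        dist = np.full(I, np.inf)
        for o in range(I):
            if o == i:
                continue
            shared = present[i] & present[o]
            ns = int(shared.sum())
            if ns == 0:
                continue
            d2 = np.sum((V[i, shared] - V[o, shared]) ** 2)
            dist[o] = np.sqrt(d2 * J / ns)
        order = np.argsort(dist, kind="stable")
        order = order[np.isfinite(dist[order])]
        neighbors = order[:k]
        if len(neighbors) == 0:
            raise ValueError(f"no neighbor with shared samples for target {normalized.index[i]!r}")
        for j in np.flatnonzero(~present[i]):
            donors = neighbors[present[neighbors, j]]
            if len(donors) == 0:
                extra = order[k:]
                donors = extra[present[extra, j]]
                if len(donors) == 0:
                    raise ValueError(
                        f"no expressed neighbor at sample {normalized.columns[j]!r} "
                        f"for target {normalized.index[i]!r}"
                    )
                donors = donors[:k]
                short_cells.setdefault(normalized.index[i], 0)
                short_cells[normalized.index[i]] += 1
            elif len(donors) < k:
                short_cells.setdefault(normalized.index[i], 0)
                short_cells[normalized.index[i]] += 1
            values.iloc[i, j] = float(V[donors, j].mean())
    if short_cells:
        detail = ", ".join(f"{t}({c})" for t, c in list(short_cells.items())[:5])
        warnings.warn(
            f"KNN imputation fell back to fewer/farther than k={k} expressed "
            f"neighbors for {sum(short_cells.values())} cells across "
            f"{len(short_cells)} targets (e.g. {detail})",
            RuntimeWarning, stacklevel=2,
        )
    return ImputedMatrix(values, "KNN", k=k)


def sequential_test(
    imputed: ImputedMatrix,
    groups: pd.Series,
    test: str = "t",
    comparison: tuple | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-target two-sample test on normalized, imputed values.

    delta_hat is the group-mean difference (reference minus comparison
    group), i.e. the log2 fold change under the one-cycle-per-doubling rule;
    it is reported for the Wilcoxon test too, alongside the rank statistic.
    """
    if test not in {"t", "wilcoxon"}:
        raise ValueError("test must be 't' or 'wilcoxon'")
    groups = groups.reindex(imputed.values.columns)
    labels = list(dict.fromkeys(groups))
    if comparison is None:
        comparison = (labels[0], labels[1])
    ref, alt = comparison
    a_cols = groups.index[groups == ref]
    b_cols = groups.index[groups == alt]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for tid, row in imputed.values.iterrows():
        a = row[a_cols].to_numpy(float)
        b = row[b_cols].to_numpy(float)
        delta = float(a.mean() - b.mean())
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            if not np.isclose(delta, 0.0):
                warnings.warn(
                    f"target {tid!r}: zero within-group variance with nonzero "
                    "difference; p set to 1", RuntimeWarning, stacklevel=2,
                )
            stat, p = 0.0, 1.0
        elif test == "t":
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append({"target_id": tid, "delta_hat": delta,
                     "wald_stat": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"])
    out["fc"] = 2.0 ** out["delta_hat"]
    return out


def sequential_pipeline(
    dataset: CqDataset,
    impute: str = "lod",
    test: str = "t",
    k: int = 10,
    comparison: tuple | None = None,
    common_only: bool = False,
    welch: bool = False,
    normalization: str = "mod",
) -> pd.DataFrame:
    """Normalize, impute and test in the classical sequential order.

    ``impute`` is one of ``"lod"``, ``"mnv1"``, ``"knn"``.  LOD imputes on
    the raw scale before normalization; MNV+1 and KNN impute on the
    normalized scale.  ``normalization="refgenes"`` replaces the modified
    global mean with per-sample reference-gene means (flagged targets).
    """
    if impute not in {"lod", "mnv1", "knn"}:
        raise ValueError("impute must be 'lod', 'mnv1' or 'knn'")
    if impute == "lod":
        mat = impute_lod(dataset, common_only=common_only,
                         normalization=normalization)
    else:
        if normalization == "refgenes":
            is_ref = dataset.targets["is_reference"].astype(bool)
            if not is_ref.any():
                raise ValueError("refgenes normalization needs flagged reference genes")
            values = dataset.cq_matrix().where(~dataset.censored_matrix())
            factors = values.loc[is_ref[is_ref].index].mean(axis=0, skipna=True)
            if factors.isna().any():
                raise ValueError("a sample has no expressed reference gene")
            normalized = values.sub(factors, axis=1)
        else:
            normalized, _ = mod_normalize(dataset, common_only=common_only)
        mat = impute_mnv1(normalized) if impute == "mnv1" \
            else impute_knn(normalized, k=k)
    return sequential_test(mat, dataset.samples["group"], test=test,
                           comparison=comparison, welch=welch)
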