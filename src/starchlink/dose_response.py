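"""Dose-correlation maps, diet rank tests, clustering, treemap tables.

The central statistic is the *averaged per-subject Pearson correlation*
between a feature's abundance and the coded resistant-starch dose
(baseline 0, low-RS 0.05, high-RS 1): each subject contributes one r
computed across that subject's own diet samples, and the map reports the
mean across subjects.  Subjects whose abundance is constant across diets
yield an undefined r and are excluded from the mean rather than counted as
zero (which would bias averaged maps toward null).

Diet comparisons use the Kruskal–Wallis test with the post-hoc Nemenyi test
on mean rank sums; pairwise p-values come from the studentized-range
distribution, with a tie-corrected chi-square variant selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .tables import RS_DOSE, FeatureTable, TableError

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    for threshold, mark in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return mark
    return ""


# ---------------------------------------------------------------------------
# Dose correlation
# ---------------------------------------------------------------------------


@dataclass
class DoseCorrelation:
    """Per-subject and averaged Pearson correlations against coded RS dose."""

    per_subject_r: pd.DataFrame  # subjects × features; NaN where undefined
    mean_r: pd.Series  # averaged over subjects with defined r
    n_subjects_used: pd.Series

    def ranked(self) -> pd.Series:
        """Features sorted by mean_r descending (NaN last)."""
        return self.mean_r.sort_values(ascending=False)


def dose_correlation(
    table: FeatureTable,
    meta: pd.DataFrame,
    dose_map: Mapping[str, float] | None = None,
    pooled: bool = False,
) -> DoseCorrelation:
    """Correlate feature abundance with coded RS dose, per subject.

    With ``pooled=True`` a single Pearson r across all samples is computed
    per feature instead (returned as a one-row ``per_subject_r`` labelled
    ``pooled``).
    """
    dose_map = dict(RS_DOSE if dose_map is None else dose_map)
    missing_diets = set(meta["diet"]) - set(dose_map)
    if missing_diets:
        raise TableError(f"dose_map lacks diets {sorted(missing_diets)}")
    indexed = meta.set_index("sample_id")
    doses = np.array([dose_map[indexed.loc[s, "diet"]] for s in table.sample_ids])
    values = table.values()

    def _pearson_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Pearson r of x against each column of Y; NaN where var is 0."""
        xc = x - x.mean()
        Yc = Y - np.nanmean(Y, axis=0)
        sx = np.sqrt((xc**2).sum())
        sy = np.sqrt(np.nansum(Yc**2, axis=0))
        # zero variance up to centering round-off -> r undefined, not tiny
        scale = np.sqrt(np.nansum(Y**2, axis=0))
        degenerate = sy <= 1e-10 * np.maximum(scale, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.nansum(xc[:, None] * Yc, axis=0) / (sx * sy)
        r[degenerate] = np.nan
        return r

    if pooled:
        if np.ptp(doses) == 0:
            raise TableError("pooled correlation needs >= 2 distinct doses")
        r = _pearson_rows(doses, values)
        per_subject = pd.DataFrame([r], index=["pooled"], columns=table.feature_ids)
    else:
        rows = []
        subjects = []
        for subj, group in indexed.loc[table.sample_ids].groupby("subject_id", sort=True):
            sample_ids = list(group.index)
            idx = [table.sample_ids.index(s) for s in sample_ids]
            x = doses[idx]
            if len(np.unique(x)) < 2:
                raise TableError(
                    f"subject {subj!r} has fewer than 2 distinct doses"
                )
            rows.append(_pearson_rows(x, values[idx]))
            subjects.append(subj)
        per_subject = pd.DataFrame(rows, index=subjects, columns=table.feature_ids)

    mean_r = per_subject.mean(axis=0, skipna=True)
    n_used = per_subject.notna().sum(axis=0)
    mean_r[n_used == 0] = np.nan
    return DoseCorrelation(per_subject, mean_r, n_used)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Nemenyi post-hoc
# ---------------------------------------------------------------------------


def kruskal_nemenyi(
    values: Sequence[float],
    groups: Sequence[str],
    dist: str = "tukey",
) -> tuple[float, pd.DataFrame]:
    """Kruskal–Wallis p plus the Nemenyi pairwise p-value matrix.

    ``dist='tukey'`` (default) refers pairwise mean-rank-sum differences to
    the studentized-range distribution; ``dist='chi2'`` uses the
    tie-corrected chi-square variant.  The pairwise matrix is symmetric with
    unit diagonal.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise TableError("need >= 2 groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise TableError(f"group {lab!r} has fewer than 2 observations")
    if dist not in ("tukey", "chi2"):
        raise TableError(f"unknown dist {dist!r}; expected tukey or chi2")

    kruskal_p = float(
        stats.kruskal(*(values[groups == lab] for lab in labels)).pvalue
    )

    ranks = stats.rankdata(values)
    n_total = len(values)
    k = len(labels)
    mean_ranks = {lab: ranks[groups == lab].mean() for lab in labels}
    sizes = {lab: int((groups == lab).sum()) for lab in labels}

    # tie correction for the chi-square variant
    _, tie_counts = np.unique(values, return_counts=True)
    tie_c = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)

    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for a in range(k):
        for b in range(a + 1, k):
            la, lb = labels[a], labels[b]
            diff = abs(mean_ranks[la] - mean_ranks[lb])
            var = n_total * (n_total + 1) / 12.0 * (1.0 / sizes[la] + 1.0 / sizes[lb])
            if dist == "tukey":
                q = diff / np.sqrt(var) * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, np.inf))
            else:
                if tie_c <= 0:
                    p = 1.0
                else:
                    chi = diff**2 / var / tie_c
                    p = float(stats.chi2.sf(chi, k - 1))
            p = min(max(p, 0.0), 1.0)
            pmat.iloc[a, b] = pmat.iloc[b, a] = p
    return kruskal_p, pmat


# ---------------------------------------------------------------------------
# Row-normalized hierarchical clustering
# ---------------------------------------------------------------------------


def cluster_matrix(
    frame: pd.DataFrame, linkage_method: str = "average"
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Normalize rows to (x − mean)/sd and cluster them by Euclidean distance.

    Rows are whatever the caller wants clustered (features, typically).  The
    standard deviation is the sample (n−1) convention.  Returns the
    normalized frame, the scipy linkage matrix, and the leaf order.
    """
    values = frame.to_numpy(dtype=float)
    sds = values.std(axis=1, ddof=1)
    zero = np.where(sds == 0)[0]
    if len(zero):
        raise TableError(f"zero-variance row {frame.index[zero[0]]!r}")
    normalized = (values - values.mean(axis=1, keepdims=True)) / sds[:, None]
    norm_frame = pd.DataFrame(normalized, index=frame.index, columns=frame.columns)
    linkage = hierarchy.linkage(normalized, method=linkage_method, metric="euclidean")
    leaves = [frame.index[i] for i in hierarchy.leaves_list(linkage)]
    return norm_frame, linkage, leaves


# ---------------------------------------------------------------------------
# Treemap-ready hierarchy tables
# ---------------------------------------------------------------------------


def treemap_table(
    table: FeatureTable,
    hierarchy_map: Mapping[str, Sequence[str]],
    correlations: DoseCorrelation | pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate mean abundances up a feature hierarchy.

    ``hierarchy_map`` assigns each feature a path (e.g. phylum → order →
    genus, or COG class → term).  Node weight is the summed mean abundance
    of its member features, so child weights sum to the parent weight by
    construction; node color is the abundance-weighted mean of the features'
    averaged dose correlations.  Output columns: path, level, weight, color.
    """
    orphans = [f for f in table.feature_ids if f not in hierarchy_map]
    if orphans:
        raise TableError(f"features missing from hierarchy: {orphans[:5]}")
    mean_abund = pd.Series(
        np.nanmean(table.values(), axis=0), index=table.feature_ids
    ).fillna(0.0)
    if correlations is None:
        mean_r = pd.Series(np.nan, index=table.feature_ids)
    elif isinstance(correlations, DoseCorrelation):
        mean_r = correlations.mean_r.reindex(table.feature_ids)
    else:
        mean_r = correlations.reindex(table.feature_ids)

    weight: dict[tuple[str, ...], float] = {}
    color_num: dict[tuple[str, ...], float] = {}
    color_den: dict[tuple[str, ...], float] = {}
    for fid in table.feature_ids:
        path = tuple(hierarchy_map[fid])
        w = float(mean_abund[fid])
        r = mean_r[fid]
        for level in range(1, len(path) + 1):
            node = path[:level]
            weight[node] = weight.get(node, 0.0) + w
            if not np.isnan(r):
                color_num[node] = color_num.get(node, 0.0) + w * float(r)
                color_den[node] = color_den.get(node, 0.0) + w

    rows = []
    for node in sorted(weight):
        den = color_den.get(node, 0.0)
        rows.append(
            {
                "path": "/".join(node),
                "level": len(node),
                "weight": weight[node],
                "color": color_num[node] / den if den > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["path", "level", "weight", "color"])
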