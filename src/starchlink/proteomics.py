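"""Spectral-count normalization across MS runs and annotation rollups.

Spectral counts are semi-quantitative: the total number of peptide-spectrum
matches differs between runs for purely instrumental reasons.  The
normalization rescales every run to the *average* run total,

    normalized SC_i = (mean over runs of run total) / (own run total) × SC_i

so that after one pass all runs share the same total and the grand total of
the matrix is preserved.  Applying it twice is a no-op.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import FeatureTable, TableError, taxon_at_rank

COG_UNASSIGNED = "unassigned"


def normalize_spectral_counts(table: FeatureTable) -> FeatureTable:
    """Scale each MS run (sample) to the mean run total.

    Every run must have a positive total.  The output is real-valued; the
    per-run totals all equal the mean of the original totals and the grand
    total is conserved.
    """
    if table.layer != "protein":
        raise TableError("spectral-count normalization applies to the protein layer")
    values = np.nan_to_num(table.values())
    totals = values.sum(axis=1)
    zero = np.where(totals <= 0)[0]
    if len(zero):
        raise TableError(f"zero-total run {table.sample_ids[zero[0]]!r}")
    mean_total = totals.mean()
    scaled = values * (mean_total / totals)[:, None]
    return table.replace(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns)
    )


def rollup(
    table: FeatureTable,
    annotations: pd.DataFrame,
    annotation_field: str = "cog_class",
    rank: str | None = None,
) -> FeatureTable:
    """Sum proteins into annotation groups per sample.

    ``annotation_field`` is either ``cog_class`` (single-letter COG
    functional class) or ``taxon``, in which case ``rank`` selects the
    taxonomic rank from each protein's lineage.  Unannotated proteins are
    pooled into an explicit ``unassigned`` group so that group totals
    conserve the matrix total.
    """
    if annotation_field not in ("cog_class", "taxon"):
        raise TableError(f"unknown annotation_field {annotation_field!r}")
    groups: dict[str, str] = {}
    for fid in table.feature_ids:
        if fid not in annotations.index:
            groups[fid] = COG_UNASSIGNED
            continue
        rec = annotations.loc[fid]
        if annotation_field == "cog_class":
            label = str(rec.get("cog_class", "") or "").strip()
        else:
            if rank is None:
                raise TableError("taxon rollup requires a rank")
            label = taxon_at_rank(str(rec.get("lineage", "") or ""), rank) or ""
        groups[fid] = label if label else COG_UNASSIGNED
    if all(g == COG_UNASSIGNED for g in groups.values()) and len(groups) and (
        annotations.shape[0] == 0
    ):
        pass  # all-unassigned is allowed; a single pooled group results
    frame = table.data.T.groupby(pd.Series(groups)).sum(min_count=1).T
    frame = frame.reindex(sorted(frame.columns), axis=1)
    return FeatureTable(table.layer, frame.fillna(0.0))


def split_human_microbial(
    table: FeatureTable, annotations: pd.DataFrame
) -> tuple[FeatureTable, FeatureTable]:
    """Partition the matrix into human and microbial protein sub-matrices.

    Proteins absent from the annotation frame count as microbial.  The two
    parts are disjoint and their column totals add back to the original.
    """
    if "is_human" not in annotations.columns:
        raise TableError("annotations lack an is_human column")
    human_ids = [
        fid
        for fid in table.feature_ids
        if fid in annotations.index and bool(annotations.loc[fid, "is_human"])
    ]
    microbial_ids = [f for f in table.feature_ids if f not in set(human_ids)]
    return table.select_features(human_ids), table.select_features(microbial_ids)
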