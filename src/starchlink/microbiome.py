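"""OTU-table quality filters, even-depth scaling, and taxon summaries.

The default pipeline order is sample-depth filtering first, then OTU
prevalence filtering — the order matters because removing shallow samples
changes per-feature prevalence.  Both filters use strict inequalities
("more than"), configurable to ``>=`` via the ``strict`` flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import FeatureTable, TableError, taxon_at_rank


@dataclass
class FilterReport:
    """Bookkeeping for an OTU filter pass."""

    features_before: int
    features_after: int
    samples_before: int
    samples_after: int
    observation_fraction: float  # kept counts / all counts

    def to_jsonable(self) -> dict:
        return self.__dict__.copy()


def filter_samples_by_depth(
    table: FeatureTable, min_reads: int = 5000, strict: bool = True
) -> FeatureTable:
    """Keep samples whose total read count exceeds ``min_reads``.

    With ``strict`` (default) a sample needs *more than* ``min_reads`` reads;
    a sample at exactly the threshold is dropped.
    """
    if table.layer != "otu":
        raise TableError("depth filtering applies to the otu layer")
    sums = np.nansum(table.values(), axis=1)
    keep = sums > min_reads if strict else sums >= min_reads
    if not keep.any():
        raise TableError(
            f"depth filter at {min_reads} removed every sample; review the threshold"
        )
    return table.select_samples([s for s, k in zip(table.sample_ids, keep) if k])


def filter_otus_by_prevalence(
    table: FeatureTable,
    min_count: int = 5,
    min_samples: int = 5,
    strict: bool = True,
    total_count_mode: bool = False,
) -> tuple[FeatureTable, FilterReport]:
    """Keep OTUs that appear more than ``min_count`` times in more than
    ``min_samples`` samples (both strict by default).

    ``total_count_mode`` switches to the alternative reading where a feature
    is kept if its *total* count across samples exceeds ``min_count`` and it
    is present (count > 0) in more than ``min_samples`` samples.
    """
    if table.layer != "otu":
        raise TableError("prevalence filtering applies to the otu layer")
    values = np.nan_to_num(table.values())
    if total_count_mode:
        count_ok = values.sum(axis=0) > min_count if strict else values.sum(axis=0) >= min_count
        present = (values > 0).sum(axis=0)
        prev_ok = present > min_samples if strict else present >= min_samples
        keep = count_ok & prev_ok
    else:
        hits = (values > min_count) if strict else (values >= min_count)
        n_hit = hits.sum(axis=0)
        keep = n_hit > min_samples if strict else n_hit >= min_samples
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    total = values.sum()
    kept_total = values[:, keep].sum() if keep.any() else 0.0
    report = FilterReport(
        features_before=table.n_features,
        features_after=len(kept_ids),
        samples_before=table.n_samples,
        samples_after=table.n_samples,
        observation_fraction=float(kept_total / total) if total > 0 else 0.0,
    )
    return table.select_features(kept_ids), report


def scale_to_even_depth(table: FeatureTable, depth: int = 5000) -> FeatureTable:
    """Proportionally scale each sample to an even total of ``depth`` reads.

    This is a multiplicative rescaling (real-valued output), not rarefaction
    subsampling; within-sample proportions are preserved exactly.  For a
    seeded subsampling alternative see :func:`rarefy`.
    """
    values = table.values()
    sums = np.nansum(values, axis=1)
    zero = np.where(sums <= 0)[0]
    if len(zero):
        raise TableError(f"zero-sum sample {table.sample_ids[zero[0]]!r}")
    scaled = values * (depth / sums)[:, None]
    return table.replace(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns)
    )


def rarefy(table: FeatureTable, depth: int = 5000, seed: int = 0) -> FeatureTable:
    """Seeded rarefaction (subsampling without replacement) to ``depth``.

    Non-default alternative to proportional scaling; samples with fewer
    than ``depth`` reads are rejected.
    """
    rng = np.random.default_rng(seed)
    values = np.nan_to_num(table.values()).astype(int)
    out = np.zeros_like(values, dtype=float)
    for i, sid in enumerate(table.sample_ids):
        total = values[i].sum()
        if total < depth:
            raise TableError(f"sample {sid!r} has fewer than {depth} reads")
        chosen = rng.choice(
            np.repeat(np.arange(values.shape[1]), values[i]), size=depth, replace=False
        )
        out[i] = np.bincount(chosen, minlength=values.shape[1])
    return table.replace(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    )


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert each sample to proportions summing to 1."""
    values = table.values()
    sums = np.nansum(values, axis=1)
    zero = np.where(sums <= 0)[0]
    if len(zero):
        raise TableError(f"zero-sum sample {table.sample_ids[zero[0]]!r}")
    rel = values / sums[:, None]
    return table.replace(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns)
    )


def taxon_ratio(
    table: FeatureTable,
    lineages: Mapping[str, str],
    numerator_taxon: str,
    denominator_taxon: str,
    rank: str = "phylum",
) -> pd.Series:
    """Per-sample ratio of summed counts of two taxa at a given rank.

    E.g. the Firmicutes/Bacteroidetes ratio at rank ``phylum``.  Samples with
    a zero denominator get NaN (undefined), never infinity.
    """
    assignments = {
        fid: taxon_at_rank(lineages.get(fid, ""), rank) for fid in table.feature_ids
    }
    num_features = [f for f, t in assignments.items() if t == numerator_taxon]
    den_features = [f for f, t in assignments.items() if t == denominator_taxon]
    if not num_features:
        raise TableError(f"taxon {numerator_taxon!r} absent at rank {rank!r}")
    if not den_features:
        raise TableError(f"taxon {denominator_taxon!r} absent at rank {rank!r}")
    num = np.nansum(table.data.loc[:, num_features].to_numpy(dtype=float), axis=1)
    den = np.nansum(table.data.loc[:, den_features].to_numpy(dtype=float), axis=1)
    ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.Series(ratio, index=table.data.index, name=f"{numerator_taxon}/{denominator_taxon}")
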