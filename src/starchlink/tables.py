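"""Shared data model and plain-text I/O for the multi-omics pipeline.

The common currency of every stage is a :class:`FeatureTable`: a samples ×
features numeric matrix tagged with the omics layer it came from (``otu``
16S counts, ``protein`` spectral counts, or ``metabolite`` intensities).
On disk, tables follow the usual omics convention of features in rows with
the first column holding feature IDs; in memory the matrix is oriented
samples-in-rows, which simplifies per-sample operations.

Zeros are data; missingness is an explicit marker (NaN) distinct from zero.
Count layers use zeros, the aligned metabolite matrix uses NaN for peaks a
sample never showed, and the network stage's 50 %-missing filter counts only
the latter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("otu", "protein", "metabolite")

#: Coded resistant-starch dose per diet label (baseline washout, low-RS and
#: high-RS arms of the crossover).  The codes approximate the grams of RS in
#: each diet relative to the high-RS meal.
RS_DOSE: Mapping[str, float] = {"baseline": 0.0, "LRS": 0.05, "HRS": 1.0}

DIETS = ("baseline", "LRS", "HRS")

TAXONOMY_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_PREFIX = dict(zip("kpcofgs", TAXONOMY_RANKS))


class TableError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class FeatureTable:
    """A samples × features matrix for one omics layer.

    Parameters
    ----------
    layer:
        One of ``otu``, ``protein``, ``metabolite``.
    data:
        DataFrame with sample IDs as the index and feature IDs as columns.
        NaN marks missing values; everything else must be ``>= 0``.
    feature_meta:
        Optional per-feature annotation frame indexed by feature ID.
    """

    layer: str
    data: pd.DataFrame
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise TableError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableError(f"duplicate sample ID {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise TableError(f"duplicate feature ID {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.feature_meta is not None:
            missing = self.data.columns.difference(self.feature_meta.index)
            if len(missing):
                raise TableError(
                    f"feature_meta lacks annotations for {list(missing[:3])!r}"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def missing_mask(self) -> np.ndarray:
        """Boolean samples × features mask of explicitly missing entries."""
        return self.data.isna().to_numpy()

    # -- derived tables ---------------------------------------------------

    def replace(self, data: pd.DataFrame) -> "FeatureTable":
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[list(data.columns)]
        return FeatureTable(self.layer, data, meta)

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        return self.replace(self.data.loc[:, list(feature_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        data = self.data.loc[list(sample_ids)]
        meta = self.feature_meta
        return FeatureTable(self.layer, data, meta)

    def with_zeros_as_missing(self) -> "FeatureTable":
        """Recode zeros as missing markers (aligned-matrix convention).

        Metabolite intensity matrices conventionally store an absent peak as
        zero; the network stage treats those as missing rather than as a
        measured zero.
        """
        data = self.data.mask(self.data == 0.0)
        return self.replace(data)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.layer == other.layer and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "subject_id", "arm", "diet", "day", "rs_dose")


def make_sample_meta(records: pd.DataFrame | Sequence[Mapping]) -> pd.DataFrame:
    """Build a validated sample-metadata frame.

    ``rs_dose`` is a deterministic function of the diet label and is always
    (re)derived from it: baseline → 0, LRS → 0.05, HRS → 1.
    """
    meta = pd.DataFrame(records).copy()
    required = {"sample_id", "subject_id", "arm", "diet", "day"}
    missing = required - set(meta.columns)
    if missing:
        raise TableError(f"sample metadata lacks columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableError(f"duplicate sample ID {dup!r} in metadata")
    bad_diet = set(meta["diet"]) - set(DIETS)
    if bad_diet:
        raise TableError(f"unknown diet labels {sorted(bad_diet)}")
    bad_arm = set(meta["arm"]) - {"HC", "LC"}
    if bad_arm:
        raise TableError(f"unknown study arms {sorted(bad_arm)}")
    meta["day"] = meta["day"].astype(int)
    meta["rs_dose"] = meta["diet"].map(RS_DOSE).astype(float)
    return meta.loc[:, list(META_COLUMNS)].reset_index(drop=True)


def join_meta(table: FeatureTable, meta: pd.DataFrame) -> tuple[FeatureTable, pd.DataFrame]:
    """Attach sample metadata to a table, ordering both consistently.

    Returns the table restricted/ordered to its own samples plus the matching
    metadata rows in the same order.  Every table sample must be present in
    the metadata.
    """
    meta = make_sample_meta(meta)
    known = set(meta["sample_id"])
    unmatched = [s for s in table.sample_ids if s not in known]
    if unmatched:
        raise TableError(f"samples missing from metadata: {unmatched}")
    indexed = meta.set_index("sample_id", drop=False)
    ordered = indexed.loc[table.sample_ids].reset_index(drop=True)
    return table, ordered


def shared_samples(a: FeatureTable, b: FeatureTable) -> list[str]:
    """Sample IDs present in both tables, in sorted order."""
    return sorted(set(a.sample_ids) & set(b.sample_ids))


# ---------------------------------------------------------------------------
# Taxonomy lineages (Greengenes-style "k__...; p__...; ..." strings)
# ---------------------------------------------------------------------------


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Greengenes-style lineage string into rank → name.

    Empty ranks (``g__``) are allowed and omitted; parsing is lenient about
    whitespace.  Assigned ranks must be contiguous from the top: a genus
    without a family is rejected.
    """
    ranks: dict[str, str] = {}
    if not lineage or not lineage.strip():
        return ranks
    for part in lineage.split(";"):
        part = part.strip()
        if not part:
            continue
        if len(part) >= 3 and part[1:3] == "__" and part[0] in _RANK_PREFIX:
            name = part[3:].strip()
            if name:
                ranks[_RANK_PREFIX[part[0]]] = name
        elif part.strip("_"):
            raise TableError(f"unparseable lineage segment {part!r}")
    seen_gap = False
    for rank in TAXONOMY_RANKS:
        if rank not in ranks:
            seen_gap = True
        elif seen_gap:
            raise TableError(
                f"lineage {lineage!r} assigns {rank} below an unassigned rank"
            )
    return ranks


def taxon_at_rank(lineage: str, rank: str) -> str | None:
    if rank not in TAXONOMY_RANKS:
        raise TableError(f"unknown taxonomic rank {rank!r}")
    return parse_lineage(lineage).get(rank)


# ---------------------------------------------------------------------------
# Readers / writers (TSV, deterministic column order)
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path, layer: str) -> FeatureTable:
    """Read a features-in-rows TSV into a FeatureTable.

    The first column holds feature IDs; the header row holds sample IDs.
    ``NA`` tokens become missing markers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise TableError(f"{path}: expected feature-ID column plus >=1 sample")
    feature_col = frame.columns[0]
    features = frame[feature_col]
    if features.duplicated().any():
        dup = features[features.duplicated()].iloc[0]
        raise TableError(f"{path}: duplicate feature ID {dup!r}")
    body = frame.drop(columns=[feature_col])
    matrix = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            token = cell.strip()
            if token in ("", "NA", "NaN", "nan"):
                matrix[i, j] = np.nan
                continue
            try:
                matrix[i, j] = float(token)
            except ValueError:
                raise TableError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{features.iloc[i]!r}, sample {col!r}"
                ) from None
    data = pd.DataFrame(matrix.T, index=list(body.columns), columns=list(features))
    data.index.name = "sample_id"
    return FeatureTable(layer, data)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as features-in-rows TSV.

    Values are written with shortest-round-trip float formatting, so a
    write/read cycle is lossless.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        values = table.values()
        for j, fid in enumerate(table.feature_ids):
            cells = []
            for i in range(table.n_samples):
                v = values[i, j]
                cells.append("NA" if np.isnan(v) else repr(float(v)))
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return make_sample_meta(frame)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    make_sample_meta(meta).to_csv(path, sep="\t", index=False)


def read_protein_annotations(path: str | Path) -> pd.DataFrame:
    """Read a protein annotation TSV (protein_id, cog_class, lineage, is_human)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "cog_class", "lineage", "is_human"}
    missing = required - set(frame.columns)
    if missing:
        raise TableError(f"annotation file lacks columns {sorted(missing)}")
    frame["is_human"] = frame["is_human"].str.lower().isin(("1", "true", "yes"))
    if (frame["is_human"] & (frame["lineage"].str.strip() != "")).any():
        bad = frame.loc[frame["is_human"] & (frame["lineage"].str.strip() != "")]
        raise TableError(
            f"human proteins must carry no taxon: {list(bad['protein_id'][:3])}"
        )
    return frame.set_index("protein_id", drop=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
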