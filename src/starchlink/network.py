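"""Cross-omics association networks by context likelihood of relatedness.

The CLR procedure scores each feature pair by how exceptional their mutual
information is against each feature's own background MI distribution: with
μᵢ, σᵢ the mean and standard deviation of feature i's off-diagonal MI row,
the rectified z-score is zᵢ = max(0, (MIᵢⱼ − μᵢ)/σᵢ) and the pair score is
√(zᵢ² + zⱼ²).  MI is estimated in bits by a plug-in estimator over
equal-frequency (value-quantile) discretization — B = ⌊√n⌋ bins, minimum 2 —
which makes the whole score invariant under monotone transformations of each
feature.

Six networks are assembled: one per layer (intra-layer edges, computed on
each single-layer table alone) and one per layer pair (inter-layer edges,
computed on the participant-matched combined table, from which only the
between-layer pairs are taken).  Edges survive at CLR z ≥ the threshold
(default 6.5), and the merged network records each edge's provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, TableError

LAYER_SHORT = {"otu": "otu", "protein": "prot", "metabolite": "metab"}

#: layers whose zeros conventionally encode an absent (missing) measurement
ZERO_IS_MISSING = ("metabolite",)

MIN_SHARED_SAMPLES = 8


def filter_missing(
    table: FeatureTable, max_missing_fraction: float = 0.5
) -> FeatureTable:
    """Drop features with *greater than* the allowed fraction of missing
    values (a feature at exactly the threshold is kept).

    Only explicit missing markers count; zeros in count layers are data.
    """
    frac = table.data.isna().mean(axis=0)
    keep = [f for f in table.feature_ids if frac[f] <= max_missing_fraction]
    return table.select_features(keep)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def n_bins(n_samples: int) -> int:
    """Discretization granularity: ⌊√n⌋ bins, at least 2."""
    return max(2, int(np.floor(np.sqrt(n_samples))))


def discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (value-quantile) bin codes per column; missing → −1.

    Quantile edges are computed on each column's non-missing values, so the
    coding is invariant under strictly monotone transformations and does not
    depend on row order.
    """
    n, p = values.shape
    codes = np.full((n, p), -1, dtype=np.int64)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(p):
        col = values[:, j]
        valid = ~np.isnan(col)
        if valid.sum() == 0:
            continue
        edges = np.quantile(col[valid], qs)
        codes[valid, j] = np.searchsorted(edges, col[valid], side="right")
    return codes


@dataclass
class MIMatrix:
    """Symmetric node × node mutual-information matrix (bits)."""

    mi: pd.DataFrame
    node_layer: dict[str, str]

    def __post_init__(self) -> None:
        values = self.mi.to_numpy()
        if values.shape[0] != values.shape[1]:
            raise TableError("MI matrix must be square")
        if (values < -1e-12).any():
            raise TableError("MI entries must be non-negative")


def _node(layer: str, fid: str) -> str:
    return f"{layer}:{fid}"


def _mi_from_codes(codes: np.ndarray, bins: int) -> np.ndarray:
    """Plug-in MI (bits) between every pair of columns, pairwise-deleting
    missing entries (code −1)."""
    n, p = codes.shape
    valid = (codes >= 0).astype(np.float64)
    indicators = [((codes == b) & (codes >= 0)).astype(np.float64) for b in range(bins)]

    n_pair = valid.T @ valid  # samples valid in both features
    # marginal counts restricted to the pairwise-complete sample set
    row_marg = [indicators[a].T @ valid for a in range(bins)]  # count(X_i = a | j valid)
    col_marg = [valid.T @ indicators[b] for b in range(bins)]  # count(X_j = b | i valid)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_n = np.where(n_pair > 0, np.log2(np.where(n_pair > 0, n_pair, 1.0)), 0.0)
        total = np.zeros((p, p))
        for a in range(bins):
            log_ra = np.where(row_marg[a] > 0,
                              np.log2(np.where(row_marg[a] > 0, row_marg[a], 1.0)), 0.0)
            for b in range(bins):
                joint = indicators[a].T @ indicators[b]
                mask = joint > 0
                if not mask.any():
                    continue
                log_cb = np.where(col_marg[b] > 0,
                                  np.log2(np.where(col_marg[b] > 0, col_marg[b], 1.0)),
                                  0.0)
                log_j = np.zeros_like(joint)
                log_j[mask] = np.log2(joint[mask])
                total += np.where(mask, joint * (log_j + log_n - log_ra - log_cb), 0.0)
        mi = np.where(n_pair > 0, total / np.where(n_pair > 0, n_pair, 1.0), 0.0)
    return np.maximum(mi, 0.0)


def pairwise_mi(
    a: FeatureTable, b: FeatureTable | None = None, bins: int | None = None
) -> MIMatrix:
    """Mutual information (bits) between all feature pairs.

    With one table the MI is computed within its features; with two, the
    tables are restricted to their shared samples and the MI covers the
    concatenated feature set (nodes named ``layer:feature``).  Fewer than
    8 shared samples is rejected.
    """
    if b is None:
        tables = [a]
        sample_ids = list(a.sample_ids)
    else:
        sample_ids = sorted(set(a.sample_ids) & set(b.sample_ids))
        tables = [a.select_samples(sample_ids), b.select_samples(sample_ids)]
    if len(sample_ids) < MIN_SHARED_SAMPLES:
        raise TableError(
            f"only {len(sample_ids)} shared samples; need >= {MIN_SHARED_SAMPLES}"
        )
    nodes: list[str] = []
    node_layer: dict[str, str] = {}
    blocks = []
    for t in tables:
        for fid in t.feature_ids:
            node = _node(t.layer, fid)
            if node in node_layer:
                raise TableError(f"duplicate node {node!r}")
            nodes.append(node)
            node_layer[node] = t.layer
        blocks.append(t.values())
    values = np.concatenate(blocks, axis=1)
    bins = n_bins(len(sample_ids)) if bins is None else bins
    codes = discretize(values, bins)
    mi = _mi_from_codes(codes, bins)
    frame = pd.DataFrame(mi, index=nodes, columns=nodes)
    return MIMatrix(frame, node_layer)


def clr_scores(mi: MIMatrix | pd.DataFrame) -> pd.DataFrame:
    """Rectified CLR z-scores: zᵢⱼ = √(max(0,zᵢ)² + max(0,zⱼ)²).

    The background μᵢ, σᵢ are the mean and standard deviation of feature i's
    off-diagonal MI row.  A constant row (σᵢ = 0) contributes 0 with a
    warning.
    """
    frame = mi.mi if isinstance(mi, MIMatrix) else mi
    values = frame.to_numpy(dtype=float)
    p = values.shape[0]
    off = values.copy()
    np.fill_diagonal(off, np.nan)
    mu = np.nanmean(off, axis=1)
    sigma = np.nanstd(off, axis=1)  # population sd of the background row
    flat = sigma == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} feature(s) have a constant MI background; "
            "their CLR contribution is 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z_row = (values - mu[:, None]) / sigma[:, None]
    z_row[flat, :] = 0.0
    z_row = np.maximum(z_row, 0.0)
    z = np.sqrt(z_row**2 + z_row.T**2)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=frame.index, columns=frame.columns)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def _provenance(layer_a: str, layer_b: str) -> str:
    order = ["otu", "protein", "metabolite"]
    la, lb = sorted((layer_a, layer_b), key=order.index)
    return f"{LAYER_SHORT[la]}-{LAYER_SHORT[lb]}"


def _match_samples(
    a: FeatureTable, b: FeatureTable, meta: pd.DataFrame
) -> tuple[FeatureTable, FeatureTable]:
    """Restrict two tables to samples matched on (subject, diet)."""
    key = meta.set_index("sample_id")[["subject_id", "diet"]].apply(tuple, axis=1)
    keys_a = {key[s]: s for s in a.sample_ids if s in key.index}
    keys_b = {key[s]: s for s in b.sample_ids if s in key.index}
    shared = sorted(set(keys_a) & set(keys_b))
    return (
        a.select_samples([keys_a[k] for k in shared]),
        b.select_samples([keys_b[k] for k in shared]),
    )


def _prepare(table: FeatureTable, max_missing_fraction: float) -> FeatureTable:
    if table.layer in ZERO_IS_MISSING:
        table = table.with_zeros_as_missing()
    return filter_missing(table, max_missing_fraction)


def build_network(
    tables: Mapping[str, FeatureTable],
    meta: pd.DataFrame,
    z_threshold: float = 6.5,
    max_missing_fraction: float = 0.5,
) -> nx.Graph:
    """Assemble the merged cross-omics network.

    Intra-layer edges come from each single-layer table's own CLR network;
    inter-layer edges come from the CLR network of the participant-matched
    combined table for that layer pair, keeping only between-layer pairs.
    Edges need CLR z ≥ ``z_threshold`` (inclusive); nodes with no surviving
    edge are omitted.  Layer pairs with fewer than 8 matched samples are
    skipped with a warning.
    """
    if len(tables) < 2:
        raise TableError("network assembly needs at least 2 layers")
    graph = nx.Graph()

    def add_edges(z: pd.DataFrame, node_layer: Mapping[str, str], inter_only: bool):
        nodes = list(z.index)
        values = z.to_numpy()
        for i, j in zip(*np.where(np.triu(values >= z_threshold, k=1))):
            ni, nj = nodes[i], nodes[j]
            la, lb = node_layer[ni], node_layer[nj]
            if inter_only == (la == lb):
                continue
            for node in (ni, nj):
                layer = node_layer[node]
                graph.add_node(node, layer=layer,
                               feature_id=node.split(":", 1)[1])
            graph.add_edge(ni, nj, z=float(values[i, j]),
                           provenance=_provenance(la, lb))

    # intra-layer networks, one per single-layer table
    for layer in sorted(tables):
        prepared = _prepare(tables[layer], max_missing_fraction)
        if prepared.n_samples < MIN_SHARED_SAMPLES or prepared.n_features < 2:
            warnings.warn(f"layer {layer!r} skipped (too few samples or features)",
                          stacklevel=2)
            continue
        mi = pairwise_mi(prepared)
        add_edges(clr_scores(mi), mi.node_layer, inter_only=False)

    # inter-layer networks, one per matched layer pair
    for layer_a, layer_b in combinations(sorted(tables), 2):
        a, b = _match_samples(tables[layer_a], tables[layer_b], meta)
        if a.n_samples < MIN_SHARED_SAMPLES:
            warnings.warn(
                f"pair {layer_a}/{layer_b} skipped: only {a.n_samples} matched samples",
                stacklevel=2,
            )
            continue
        a = _prepare(a, max_missing_fraction)
        b = _prepare(b, max_missing_fraction)
        if a.n_features == 0 or b.n_features == 0:
            continue
        mi = pairwise_mi(a, b)
        add_edges(clr_scores(mi), mi.node_layer, inter_only=True)

    return graph


# ---------------------------------------------------------------------------
# Node coloring by diet association
# ---------------------------------------------------------------------------


def color_nodes(
    graph: nx.Graph,
    tables: Mapping[str, FeatureTable],
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("baseline", "HRS"),
    alpha: float = 0.05,
    drop_neutral: bool = False,
) -> nx.Graph:
    """Color nodes by diet association (two-sided two-sample t test).

    A node is ``higher`` (``lower``) when the second contrast group's mean is
    significantly above (below) the first at level ``alpha``, else
    ``neutral``.  With ``drop_neutral`` only significant nodes are kept.
    """
    indexed = meta.set_index("sample_id")
    for node in list(graph.nodes):
        layer = graph.nodes[node]["layer"]
        fid = graph.nodes[node]["feature_id"]
        table = tables[layer]
        if layer in ZERO_IS_MISSING:
            table = table.with_zeros_as_missing()
        series = table.data[fid]
        groups = []
        for diet in contrast:
            samples = [
                s for s in table.sample_ids if indexed.loc[s, "diet"] == diet
            ]
            vals = series.loc[samples].dropna().to_numpy(dtype=float)
            groups.append(vals)
        if min(len(g) for g in groups) < 2:
            warnings.warn(f"node {node!r}: a contrast group has < 2 samples; neutral",
                          stacklevel=2)
            color, p = "neutral", np.nan
        else:
            stat = stats.ttest_ind(groups[1], groups[0])
            p = float(stat.pvalue)
            if np.isnan(p) or p >= alpha:
                color = "neutral"
            else:
                color = "higher" if groups[1].mean() > groups[0].mean() else "lower"
        graph.nodes[node]["color"] = color
        graph.nodes[node]["p_value"] = p
    if drop_neutral:
        neutral = [n for n in graph.nodes if graph.nodes[n]["color"] == "neutral"]
        graph.remove_nodes_from(neutral)
    return graph


# ---------------------------------------------------------------------------
# Modules and hubs
# ---------------------------------------------------------------------------


@dataclass
class NetworkModule:
    module_id: int
    members: list[str]
    layer_composition: dict[str, int]


def extract_modules(
    graph: nx.Graph, method: str = "components", seed: int = 0
) -> list[NetworkModule]:
    """Partition the non-isolated nodes into modules.

    ``components``: connected components.  ``modularity``: seeded Louvain
    modularity maximization.  Modules are sorted by size descending, ties by
    smallest member ID.
    """
    if graph.number_of_nodes() == 0:
        return []
    if method == "components":
        raw = [set(c) for c in nx.connected_components(graph)]
    elif method == "modularity":
        raw = [set(c) for c in nx.community.louvain_communities(graph, seed=seed)]
    else:
        raise TableError(f"unknown module method {method!r}")
    raw = [c for c in raw if len(c) > 0]
    ordered = sorted(raw, key=lambda c: (-len(c), min(c)))
    modules = []
    for i, community in enumerate(ordered, start=1):
        members = sorted(community)
        composition: dict[str, int] = {}
        for node in members:
            layer = graph.nodes[node]["layer"]
            composition[layer] = composition.get(layer, 0) + 1
        modules.append(NetworkModule(i, members, composition))
    return modules


def hub_report(graph: nx.Graph, top_k: int = 10) -> pd.DataFrame:
    """Nodes ranked by degree (descending), ties broken by node ID."""
    if graph.number_of_nodes() == 0:
        raise TableError("hub report on an empty network")
    ranked = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return pd.DataFrame(ranked, columns=["node", "degree"])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, attrs in sorted(graph.edges(data=True)):
        la, fa = u.split(":", 1)
        lb, fb = v.split(":", 1)
        rows.append((la, fa, lb, fb, attrs["z"], attrs["provenance"]))
    frame = pd.DataFrame(
        rows,
        columns=["source_layer", "source_id", "target_layer", "target_id",
                 "z", "provenance"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_nodes_tsv(graph: nx.Graph, path: str | Path) -> None:
    rows = []
    for node, attrs in sorted(graph.nodes(data=True)):
        rows.append(
            (node, attrs.get("layer"), attrs.get("feature_id"),
             attrs.get("color", ""), attrs.get("p_value", np.nan))
        )
    frame = pd.DataFrame(rows, columns=["node", "layer", "feature_id",
                                        "color", "p_value"])
    frame.to_csv(path, sep="\t", index=False)


def write_modules_tsv(modules: Sequence[NetworkModule], path: str | Path) -> None:
    rows = []
    for module in modules:
        for node in module.members:
            layer, fid = node.split(":", 1)
            rows.append((module.module_id, layer, fid))
    pd.DataFrame(rows, columns=["module_id", "layer", "feature"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    export = graph.copy()
    for _, attrs in export.nodes(data=True):
        if "p_value" in attrs and (attrs["p_value"] is None or np.isnan(attrs["p_value"])):
            attrs["p_value"] = -1.0
    nx.write_graphml(export, str(path))
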