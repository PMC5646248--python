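"""Mutual information, CLR scoring, network assembly, modules, hubs."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starchlink.network import (
    MIMatrix,
    build_network,
    clr_scores,
    color_nodes,
    discretize,
    extract_modules,
    filter_missing,
    hub_report,
    pairwise_mi,
)
from starchlink.tables import TableError

from conftest import make_table, recovery_cohort


class TestFilterMissing:
    def test_boundary_exactly_half_kept(self):
        matrix = np.ones((10, 2))
        matrix[:6, 0] = np.nan  # 0.6 missing -> removed
        matrix[:5, 1] = np.nan  # 0.5 missing -> kept (strict "greater than")
        table = make_table(np.nan_to_num(matrix), layer="metabolite")
        table = table.replace(table.data.mask(np.isnan(matrix)))
        kept = filter_missing(table, 0.5)
        assert kept.feature_ids == ["f1"]

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        matrix = rng.random((20, 15))
        mask = rng.random((20, 15)) < 0.4
        matrix[mask] = np.nan
        table = make_table(np.nan_to_num(matrix), layer="metabolite")
        table = table.replace(table.data.mask(np.isnan(matrix)))
        kept = filter_missing(table, 0.5)
        expected = [f for f in table.feature_ids
                    if table.data[f].isna().mean() <= 0.5]
        assert kept.feature_ids == expected


class TestMutualInformation:
    def test_self_mi_is_entropy_of_four_bins(self):
        # 2000 distinct values in 4 equiprobable bins: MI(X,X) = H(X) = 2 bits
        rng = np.random.default_rng(1)
        x = rng.random(2000)
        table = make_table(np.column_stack([x, rng.random(2000)]))
        mi = pairwise_mi(table, bins=4)
        assert mi.mi.iloc[0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_independent_features_low_mi(self):
        """Bias-adjusted plug-in MI of independent features is near zero.

        The plug-in estimator carries a known positive bias of about
        (B−1)²/(2N ln2) bits; after removing it, independent uniforms at
        n = 2000 sit below 0.05 bits.  (CLR is unaffected by this constant
        offset, since its z-scores are background-relative.)
        """
        rng = np.random.default_rng(2)
        n = 2000
        table = make_table(rng.random((n, 2)))
        # coarse, fixed-B regime: the classical consistency statement
        coarse = pairwise_mi(table, bins=4)
        assert coarse.mi.iloc[0, 1] < 0.05
        # default-B regime (B² ≈ N is sparse): the estimate stays at the
        # order of the null bias, i.e. carries no dependence signal
        mi = pairwise_mi(table)
        bins = int(np.floor(np.sqrt(n)))
        bias = (bins - 1) ** 2 / (2 * n * np.log(2))
        assert mi.mi.iloc[0, 1] < 1.5 * bias

    def test_matches_exhaustive_histogram_oracle(self):
        """Estimator equals a brute-force plug-in MI over the joint
        histogram, to 1e-12."""
        rng = np.random.default_rng(3)
        values = rng.random((40, 5))
        values[rng.random((40, 5)) < 0.15] = np.nan
        table = make_table(np.nan_to_num(values), layer="metabolite")
        table = table.replace(table.data.mask(np.isnan(values)))
        bins = 3
        mi = pairwise_mi(table, bins=bins)

        codes = discretize(values, bins)
        p = values.shape[1]
        for i in range(p):
            for j in range(p):
                valid = (codes[:, i] >= 0) & (codes[:, j] >= 0)
                ci, cj = codes[valid, i], codes[valid, j]
                n = valid.sum()
                expected = 0.0
                for a in range(bins):
                    for b in range(bins):
                        nab = ((ci == a) & (cj == b)).sum()
                        if nab == 0:
                            continue
                        na, nb = (ci == a).sum(), (cj == b).sum()
                        expected += (nab / n) * np.log2(nab * n / (na * nb))
                assert mi.mi.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transformation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.random((120, 4))
        table = make_table(values)
        transformed = make_table(np.exp(3 * values))  # strictly monotone
        a = pairwise_mi(table)
        b = pairwise_mi(transformed)
        assert np.allclose(a.mi.to_numpy(), b.mi.to_numpy(), atol=1e-12)

    def test_too_few_shared_samples_rejected(self):
        a = make_table(np.random.default_rng(5).random((5, 3)))
        with pytest.raises(TableError, match="shared samples"):
            pairwise_mi(a)


class TestClrScores:
    def test_flat_background_all_zero(self):
        mi = pd.DataFrame(
            [[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.warns(UserWarning, match="constant MI background"):
            z = clr_scores(mi)
        assert np.allclose(z.to_numpy(), 0.0)

    def test_hand_case(self):
        # backgrounds mu1=1 sd1=0.5, mu2=2 sd2=1, MI12=2 -> z1=2, z2=0, z=2
        mi = pd.DataFrame(
            [
                [9.0, 2.0, 0.5, 1.5],
                [2.0, 9.0, 1.0, 3.0],
                [0.5, 1.0, 9.0, 1.0],
                [1.5, 3.0, 1.0, 9.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        row1 = np.array([2.0, 0.5, 1.5])
        row2 = np.array([2.0, 1.0, 3.0])
        z = clr_scores(mi)
        mu1, s1 = row1.mean(), row1.std()
        mu2, s2 = row2.mean(), row2.std()
        z1 = max(0.0, (2.0 - mu1) / s1)
        z2 = max(0.0, (2.0 - mu2) / s2)
        assert z.loc["a", "b"] == pytest.approx(np.hypot(z1, z2), abs=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(6)
        p = 12
        raw = rng.random((p, p))
        mi_values = (raw + raw.T) / 2
        np.fill_diagonal(mi_values, 3.0)
        frame = pd.DataFrame(mi_values, index=[f"f{i}" for i in range(p)],
                             columns=[f"f{i}" for i in range(p)])
        z = clr_scores(frame)
        # independently coded two-pass oracle
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                row_i = np.delete(mi_values[i], i)
                row_j = np.delete(mi_values[j], j)
                zi = max(0.0, (mi_values[i, j] - row_i.mean()) / row_i.std())
                zj = max(0.0, (mi_values[i, j] - row_j.mean()) / row_j.std())
                assert z.iloc[i, j] == pytest.approx(
                    np.sqrt(zi**2 + zj**2), abs=1e-10
                )

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        raw = rng.random((8, 8))
        mi_values = (raw + raw.T) / 2 + np.eye(8)
        frame = pd.DataFrame(mi_values)
        z = clr_scores(frame)
        assert np.allclose(z.to_numpy(), z.to_numpy().T)


class TestBuildNetwork:
    def test_infinite_threshold_gives_empty_network(self, small_cohort):
        tables, meta, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_network(tables, meta, z_threshold=np.inf)
        assert graph.number_of_edges() == 0

    def test_planted_cross_layer_edge_recovered(self):
        tables, meta, truth = recovery_cohort(seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_network(tables, meta, z_threshold=6.5)
        assert graph.has_edge("otu:OTU_0001", "protein:PROT_0001")
        edge = graph.edges["otu:OTU_0001", "protein:PROT_0001"]
        assert edge["provenance"] == "otu-prot"
        assert edge["z"] >= 6.5

    def test_planted_pair_attains_maximum_interlayer_z(self):
        """Threshold-free rank criterion: the strongest planted cross-layer
        pair carries the largest inter-layer z in the merged network."""
        tables, meta, truth = recovery_cohort(seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_network(tables, meta, z_threshold=0.1)
        inter = [(u, v, d["z"]) for u, v, d in graph.edges(data=True)
                 if graph.nodes[u]["layer"] != graph.nodes[v]["layer"]]
        top = max(inter, key=lambda e: e[2])
        planted = {f"{layer}:{fid}" for (layer, fid) in truth.module_map}
        assert {top[0], top[1]} <= planted

    def test_merged_edges_equal_union_of_six_networks(self, small_cohort):
        """The merge rule is a set union: intra edges from single-layer
        networks, inter edges from pairwise-combined networks."""
        from itertools import combinations

        from starchlink.network import _match_samples, _prepare

        tables, meta, _ = small_cohort
        threshold = 3.0  # low enough to produce edges on a null cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_network(tables, meta, z_threshold=threshold)
            expected = set()
            for layer in tables:
                prepared = _prepare(tables[layer], 0.5)
                z = clr_scores(pairwise_mi(prepared))
                vals = z.to_numpy()
                nodes = list(z.index)
                for i, j in zip(*np.where(np.triu(vals >= threshold, 1))):
                    expected.add(frozenset((nodes[i], nodes[j])))
            for la, lb in combinations(sorted(tables), 2):
                a, b = _match_samples(tables[la], tables[lb], meta)
                mi = pairwise_mi(_prepare(a, 0.5), _prepare(b, 0.5))
                z = clr_scores(mi)
                vals = z.to_numpy()
                nodes = list(z.index)
                for i, j in zip(*np.where(np.triu(vals >= threshold, 1))):
                    if mi.node_layer[nodes[i]] != mi.node_layer[nodes[j]]:
                        expected.add(frozenset((nodes[i], nodes[j])))
        assert {frozenset(e) for e in graph.edges()} == expected


class TestColorNodes:
    def _toy_graph_and_tables(self, shift):
        rng = np.random.default_rng(8)
        from starchlink.tables import make_sample_meta

        records = []
        n = 20
        for i in range(n):
            for diet, day in (("baseline", 14), ("HRS", 56), ("LRS", 28)):
                records.append({"sample_id": f"S{i:02d}-{diet}",
                                "subject_id": f"S{i:02d}", "arm": "LC",
                                "diet": diet, "day": day})
        meta = make_sample_meta(records)
        values = rng.standard_normal((len(meta), 2)) + 5.0
        hrs_rows = [i for i, d in enumerate(meta["diet"]) if d == "HRS"]
        values[hrs_rows, 0] += shift
        table = make_table(values, layer="otu",
                           sample_ids=list(meta["sample_id"]),
                           feature_ids=["shifted", "null"])
        graph = nx.Graph()
        for fid in table.feature_ids:
            graph.add_node(f"otu:{fid}", layer="otu", feature_id=fid)
        graph.add_edge("otu:shifted", "otu:null", z=7.0, provenance="otu-otu")
        return graph, {"otu": table}, meta

    def test_large_shift_colored_correctly(self):
        graph, tables, meta = self._toy_graph_and_tables(shift=10.0)
        color_nodes(graph, tables, meta)
        assert graph.nodes["otu:shifted"]["color"] == "higher"

    def test_identical_groups_neutral(self):
        graph, tables, meta = self._toy_graph_and_tables(shift=0.0)
        color_nodes(graph, tables, meta, alpha=1e-6)
        assert graph.nodes["otu:null"]["color"] == "neutral"

    def test_t_statistic_matches_closed_form_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 4.5, 5.5])
        result = stats.ttest_ind(b, a)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2))
        expected_t = (b.mean() - a.mean()) / (sp * np.sqrt(2 / 4))
        assert result.statistic == pytest.approx(expected_t, abs=1e-12)


class TestModulesAndHubs:
    def _graph(self, edges):
        graph = nx.Graph()
        for u, v in edges:
            for node in (u, v):
                graph.add_node(node, layer=node.split(":")[0],
                               feature_id=node.split(":")[1])
            graph.add_edge(u, v, z=7.0, provenance="otu-otu")
        return graph

    def test_two_triangles_two_modules(self):
        edges = [("otu:a", "otu:b"), ("otu:b", "otu:c"), ("otu:a", "otu:c"),
                 ("otu:x", "otu:y"), ("otu:y", "otu:z"), ("otu:x", "otu:z")]
        modules = extract_modules(self._graph(edges))
        assert len(modules) == 2
        assert all(len(m.members) == 3 for m in modules)
        assert modules[0].members[0] < modules[1].members[0]  # tie-break by ID

    def test_empty_network_empty_modules(self):
        assert extract_modules(nx.Graph()) == []

    def test_planted_modules_recovered_with_high_jaccard(self):
        tables, meta, truth = recovery_cohort(seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_network(tables, meta, z_threshold=6.5)
        modules = extract_modules(graph, method="components")
        for module_id in (1, 2):
            expected = {f"{l}:{f}" for (l, f), m in truth.module_map.items()
                        if m == module_id}
            jaccard = max(
                (len(expected & set(m.members)) / len(expected | set(m.members))
                 for m in modules),
                default=0.0,
            )
            assert jaccard >= 0.8

    def test_star_center_is_top_hub(self):
        edges = [("otu:center", f"otu:leaf{i}") for i in range(5)]
        report = hub_report(self._graph(edges), top_k=3)
        assert report.iloc[0]["node"] == "otu:center"
        assert report.iloc[0]["degree"] == 5

    def test_hub_ties_broken_deterministically(self):
        edges = [("otu:a", "otu:b"), ("otu:c", "otu:d")]
        report = hub_report(self._graph(edges), top_k=4)
        # all degrees equal: order falls back to node ID
        assert list(report["node"]) == ["otu:a", "otu:b", "otu:c", "otu:d"]


def test_null_layers_produce_no_edges(small_cohort):
    """On a cohort with no planted structure, the default z filter keeps
    nothing."""
    tables, meta, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = build_network(tables, meta, z_threshold=6.5)
    assert graph.number_of_edges() == 0
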