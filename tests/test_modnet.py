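"""Module-module interaction weights against dense-loop oracles."""

import numpy as np
import pandas as pd
import pytest

from coexnet.modnet import build_module_network, module_module_weight, overlay_de
from coexnet.modules import ModulePartition, UNASSIGNED
from coexnet.network import CoexprNetwork


def _partition(assignments):
    return ModulePartition(module_of=dict(assignments), min_size=1)


def _net(edge_rows, nodes=None):
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "r", "weight"])
    nodes = nodes or sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CoexprNetwork(nodes=nodes, edges=edges)


def dense_weight_oracle(net, partition, mi, mj):
    """O(|Mi| x |Mj|) literal evaluation of the w formula."""
    lookup = {}
    for _, row in net.edges.iterrows():
        lookup[(row["gene_a"], row["gene_b"])] = row["weight"]
        lookup[(row["gene_b"], row["gene_a"])] = row["weight"]
    total = 0.0
    for g in partition.modules[mi]:
        for h in partition.modules[mj]:
            total += lookup.get((g, h), 0.0)
    return total / (len(partition.modules[mi]) * len(partition.modules[mj]))


def random_instance(rng):
    n = int(rng.integers(6, 50))
    genes = [f"g{i:02d}" for i in range(n)]
    n_modules = int(rng.integers(2, 7))
    labels = [f"M{k + 1}" for k in range(n_modules)]
    assign = {g: labels[rng.integers(n_modules)] for g in genes}
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                r = rng.uniform(0.8, 1.0)
                rows.append((genes[i], genes[j], r, r**7))
    part = ModulePartition(module_of=assign, min_size=1)
    return _net(rows, nodes=genes), part


class TestWeight:
    def test_complete_unit_bipartite_gives_one(self):
        rows = [(a, b, 1.0, 1.0) for a in ("a1", "a2") for b in ("b1", "b2", "b3")]
        part = _partition({"a1": "Mi", "a2": "Mi", "b1": "Mj", "b2": "Mj", "b3": "Mj"})
        assert module_module_weight(_net(rows), part, "Mi", "Mj") == pytest.approx(1.0)

    def test_no_inter_module_edges_gives_zero(self):
        rows = [("a1", "a2", 0.9, 0.9**7)]
        part = _partition({"a1": "Mi", "a2": "Mi", "b1": "Mj"})
        net = _net(rows, nodes=["a1", "a2", "b1"])
        assert module_module_weight(net, part, "Mi", "Mj") == 0.0

    def test_hand_case_half(self):
        rows = [("a", "c", 0.9, 0.6), ("b", "c", 0.85, 0.4)]
        part = _partition({"a": "Mi", "b": "Mi", "c": "Mj"})
        assert module_module_weight(_net(rows), part, "Mi", "Mj") == pytest.approx(0.5)

    def test_symmetric_and_bounded_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            net, part = random_instance(rng)
            labels = part.labels
            if len(labels) < 2:
                continue
            mi, mj = labels[0], labels[1]
            w = module_module_weight(net, part, mi, mj)
            assert 0.0 <= w <= 1.0
            assert w == pytest.approx(module_module_weight(net, part, mj, mi), abs=1e-15)

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            net, part = random_instance(rng)
            labels = part.labels
            for mi in labels:
                for mj in labels:
                    if mi >= mj:
                        continue
                    assert module_module_weight(net, part, mi, mj) == pytest.approx(
                        dense_weight_oracle(net, part, mi, mj), abs=1e-12
                    )

    def test_unknown_module_is_an_error(self):
        rows = [("a", "b", 0.9, 0.5)]
        part = _partition({"a": "Mi", "b": "Mj"})
        with pytest.raises(KeyError):
            module_module_weight(_net(rows), part, "Mi", "Mz")


class TestBuild:
    def test_retention_boundary_at_half(self):
        # w = 0.5 exactly -> retained; w = 0.49 -> absent
        rows = [("a", "c", 0.9, 0.5), ("b", "d", 0.9, 0.49)]
        part = _partition({"a": "M1", "b": "M1", "c": "M2", "d": "M3"})
        net = _net(rows, nodes=["a", "b", "c", "d"])
        # M1-M2: single edge 0.5 over 2x1 -> 0.25; build custom pairs instead
        w12 = module_module_weight(net, part, "M1", "M2")
        assert w12 == pytest.approx(0.25)
        rows = [("a", "c", 0.9, 0.5)]
        part = _partition({"a": "M1", "c": "M2"})
        mnet = build_module_network(_net(rows), part)
        assert list(zip(mnet.edges["module_a"], mnet.edges["module_b"])) == [("M1", "M2")]
        rows = [("a", "c", 0.9, 0.49)]
        mnet = build_module_network(_net(rows), _partition({"a": "M1", "c": "M2"}))
        assert mnet.edges.empty

    def test_matches_brute_force_on_four_modules(self):
        rng = np.random.default_rng(2)
        net, part = random_instance(rng)
        mnet = build_module_network(net, part, w_min=0.05)
        expected = set()
        labels = part.labels
        for i, mi in enumerate(labels):
            for mj in labels[i + 1:]:
                if dense_weight_oracle(net, part, mi, mj) >= 0.05:
                    expected.add(tuple(sorted((mi, mj))))
        got = {tuple(sorted(p)) for p in zip(mnet.edges["module_a"], mnet.edges["module_b"])}
        assert got == expected

    def test_node_sizes_come_from_partition(self):
        rows = [("a", "c", 0.9, 0.6)]
        part = _partition({"a": "M1", "b": "M1", "c": "M2"})
        mnet = build_module_network(_net(rows, nodes=["a", "b", "c"]), part, w_min=0.0)
        assert mnet.nodes.loc["M1", "size"] == 2
        assert mnet.nodes.loc["M2", "size"] == 1


class TestOverlay:
    def _de(self, calls):
        return pd.DataFrame(
            {"log2FC": 0.0, "p": 0.5, "fdr": 0.5, "call": pd.Series(calls)}
        ).rename_axis("gene")

    def test_fraction_arithmetic(self):
        genes = [f"g{i}" for i in range(10)]
        part = _partition({g: "M1" for g in genes})
        net = _net([(genes[0], genes[1], 0.9, 0.5)], nodes=genes)
        mnet = build_module_network(net, part)
        calls = {g: ("up" if i < 5 else "ns") for i, g in enumerate(genes)}
        out = overlay_de(mnet, part, {"c1": self._de(calls)})
        assert out.nodes.loc["M1", "up_frac_c1"] == pytest.approx(0.5)
        assert out.nodes.loc["M1", "down_frac_c1"] == 0.0

    def test_no_de_genes_gives_zero_fractions(self):
        part = _partition({"a": "M1", "b": "M1"})
        net = _net([("a", "b", 0.9, 0.5)])
        mnet = build_module_network(net, part)
        out = overlay_de(mnet, part, {"c1": self._de({"a": "ns", "b": "ns"})})
        assert out.nodes.loc["M1", "up_frac_c1"] == 0.0

    def test_disjoint_universe_is_an_error(self):
        part = _partition({"a": "M1", "b": "M1"})
        net = _net([("a", "b", 0.9, 0.5)])
        mnet = build_module_network(net, part)
        with pytest.raises(ValueError, match="disjoint"):
            overlay_de(mnet, part, {"c1": self._de({"zz": "up"})})

    def test_genes_outside_universe_count_in_denominator(self):
        part = _partition({"a": "M1", "b": "M1", "c": "M1", "d": "M1"})
        net = _net([("a", "b", 0.9, 0.5)], nodes=list("abcd"))
        mnet = build_module_network(net, part)
        out = overlay_de(mnet, part, {"c1": self._de({"a": "up", "b": "up"})})
        assert out.nodes.loc["M1", "up_frac_c1"] == pytest.approx(0.5)
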