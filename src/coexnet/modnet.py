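"""Module-module interaction network with differential-expression overlays.

The interaction weight between two modules Mi and Mj is the sum of the
co-expression edge weights running between them divided by the number of
possible inter-module gene pairs |Mi| x |Mj|; absent pairs contribute 0, so
w always lies in [0, 1]. Module pairs with w >= 0.5 (inclusive) form the
module network. Each module node carries its size, its annotation, and per
contrast the fraction of member genes called up- or down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from coexnet.modules import ModulePartition, UNASSIGNED, module_sizes
from coexnet.network import CoexprNetwork


@dataclass
class ModuleNetwork:
    """Summarised module graph: node table + w-weighted edge table.

    ``nodes`` is indexed by module label with columns ``size``,
    ``annotation``, ``intra_density`` (reporting only; never an edge) and
    per-contrast ``up_frac_<name>`` / ``down_frac_<name>`` columns added by
    :func:`overlay_de`. ``edges`` has columns module_a, module_b, w.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    w_min: float = 0.5

    def to_tsv(self, nodes_path, edges_path) -> None:
        self.nodes.rename_axis("module").to_csv(nodes_path, sep="\t")
        self.edges.to_csv(edges_path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        for m, row in self.nodes.iterrows():
            g.add_node(m, **{k: v for k, v in row.items() if pd.notna(v)})
        for _, row in self.edges.iterrows():
            g.add_edge(row["module_a"], row["module_b"], w=float(row["w"]))
        nx.write_graphml(g, path)


def _inter_module_sums(
    network: CoexprNetwork, partition: ModulePartition
) -> dict[tuple[str, str], float]:
    module_of = partition.module_of
    sums: dict[tuple[str, str], float] = {}
    for a, b, w in zip(
        network.edges["gene_a"], network.edges["gene_b"], network.edges["weight"]
    ):
        ma = module_of.get(a, UNASSIGNED)
        mb = module_of.get(b, UNASSIGNED)
        if ma == UNASSIGNED or mb == UNASSIGNED:
            continue
        key = (ma, mb) if ma <= mb else (mb, ma)
        sums[key] = sums.get(key, 0.0) + float(w)
    return sums


def module_module_weight(
    network: CoexprNetwork, partition: ModulePartition, mi: str, mj: str
) -> float:
    """w(Mi, Mj): inter-module edge-weight sum over |Mi| x |Mj|."""
    for m in (mi, mj):
        if m not in partition.modules:
            raise KeyError(f"unknown module label {m!r}")
    if mi == mj:
        raise ValueError("w is defined for pairs of distinct modules")
    sums = _inter_module_sums(network, partition)
    key = (mi, mj) if mi <= mj else (mj, mi)
    total = sums.get(key, 0.0)
    return total / (len(partition.modules[mi]) * len(partition.modules[mj]))


def intra_module_density(
    network: CoexprNetwork, partition: ModulePartition, m: str
) -> float:
    """Within-module analogue of w, denominator |M|(|M|-1)/2. Reporting only."""
    genes = set(partition.modules[m])
    size = len(genes)
    if size < 2:
        return 0.0
    total = sum(
        float(w)
        for a, b, w in zip(
            network.edges["gene_a"], network.edges["gene_b"], network.edges["weight"]
        )
        if a in genes and b in genes
    )
    return total / (size * (size - 1) / 2)


def build_module_network(
    network: CoexprNetwork, partition: ModulePartition, w_min: float = 0.5
) -> ModuleNetwork:
    """Evaluate w for every module pair and keep edges with w >= w_min."""
    labels = partition.labels
    sizes = module_sizes(partition)
    sums = _inter_module_sums(network, partition)
    rows = []
    for mi, mj in combinations(labels, 2):
        key = (mi, mj) if mi <= mj else (mj, mi)
        w = sums.get(key, 0.0) / (sizes[mi] * sizes[mj])
        if w >= w_min:
            rows.append((mi, mj, w))
    edges = pd.DataFrame(rows, columns=["module_a", "module_b", "w"])
    nodes = pd.DataFrame(
        {
            "size": [sizes[m] for m in labels],
            "annotation": ["NS"] * len(labels),
            "intra_density": [
                intra_module_density(network, partition, m) for m in labels
            ],
        },
        index=pd.Index(labels, name="module"),
    )
    return ModuleNetwork(nodes=nodes, edges=edges, w_min=w_min)


def overlay_de(
    module_net: ModuleNetwork,
    partition: ModulePartition,
    de_results: dict[str, pd.DataFrame],
) -> ModuleNetwork:
    """Attach per-contrast up/down fractions to every module node.

    For each module M and contrast: up_fraction = |M ∩ up-called| / |M|
    (denominator is the full module size; genes outside the DE universe
    count against it). ``de_results`` maps contrast name to a called DE
    table with ``call`` in {up, down, ns}.
    """
    nodes = module_net.nodes.copy()
    for name, de in de_results.items():
        if "call" not in de.columns:
            raise ValueError(f"DE table for {name!r} has no 'call' column")
        universe = set(de.index)
        if not universe & set(partition.module_of):
            raise ValueError("DE universe and partition genes are disjoint")
        up = set(de.index[de["call"] == "up"])
        down = set(de.index[de["call"] == "down"])
        ups, downs = [], []
        for m in nodes.index:
            genes = set(partition.modules[m])
            ups.append(len(genes & up) / len(genes))
            downs.append(len(genes & down) / len(genes))
        nodes[f"up_frac_{name}"] = ups
        nodes[f"down_frac_{name}"] = downs
    return ModuleNetwork(nodes=nodes, edges=module_net.edges, w_min=module_net.w_min)
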