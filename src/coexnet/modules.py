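"""Module detection by hierarchical clustering of the network.

Genes with at least one retained edge are clustered within their connected
component by hierarchical agglomeration of a network dissimilarity, and the
dendrogram is cut at a fixed height (default 0.10). Clusters smaller than
``min_size`` and genes without retained edges are left unassigned.

Two dissimilarities are supported; non-adjacent pairs score 1 under both:

* ``"correlation"`` (default): d = 1 - |r|, on the same scale as the
  network's own correlation cut-off (0.8).
* ``"weight"``: d = 1 - weight = 1 - |r|^beta. With beta = 7 a 0.10 cut
  would demand |r| >= 0.985 and fragments the network into singletons, so
  this variant is only useful with a much higher cut height.

The default linkage is single: with the correlation dissimilarity, cutting
a single-linkage dendrogram at 0.10 is exactly taking the connected
components of the |r| >= 0.90 subnetwork, which assembles co-expression
blocks reliably even when their mean within-block correlation sits near the
cut. Average linkage (available via ``linkage_method``) instead compares
the *cluster mean* dissimilarity to the cut and stalls whenever that mean
straddles it.

Module labels are M1, M2, ... in decreasing size order (ties broken by the
lexicographically smallest member gene), so the partition is deterministic
given the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from coexnet.network import CoexprNetwork

UNASSIGNED = "unassigned"


@dataclass
class ModulePartition:
    """Assignment of genes to labelled modules plus an unassigned pool."""

    module_of: dict[str, str]
    min_size: int
    modules: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        mods: dict[str, list[str]] = {}
        for g, m in self.module_of.items():
            if m != UNASSIGNED:
                mods.setdefault(m, []).append(g)
        self.modules = {m: sorted(gs) for m, gs in sorted(mods.items())}

    @property
    def labels(self) -> list[str]:
        return list(self.modules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.module_of), "module": list(self.module_of.values())}
        ).sort_values("gene", ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _component_labels(genes: list[str], edges: pd.DataFrame) -> np.ndarray:
    idx = {g: i for i, g in enumerate(genes)}
    ia = edges["gene_a"].map(idx).to_numpy()
    ib = edges["gene_b"].map(idx).to_numpy()
    n = len(genes)
    adj = csr_matrix((np.ones(len(edges)), (ia, ib)), shape=(n, n))
    _, labels = connected_components(adj + adj.T, directed=False)
    return labels


def detect_modules(
    network: CoexprNetwork,
    cut_height: float = 0.10,
    min_size: int = 10,
    dissimilarity: str = "correlation",
    linkage_method: str = "single",
) -> ModulePartition:
    """Cut the average-linkage dendrogram of the network at ``cut_height``.

    Genes with no retained edges never enter the tree and are unassigned;
    each connected component is clustered separately (so a cut at height 1
    returns one module per component). Clusters below ``min_size`` are
    unassigned.
    """
    if network.edges.empty:
        warnings.warn("empty network: every gene is unassigned", stacklevel=2)
        return ModulePartition(
            module_of={g: UNASSIGNED for g in network.nodes}, min_size=min_size
        )
    connected_genes = sorted(
        set(network.edges["gene_a"]) | set(network.edges["gene_b"])
    )
    module_of = {g: UNASSIGNED for g in network.nodes}

    if dissimilarity == "correlation":
        sim = network.edges["r"].abs().to_numpy()
    elif dissimilarity == "weight":
        sim = network.edges["weight"].to_numpy()
    else:
        raise ValueError("dissimilarity must be 'correlation' or 'weight'")

    comp = _component_labels(connected_genes, network.edges)
    gidx = {g: i for i, g in enumerate(connected_genes)}
    edge_ij = np.stack(
        [network.edges["gene_a"].map(gidx), network.edges["gene_b"].map(gidx)]
    )

    clusters: list[list[str]] = []
    for c in np.unique(comp):
        members = [g for g, lab in zip(connected_genes, comp) if lab == c]
        if len(members) == 1:
            clusters.append(members)
            continue
        local = {gidx[g]: k for k, g in enumerate(members)}
        n = len(members)
        d = np.ones((n, n))
        np.fill_diagonal(d, 0.0)
        in_comp = np.array([i in local for i in edge_ij[0]])
        for i, j, s in zip(edge_ij[0][in_comp], edge_ij[1][in_comp], sim[in_comp]):
            a, b = local[i], local[j]
            d[a, b] = d[b, a] = 1.0 - s
        Z = linkage(squareform(d, checks=False), method=linkage_method)
        flat = fcluster(Z, t=cut_height, criterion="distance")
        for lab in np.unique(flat):
            clusters.append([members[k] for k in np.where(flat == lab)[0]])

    kept = [sorted(cl) for cl in clusters if len(cl) >= min_size]
    kept.sort(key=lambda cl: (-len(cl), cl[0]))
    for i, cl in enumerate(kept, start=1):
        for g in cl:
            module_of[g] = f"M{i}"
    if not kept:
        warnings.warn("no cluster reached min_size: all genes unassigned", stacklevel=2)
    return ModulePartition(module_of=module_of, min_size=min_size)


def module_sizes(partition: ModulePartition) -> dict[str, int]:
    """Gene counts per module, in module-label order."""
    return {m: len(gs) for m, gs in partition.modules.items()}


def module_summary(partition: ModulePartition, network: CoexprNetwork) -> pd.DataFrame:
    """Per-module size and mean intra-module edge weight."""
    lookup = network.weight_lookup()
    rows = []
    for m, genes in partition.modules.items():
        gs = set(genes)
        weights = [w for (a, b), w in lookup.items() if a in gs and b in gs]
        rows.append((m, len(genes), float(np.mean(weights)) if weights else 0.0))
    return pd.DataFrame(rows, columns=["module", "size", "mean_intra_weight"])
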