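"""Weighted gene co-expression network construction.

Pairwise Pearson correlations of log2-CPM are soft-thresholded by powering:
unsigned adjacency a_ij = |r_ij|^beta (recommended beta = 7), which
emphasises strong co-expression and drives the connectivity distribution
toward a scale-free law. The final network keeps gene pairs with
|r| >= r_cutoff (default 0.8, i.e. weight >= 0.8^beta), stored as a sparse
edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NetworkConfig:
    beta: int = 7
    r_cutoff: float = 0.8
    signed: bool = False

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.r_cutoff < 1.0:
            raise ValueError("r_cutoff must lie in (0, 1)")


@dataclass
class CoexprNetwork:
    """Thresholded co-expression network as an edge list.

    ``edges`` has columns gene_a, gene_b, r, weight with gene_a < gene_b;
    ``nodes`` lists every gene that entered network construction (including
    genes left without retained edges).
    """

    nodes: list[str]
    edges: pd.DataFrame
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def n_edges(self) -> int:
        return len(self.edges)

    def weight_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): w
            for a, b, w in zip(self.edges["gene_a"], self.edges["gene_b"], self.edges["weight"])
        }

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def pairwise_correlation(expr, genes: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of genes over samples.

    Accepts a NormalizedExpression or a gene x sample DataFrame.
    Zero-variance genes are excluded with a warning.
    """
    mat = expr.log2_cpm if hasattr(expr, "log2_cpm") else expr
    if genes is not None:
        mat = mat.loc[genes]
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = mat.std(axis=1, ddof=1)
    flat = sd[sd == 0].index
    if len(flat):
        warnings.warn(
            f"excluded {len(flat)} zero-variance gene(s) from the correlation matrix",
            stacklevel=2,
        )
        mat = mat.drop(index=flat)
    r = np.atleast_2d(np.corrcoef(mat.to_numpy()))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=mat.index, columns=mat.index)


def soft_power_adjacency(r: pd.DataFrame, config: NetworkConfig) -> pd.DataFrame:
    """Powered adjacency: |r|^beta unsigned, ((1+r)/2)^beta signed; diag 0."""
    rv = r.to_numpy()
    if config.signed:
        a = ((1.0 + rv) / 2.0) ** config.beta
    else:
        a = np.abs(rv) ** config.beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity-distribution fit.

    Node connectivity k is the adjacency row sum; k is binned into
    ``n_bins`` logarithmic bins and log10 p(k) regressed on log10 of the
    bin-mean connectivity. Degenerate inputs (all k equal, or fewer than
    two occupied bins) return NaN.
    """
    k = adjacency.to_numpy().sum(axis=1)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return float("nan")
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 2:
        return float("nan")
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2)


def threshold_network(
    r: pd.DataFrame, config: NetworkConfig | None = None
) -> CoexprNetwork:
    """Apply the correlation cut-off and store the surviving edges.

    A pair is retained iff |r| >= r_cutoff (inclusive), equivalently
    weight >= r_cutoff^beta for the unsigned adjacency.
    """
    config = config or NetworkConfig()
    genes = list(r.index)
    rv = r.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    keep = np.abs(rv[iu]) >= config.r_cutoff
    ia, ib = iu[0][keep], iu[1][keep]
    rr = rv[iu][keep]
    if config.signed:
        w = ((1.0 + rr) / 2.0) ** config.beta
    else:
        w = np.abs(rr) ** config.beta
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ia],
            "gene_b": [genes[j] for j in ib],
            "r": rr,
            "weight": w,
        }
    )
    # canonical ordering: gene_a < gene_b lexicographically, rows sorted
    swap = edges["gene_a"] > edges["gene_b"]
    edges.loc[swap, ["gene_a", "gene_b"]] = edges.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    edges = edges.sort_values(["gene_a", "gene_b"], ignore_index=True)
    if edges.empty:
        warnings.warn("no edges survive the correlation cut-off", stacklevel=2)
    return CoexprNetwork(nodes=genes, edges=edges, config=config)


def build_network(expr, config: NetworkConfig | None = None) -> CoexprNetwork:
    """Correlations -> powering -> cut-off in one call."""
    r = pairwise_correlation(expr)
    return threshold_network(r, config or NetworkConfig())
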