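"""Overrepresentation analysis of gene lists against GMT collections.

Each (query, gene set) pair gets a one-sided hypergeometric upper-tail
p-value P(X >= k) for drawing k annotated genes in a query of size n from
a universe of N genes containing K set members. Modules are annotated by
the smallest-FDR set (BH across sets, per module) or the sentinel "NS"
when nothing clears the significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from coexnet.diffexpr import bh_adjust
from coexnet.modules import ModulePartition

NOT_SIGNIFICANT = "NS"


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, insertion order preserved."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set[str]:
        return {g for genes in self.sets.values() for g in genes}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = parts
        seen: list[str] = []
        for g in genes:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
        descriptions[name] = desc
    if not sets:
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions) if sets else GeneSetCollection(sets={}, descriptions={})


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, ""), *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def ora_test(
    query: set[str], target: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric overrepresentation test.

    Returns (k, p) with k = |query ∩ target| and p = P(X >= k) for
    X ~ Hypergeom(N=|universe|, K=|target|, n=|query|).
    """
    query, target, universe = set(query), set(target), set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    target = target & universe
    k = len(query & target)
    p = float(hypergeom.sf(k - 1, len(universe), len(target), len(query)))
    return k, min(p, 1.0)


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    query_name: str = "query",
) -> pd.DataFrame:
    """ORA of one gene list against every set, BH-adjusted across sets."""
    rows = []
    for name, genes in collection.sets.items():
        target = set(genes) & universe
        if not target:
            continue
        k, p = ora_test(query, target, universe)
        rows.append((query_name, name, k, len(query), len(target), len(universe), p))
    out = pd.DataFrame(
        rows, columns=["query", "set", "k", "n", "K", "N", "p"]
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def annotate_modules(
    partition: ModulePartition,
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Top-ranking significant gene set per module, or "NS".

    The universe defaults to all genes in the partition (assigned or not) —
    the analysed transcriptome. Ties on FDR are broken by larger overlap,
    then set name.
    """
    if universe is None:
        universe = set(partition.module_of)
    annotations: dict[str, str] = {}
    for m, genes in partition.modules.items():
        table = enrich(set(genes) & universe, collection, universe, query_name=m)
        if table.empty:
            annotations[m] = NOT_SIGNIFICANT
            continue
        table = table.sort_values(
            ["fdr", "k", "set"], ascending=[True, False, True], ignore_index=True
        )
        best = table.iloc[0]
        annotations[m] = best["set"] if best["fdr"] < alpha else NOT_SIGNIFICANT
    return annotations
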