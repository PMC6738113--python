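#!/usr/bin/env python
"""TMM normalisation and the 5-CPM expression filter.

Reads the simulated counts from results/01_simulated/, computes TMM
factors, keeps genes with mean CPM >= 5 in at least one cell line and
writes log2-CPM (prior 0.5) under results/02_preprocess/.
"""

from pathlib import Path

from coexnet.preprocess import CountMatrix, filter_low_expression, log_cpm, tmm_factors

IN = Path("results/01_simulated")
OUT = Path("results/02_preprocess")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm = CountMatrix.from_tsv(IN / "counts.tsv", IN / "samples.tsv")
    factors = tmm_factors(cm)
    factors.to_frame().rename_axis("sample").to_csv(OUT / "tmm_factors.tsv", sep="\t")
    print(f"TMM factors in [{factors.min():.3f}, {factors.max():.3f}] (geometric mean 1)")

    filtered = filter_low_expression(cm, min_cpm=5.0)
    filtered.counts.rename_axis("gene").to_csv(OUT / "filtered_counts.tsv", sep="\t")
    print(
        f"expression filter: kept {filtered.counts.shape[0]} of {cm.counts.shape[0]} genes "
        "(mean CPM >= 5 in at least one cell line)"
    )

    expr = log_cpm(filtered, factors, prior_count=0.5)
    expr.log2_cpm.rename_axis("gene").to_csv(OUT / "log_cpm.tsv", sep="\t")
    print(f"log2-CPM written for {expr.log2_cpm.shape[0]} genes")


if __name__ == "__main__":
    main()
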