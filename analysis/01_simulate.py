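#!/usr/bin/env python
"""Generate the synthetic study: counts, metabolite panel and qPCR plates.

Emulates the 36-sample RNA-seq design (2 isogenic cell lines x 6 time
points x 3 replicates) with eight 100-gene co-expression modules planted at
within-module r = 0.9 and 10% of genes carrying |log2FC| = 2 genotype
effects, plus the 188-analyte targeted metabolite panel (4 cell lines x 6
replicates) and a noiseless + noisy qPCR plate for the ddCq calculator.

Writes everything under results/01_simulated/.
"""

from pathlib import Path

from coexnet.pipeline import write_metabolite_table
from coexnet.simulate import (
    SimDesign,
    default_metabolite_panel,
    simulate_counts,
    simulate_metabolites,
    simulate_qpcr,
    write_simulation,
)

OUT = Path("results/01_simulated")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = SimDesign(
        n_genes=2000,
        module_sizes=(100,) * 8,
        module_correlation=0.9,
        de_fraction=0.1,
        de_log2fc=2.0,
        seed=SEED,
    )
    cm, truth = simulate_counts(design)
    write_simulation(cm, truth, design, OUT)
    n_modular = sum(m is not None for m in truth.module_of.values())
    print(f"counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples")
    print(f"planted: {n_modular} module genes, {len(truth.de_genes['genotype'])} DE genes")

    panel = default_metabolite_panel()
    table, met_truth = simulate_metabolites(
        n_groups=4,
        n_reps=6,
        effect_metabolites=set(list(panel)[::3]),
        effect_log2fc=1.0,
        seed=SEED + 1000,
    )
    write_metabolite_table(table, OUT / "metabolites.tsv", OUT / "metabolite_groups.tsv")
    print(
        f"metabolites: {table.concentrations.shape[0]} analytes, "
        f"{len(met_truth.de_genes['group_effect'])} with planted group shifts"
    )

    for name, fc, sd in (("qpcr_noiseless.tsv", 4.0, 0.0), ("qpcr_noisy.tsv", 4.0, 0.1)):
        simulate_qpcr(fc, noise_sd=sd, seed=SEED + 2000).to_csv(OUT / name, sep="\t", index=False)
    print("qPCR plates written (true fold change 4)")


if __name__ == "__main__":
    main()
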