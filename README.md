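# coexnet

Weighted co-expression module networks, negative-binomial differential
expression and targeted-metabolomics statistics for two-genotype RNA-seq
time courses.

The package re-implements, as a tested and reusable pipeline, the
computational analysis used to characterise transcriptional and metabolic
rewiring between isogenic KRAS wild-type and KRAS(G13D) colorectal cancer
cell lines sampled over a growth-factor stimulation time course
(2 genotypes × 6 time points × 3 replicates = 36 RNA-seq samples). It is
aimed at computational biologists who want each stage of that analysis as a
plain, testable Python function rather than a chain of R scripts, together
with a synthetic-data generator that plants known structure so every stage
can be validated against ground truth.

## What it computes

**Differential expression.** Counts are TMM-normalised (trimmed mean of
M-values: 30%/5% double trimming, inverse-variance weights, factors scaled
to geometric mean 1), genes are kept when their mean CPM reaches 5 in at
least one cell line, and each gene is fitted with a negative-binomial GLM
(log link, library-size offsets):

    y_gs ~ NB(mu_gs, phi),   log mu_gs = x_s' beta_g + log N_s

A single common dispersion phi maximises the Cox–Reid adjusted profile
likelihood summed over genes; contrasts are tested with a likelihood-ratio
test against chi-square(1). A gene is called up/down when |log2FC| > 1 and
the Benjamini–Hochberg FDR < 0.05 (both strict). qPCR plates are analysed
with the 2^-ddCq method against the mean of the reference genes.

**Co-expression network and modules.** Pearson correlations of log2-CPM are
soft-thresholded to an unsigned adjacency a_ij = |r_ij|^beta (beta = 7) and
edges with |r| >= 0.8 form the network. Modules come from hierarchical
clustering of the network dissimilarity (d = 1 − |r|, non-edges at 1) cut
at height 0.10, with clusters under 10 genes left unassigned.

**Module–module interaction network.** For modules Mi, Mj the interaction
weight is

    w(Mi, Mj) = ( Σ_{g∈Mi, h∈Mj} a_gh ) / ( |Mi| · |Mj| )  ∈ [0, 1]

and pairs with w >= 0.5 are retained. Each module node carries its size,
its top overrepresented gene set (hypergeometric test against a GMT
collection, BH across sets, "NS" when nothing is significant) and, per
contrast, the fraction of member genes called up- or down-regulated.

**Targeted metabolomics.** A 188-analyte panel (21 amino acids, 21 biogenic
amines, 40 acylcarnitines, 90 phosphatidylcholines, 15 sphingomyelins,
total hexoses) is compared across cell-line groups by one-way ANOVA on
log2 concentrations with Bonferroni correction over the panel, class-level
log2-ratio summaries and PCA of the scaled profiles.

## Worked example

Run the whole pipeline on the built-in synthetic study (everything is
seeded, so these numbers are reproducible):

```bash
coexnet run-all --outdir results/demo --seed 1
```

or drive the stages individually with the numbered scripts:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_diffexpr.py
python analysis/04_network_modules.py
python analysis/05_module_network.py
python analysis/06_metabolomics.py
```

which prints, for seed 1:

```
TMM factors in [0.719, 1.126] (geometric mean 1)
expression filter: kept 1793 of 2000 genes (mean CPM >= 5 in at least one cell line)
common NB dispersion (Cox-Reid): 0.3441
genotype_all_times: 91 up / 97 down of 1793 genes; planted-effect recall 100.00%
qpcr_noiseless: 2^-ddCq fold change = 4.000 (truth 4)
network: 35341 edges among 1793 genes (|r| >= 0.8, weights |r|^7)
modules at cut 0.10: {'M1': 94, 'M2': 94, ..., 'M9': 58}
planted-module recovery ARI = 0.782
differentially abundant metabolites: 69 raw (59 after Bonferroni over 188 analytes)
```

Reading the output: the expression filter removes the ~10% of genes
simulated below 5 CPM; the genotype contrast pooled over the time course
recovers every planted |log2FC| = 2 effect while calling essentially
nothing outside them; the network recovers the eight planted co-expression
modules (the ninth detected module is the cluster of strongly DE genes,
which genuinely co-express with respect to genotype); and the metabolite
ANOVA flags the planted group shifts with Bonferroni control over the full
panel. The module nodes table written by script 05 carries the per-module
up/down DE fractions and annotations that module-network figures in this
kind of study display.

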