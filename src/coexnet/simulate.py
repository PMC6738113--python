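"""Synthetic data with planted ground truth.

Emulates the study design the pipeline targets: 36 RNA-seq samples
(2 isogenic cell lines x 6 time points after growth-factor stimulation x
3 replicates) with negative-binomial counts, planted co-expression modules
and planted differential-expression effects; a 188-metabolite targeted
panel over 4 cell lines x 6 replicates; and qPCR Cq tables for the
2^-ddCq calculator. Every generator is deterministic under its seed.

Counts follow a log-linear latent-factor model: for gene *g* in sample *s*

    log2 mean CPM = baseline_g + loading_g * factor_{m(g),s} + effect_g(s)

with one standard-normal latent factor per module per sample, and the count
drawn as NB(mean = CPM x lib_size/1e6, dispersion phi). Loadings are
calibrated so that the within-module Pearson correlation of log-CPM hits
the requested target despite the NB sampling noise (the delta-method noise
variance of log counts is phi + 1/mean).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from coexnet.preprocess import CountMatrix

LN2 = math.log(2.0)

#: canonical stimulation time course (minutes) for up to six time points
DEFAULT_TIMEPOINTS = (0, 15, 30, 60, 90, 120)


@dataclass
class SimDesign:
    """Parameters of the RNA-seq count simulation.

    ``module_sizes`` plants that many co-expressed gene blocks;
    ``module_correlation`` is the target within-module Pearson r of log-CPM.
    ``de_fraction`` of genes receive a genotype effect of ``de_log2fc``
    (random sign) in the second cell line from time point index
    ``de_onset_timepoint`` onward (a step change, emulating transcriptional
    waves); ``de_in_module`` instead plants the effect on every gene of one
    module (all upregulated).
    """

    n_genes: int = 2000
    n_cell_lines: int = 2
    n_timepoints: int = 6
    n_reps: int = 3
    module_sizes: tuple[int, ...] = ()
    module_correlation: float = 0.0
    de_fraction: float = 0.0
    de_log2fc: float = 0.0
    de_onset_timepoint: int = 0
    de_in_module: int | None = None
    nb_dispersion: float = 0.1
    lib_size_mean: float = 2.0e7
    lib_size_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cell_lines < 1 or self.n_timepoints < 1 or self.n_reps < 1:
            raise ValueError("design dimensions must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module must have at least 2 genes")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must lie in [0, 1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.de_in_module is not None and not 0 <= self.de_in_module < len(self.module_sizes):
            raise ValueError("de_in_module out of range")


@dataclass
class GroundTruth:
    """Planted structure of one simulated data set."""

    module_of: dict[str, str | None]
    de_genes: dict[str, dict[str, float]]
    lib_sizes: dict[str, int]
    latent_factors: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of": self.module_of,
            "de_genes": self.de_genes,
            "lib_sizes": self.lib_sizes,
        }
        if self.latent_factors is not None:
            payload["latent_factors"] = {
                m: [float(v) for v in row]
                for m, row in self.latent_factors.iterrows()
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _cell_line_names(n: int) -> list[str]:
    base = ["wt", "mt"]
    return base[:n] + [f"cl{i + 1}" for i in range(2, n)]


def _timepoints(n: int) -> list[int]:
    if n <= len(DEFAULT_TIMEPOINTS):
        return list(DEFAULT_TIMEPOINTS[:n])
    extra = [DEFAULT_TIMEPOINTS[-1] + 30 * (i + 1) for i in range(n - len(DEFAULT_TIMEPOINTS))]
    return list(DEFAULT_TIMEPOINTS) + extra


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, GroundTruth]:
    """Draw an NB count matrix with planted modules and DE effects.

    Returns the count matrix (with its sample sheet) and the ground truth:
    gene-to-module map, per-contrast true log2 fold changes (the planted
    genotype effect is recorded under the contrast name ``"genotype"``),
    and the realised library sizes.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    lines = _cell_line_names(design.n_cell_lines)
    times = _timepoints(design.n_timepoints)
    sample_rows = []
    for cl in lines:
        for t in times:
            for r in range(1, design.n_reps + 1):
                sample_rows.append((f"{cl}_t{t:03d}_r{r}", cl, t, r))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "cell_line", "time_min", "replicate"]
    ).set_index("sample")
    n_samples = len(samples)

    # library sizes: log-normal with the requested mean and CV
    sigma2 = math.log1p(design.lib_size_cv**2)
    mu_log = math.log(design.lib_size_mean) - sigma2 / 2.0
    lib_sizes = rng.lognormal(mu_log, math.sqrt(sigma2), size=n_samples)
    lib_sizes = np.round(lib_sizes).astype(np.int64)

    # baselines in log2-CPM: module genes are planted among well-expressed
    # genes (co-expression is only identifiable above the expression filter);
    # background genes span a wide range so the 5-CPM filter has work to do
    n_module_genes = sum(design.module_sizes)
    baseline = np.empty(design.n_genes)
    baseline[:n_module_genes] = rng.uniform(5.0, 10.0, size=n_module_genes)
    baseline[n_module_genes:] = rng.uniform(0.0, 12.0, size=design.n_genes - n_module_genes)

    # module structure: one latent factor per module per (time, replicate),
    # shared across cell lines — biological covariation (stimulation batch,
    # time-course biology) affects the isogenic lines together, so module
    # factors are balanced against any genotype contrast by construction
    module_of: dict[str, str | None] = {g: None for g in genes}
    signal = np.tile(baseline[:, None], (1, n_samples))
    n_conditions = design.n_timepoints * design.n_reps
    factors_tr = rng.standard_normal((len(design.module_sizes), n_conditions))
    factors = np.tile(factors_tr, (1, design.n_cell_lines))
    rho = design.module_correlation
    start = 0
    for m, size in enumerate(design.module_sizes):
        label = f"sim{m + 1}"
        idx = np.arange(start, start + size)
        for i in idx:
            module_of[genes[i]] = label
        if rho > 0:
            mean_count = 2.0 ** baseline[idx] * design.lib_size_mean / 1e6
            noise_var = design.nb_dispersion + 1.0 / mean_count  # natural-log scale
            loading = np.sqrt(rho / (1.0 - rho) * noise_var) / LN2
            # random loading signs keep the library composition balanced, so
            # per-sample CPM normalisation does not absorb the shared factor
            loading *= rng.choice([-1.0, 1.0], size=size)
            signal[idx, :] += loading[:, None] * factors[m][None, :]
        start += size

    # planted DE: step change in the second cell line from the onset time on
    de_true: dict[str, float] = {}
    if design.de_in_module is not None:
        de_idx = np.arange(
            sum(design.module_sizes[: design.de_in_module]),
            sum(design.module_sizes[: design.de_in_module + 1]),
        )
        lfc = np.full(de_idx.size, design.de_log2fc)
    elif design.de_fraction > 0 and design.de_log2fc != 0:
        n_de = int(round(design.de_fraction * design.n_genes))
        de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
        lfc = design.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)
    else:
        de_idx = np.array([], dtype=int)
        lfc = np.array([])
    if de_idx.size:
        if design.n_cell_lines < 2:
            raise ValueError("planted genotype effects need at least 2 cell lines")
        affected = (
            (samples["cell_line"] == lines[1])
            & (samples["time_min"] >= times[design.de_onset_timepoint])
        ).to_numpy()
        signal[np.ix_(de_idx, np.where(affected)[0])] += lfc[:, None]
        de_true = {genes[i]: float(f) for i, f in zip(de_idx, lfc)}

    mean = 2.0**signal * (lib_sizes[None, :] / 1e6)
    if design.nb_dispersion > 0:
        r = 1.0 / design.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        design=samples,
    )
    truth = GroundTruth(
        module_of=module_of,
        de_genes={"genotype": de_true},
        lib_sizes={s: int(n) for s, n in zip(samples.index, lib_sizes)},
        latent_factors=pd.DataFrame(
            factors, index=[f"sim{m + 1}" for m in range(len(design.module_sizes))],
            columns=samples.index,
        ),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# targeted metabolomics panel
# ---------------------------------------------------------------------------

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
_BIOGENIC_AMINES = [
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "Histamine",
    "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro", "PEA", "Putrescine",
    "Sarcosine", "SDMA", "Serotonin", "Spermidine", "Spermine", "Taurine",
    "DOPA", "Dopamine", "total-DMA",
]

# rough cellular-extract concentration scales per compound class (uM)
_CLASS_SCALE = {"AA": 150.0, "BA": 2.0, "AC": 0.3, "PC": 30.0, "SM": 5.0, "H1": 3000.0}


def default_metabolite_panel() -> dict[str, str]:
    """The 188-analyte targeted panel: metabolite -> compound class.

    21 amino acids (AA), 21 biogenic amines (BA), 40 acylcarnitines (AC),
    90 glycerophospholipids (PC), 15 sphingomyelins (SM) and total
    hexoses (H1), mirroring a standard flow-injection/LC-MS kit.
    """
    panel: dict[str, str] = {}
    for m in _AMINO_ACIDS:
        panel[m] = "AA"
    for m in _BIOGENIC_AMINES:
        panel[m] = "BA"
    for i in range(40):
        panel[f"C{i}" if i < 19 else f"C{i - 18}:1-OH"] = "AC"
    carbons = [22, 24, 26, 28, 30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50]
    k = 0
    for c in carbons:
        for d in range(6):
            if k >= 90:
                break
            kind = "aa" if k % 2 == 0 else "ae"
            panel[f"PC {kind} C{c}:{d}"] = "PC"
            k += 1
    for i, (c, d) in enumerate(
        [(16, 0), (16, 1), (18, 0), (18, 1), (20, 2), (22, 3), (24, 0), (24, 1),
         (26, 0), (26, 1), (14, 1), (22, 0), (20, 0), (18, 2), (16, 2)]
    ):
        panel[f"SM C{c}:{d}"] = "SM"
    panel["H1"] = "H1"
    assert len(panel) == 188
    return panel


def simulate_metabolites(
    n_groups: int = 4,
    n_reps: int = 6,
    panel: dict[str, str] | None = None,
    effect_metabolites: set[str] | frozenset[str] = frozenset(),
    effect_log2fc: float = 0.0,
    effect_groups: tuple[str, ...] | None = None,
    noise_log2_sd: float = 0.3,
    seed: int = 0,
):
    """Log-normal metabolite concentrations (uM) over cell-line groups.

    Baseline abundances are drawn per metabolite around its compound-class
    scale; effect metabolites are shifted by ``effect_log2fc`` in the
    designated groups (default: every group except the first, which acts
    as the wild-type reference).
    """
    if n_groups < 2 or n_reps < 2:
        raise ValueError("need at least 2 groups and 2 replicates")
    panel = default_metabolite_panel() if panel is None else dict(panel)
    if not panel:
        raise ValueError("empty metabolite panel")
    # local import: metabolomics consumes what this generator produces
    from coexnet.metabolomics import MetaboliteTable

    rng = np.random.default_rng(seed)
    groups = (["wt", "mt", "parental", "hct"] + [f"grp{i}" for i in range(5, n_groups + 1)])[:n_groups]
    if effect_groups is None:
        effect_groups = tuple(groups[1:])
    unknown = set(effect_groups) - set(groups)
    if unknown:
        raise ValueError(f"unknown effect groups: {sorted(unknown)}")

    mets = list(panel)
    base = np.array(
        [rng.normal(math.log2(_CLASS_SCALE[panel[m]]), 1.5) for m in mets]
    )
    sample_ids = [f"{g}_r{r}" for g in groups for r in range(1, n_reps + 1)]
    group_of = {s: s.rsplit("_r", 1)[0] for s in sample_ids}
    log2_conc = np.tile(base[:, None], (1, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        if group_of[s] in effect_groups:
            for i, m in enumerate(mets):
                if m in effect_metabolites:
                    log2_conc[i, j] += effect_log2fc
    log2_conc += rng.normal(0.0, noise_log2_sd, size=log2_conc.shape)

    table = MetaboliteTable(
        concentrations=pd.DataFrame(2.0**log2_conc, index=mets, columns=sample_ids),
        classes=pd.Series({m: panel[m] for m in mets}),
        groups=pd.Series(group_of),
    )
    truth = GroundTruth(
        module_of={},
        de_genes={"group_effect": {m: effect_log2fc for m in mets if m in effect_metabolites}},
        lib_sizes={},
    )
    return table, truth


def simulate_qpcr(
    true_fold_change: float,
    ref_genes: int = 2,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq table for the 2^-ddCq calculator.

    The target's treated-condition Cq is shifted by -log2(fold change)
    relative to control; reference genes keep constant expression. Gaussian
    Cq noise with ``noise_sd`` cycles is added to every measurement.
    Returns a long table (condition, replicate, gene, role, cq).
    """
    if true_fold_change <= 0:
        raise ValueError("fold change must be positive")
    if ref_genes < 1:
        raise ValueError("need at least one reference gene")
    rng = np.random.default_rng(seed)
    rows = []
    ref_cq = {f"ref{i + 1}": 20.0 + 2.0 * i for i in range(ref_genes)}
    target_cq = {"control": 25.0, "treated": 25.0 - math.log2(true_fold_change)}
    for cond in ("control", "treated"):
        for r in range(1, n_replicates + 1):
            rows.append(
                (cond, r, "target", "target", target_cq[cond] + rng.normal(0, noise_sd) if noise_sd else target_cq[cond])
            )
            for g, cq in ref_cq.items():
                rows.append(
                    (cond, r, g, "reference", cq + rng.normal(0, noise_sd) if noise_sd else cq)
                )
    return pd.DataFrame(rows, columns=["condition", "replicate", "gene", "role", "cq"])


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_simulation(
    cm: CountMatrix, truth: GroundTruth, design: SimDesign, outdir: str | Path
) -> None:
    """Write counts.tsv, samples.tsv, truth.json and provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")
    prov = asdict(design)
    prov["generator"] = "coexnet.simulate.simulate_counts"
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
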