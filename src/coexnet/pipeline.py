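"""Run configuration and end-to-end orchestration.

``run_pipeline`` executes the full analysis in stage order — simulate (when
no counts are supplied) -> TMM + filtering -> NB-GLM differential
expression for every configured contrast -> co-expression network ->
module detection -> module-module network with DE overlays (and GMT
annotation when a collection is given) -> targeted-metabolomics statistics
— writing each stage's TSV outputs before the next stage starts and
finishing with a run manifest. Reruns with the same config and seed produce
byte-identical stage outputs; only manifest timestamps differ.

All randomness flows from the single config seed: the count simulation uses
``seed`` and the metabolite simulation ``seed + 1000``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coexnet import diffexpr, enrichment, metabolomics, modnet, modules, network, preprocess
from coexnet.preprocess import CountMatrix

log = logging.getLogger("coexnet")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or unreadable inputs (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""


@dataclass
class RunConfig:
    """Every knob of the pipeline, defaulting to the published thresholds."""

    outdir: str = "results/run"
    counts: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None
    metabolites: str | None = None
    metabolite_groups: str | None = None

    min_cpm: float = 5.0
    lfc: float = 1.0
    alpha: float = 0.05
    beta: int = 7
    r_cutoff: float = 0.8
    cut_height: float = 0.10
    min_module_size: int = 10
    w_min: float = 0.5
    dissimilarity: str = "correlation"
    prior_count: float = 0.5

    contrasts: list[dict] = field(
        default_factory=lambda: [
            {"name": "genotype_t0", "type": "genotype", "time": 0},
            {"name": "genotype_all", "type": "genotype", "time": None},
        ]
    )

    # synthetic-data design used when no counts are supplied
    simulate: bool = True
    n_genes: int = 2000
    module_sizes: list[int] = field(default_factory=lambda: [100] * 8)
    module_correlation: float = 0.9
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    lib_size_mean: float = 2.0e7
    lib_size_cv: float = 0.2
    simulate_metabolites: bool = True
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.min_cpm >= 0, "min_cpm must be >= 0"),
            (self.lfc >= 0, "lfc must be >= 0"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.beta >= 1, "beta must be >= 1"),
            (0 < self.r_cutoff < 1, "r_cutoff must lie in (0, 1)"),
            (0 <= self.cut_height <= 1, "cut_height must lie in [0, 1]"),
            (self.min_module_size >= 1, "min_module_size must be >= 1"),
            (0 <= self.w_min <= 1, "w_min must lie in [0, 1]"),
            (len(self.contrasts) > 0, "at least one contrast is required"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output path is excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_contrast_fit(
    counts: CountMatrix, spec: dict
) -> tuple[pd.DataFrame, np.ndarray, diffexpr.Contrast, pd.Index]:
    """Design matrix, contrast vector and sample subset for one contrast.

    Supported specs: ``{"type": "genotype", "time": t}`` compares the second
    cell line to the first at one time point (``time: null`` pools every
    time point); ``{"type": "time", "cell_line": cl, "time": t,
    "baseline": t0}`` compares two time points within one cell line.
    """
    design = counts.design
    name = spec.get("name", spec.get("type", "contrast"))
    lines = list(dict.fromkeys(design["cell_line"]))
    if spec.get("type") == "genotype":
        t = spec.get("time", 0)
        if len(lines) < 2:
            raise ConfigError(f"contrast {name!r} needs two cell lines")
        sel = design["time_min"] == t if t is not None else pd.Series(True, index=design.index)
        if not sel.any():
            raise ConfigError(f"contrast {name!r}: no samples at time {t}")
        sub = design[sel]
        x = (sub["cell_line"] == lines[1]).astype(float).to_numpy()
    elif spec.get("type") == "time":
        cl = spec.get("cell_line", lines[0])
        t, t0 = spec["time"], spec.get("baseline", 0)
        sel = (design["cell_line"] == cl) & design["time_min"].isin([t, t0])
        if not sel.any():
            raise ConfigError(f"contrast {name!r}: no matching samples")
        sub = design[sel]
        x = (sub["time_min"] == t).astype(float).to_numpy()
    else:
        raise ConfigError(f"unknown contrast type in {spec!r}")
    X = np.column_stack([np.ones(len(sub)), x])
    return sub, X, diffexpr.Contrast(name=name, coefficients=np.array([0.0, 1.0])), sub.index


def group_design_matrix(design: pd.DataFrame) -> np.ndarray:
    """One-hot cell-line x time-point group design (means parameterisation)."""
    groups = design["cell_line"].astype(str) + ":" + design["time_min"].astype(str)
    levels = list(dict.fromkeys(groups))
    return np.column_stack([(groups == lv).to_numpy(float) for lv in levels])


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    from coexnet import __version__
    from coexnet.simulate import SimDesign, simulate_counts, simulate_metabolites, write_simulation

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "coexnet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    for key, value in sorted(config.to_dict().items()):
        log.info("config %s = %r", key, value)

    # ---- stage: counts ---------------------------------------------------
    truth = None
    if config.counts is not None:
        if config.sample_sheet is None:
            raise InputError("counts given without a sample sheet")
        for p in (config.counts, config.sample_sheet):
            if not Path(p).exists():
                raise InputError(f"input not found: {p}")
        cm = CountMatrix.from_tsv(config.counts, config.sample_sheet)
        manifest["inputs"] = {
            p: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for p in (config.counts, config.sample_sheet)
        }
    elif config.simulate:
        design = SimDesign(
            n_genes=config.n_genes,
            module_sizes=tuple(config.module_sizes),
            module_correlation=config.module_correlation,
            de_fraction=config.de_fraction,
            de_log2fc=config.de_log2fc,
            nb_dispersion=config.nb_dispersion,
            lib_size_mean=config.lib_size_mean,
            lib_size_cv=config.lib_size_cv,
            seed=config.seed,
        )
        cm, truth = simulate_counts(design)
        write_simulation(cm, truth, design, outdir)
        log.info("simulated %d genes x %d samples", *cm.counts.shape)
    else:
        raise InputError("no counts supplied and simulation disabled")
    manifest["stages"]["counts"] = {"genes": cm.counts.shape[0], "samples": cm.counts.shape[1]}

    try:
        # ---- stage: preprocess ------------------------------------------
        factors = preprocess.tmm_factors(cm)
        factors.to_frame().rename_axis("sample").to_csv(outdir / "tmm_factors.tsv", sep="\t")
        filtered = preprocess.filter_low_expression(cm, min_cpm=config.min_cpm)
        filtered.counts.rename_axis("gene").to_csv(outdir / "filtered_counts.tsv", sep="\t")
        expr = preprocess.log_cpm(filtered, factors, prior_count=config.prior_count)
        expr.log2_cpm.rename_axis("gene").to_csv(outdir / "log_cpm.tsv", sep="\t")
        manifest["stages"]["preprocess"] = {
            "genes_after_filter": filtered.counts.shape[0],
            "tmm_factor_range": [float(factors.min()), float(factors.max())],
        }
        log.info("expression filter kept %d genes", filtered.counts.shape[0])
        if filtered.counts.shape[0] < 2:
            warnings.warn("fewer than 2 genes survive filtering; stopping before the network stage")
            manifest["stages"]["network"] = {"stopped": "empty filtered matrix"}
            manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
            _write_json(outdir / "manifest.json", manifest)
            return manifest

        # ---- stage: differential expression -----------------------------
        offsets_all = np.log(filtered.lib_sizes().to_numpy(dtype=float) * factors.to_numpy())
        phi = diffexpr.estimate_dispersion(
            filtered, group_design_matrix(filtered.design), offsets=offsets_all
        )
        log.info("common NB dispersion: %.4g", phi)
        de_tables: dict[str, pd.DataFrame] = {}
        for spec in config.contrasts:
            sub, X, contrast, sample_idx = build_contrast_fit(filtered, spec)
            sub_counts = filtered.counts[sample_idx]
            offs = np.log(
                filtered.lib_sizes().loc[sample_idx].to_numpy(dtype=float)
                * factors.loc[sample_idx].to_numpy()
            )
            res = diffexpr.nb_glm_lrt(sub_counts, X, offs, phi, contrast)
            called = diffexpr.call_de(res, lfc_threshold=config.lfc, alpha=config.alpha)
            called.to_csv(outdir / f"de_{contrast.name}.tsv", sep="\t")
            de_tables[contrast.name] = called
            n_up = int((called["call"] == "up").sum())
            n_down = int((called["call"] == "down").sum())
            log.info("contrast %s: %d up, %d down", contrast.name, n_up, n_down)
            manifest["stages"][f"de_{contrast.name}"] = {"up": n_up, "down": n_down}
        manifest["stages"]["dispersion"] = {"phi": phi}

        # ---- stage: co-expression network -------------------------------
        net_config = network.NetworkConfig(beta=config.beta, r_cutoff=config.r_cutoff)
        rmat = network.pairwise_correlation(expr)
        adjacency = network.soft_power_adjacency(rmat, net_config)
        r2 = network.scale_free_fit(adjacency)
        net = network.threshold_network(rmat, net_config)
        net.to_tsv(outdir / "edges.tsv")
        _write_json(
            outdir / "network_config.json",
            {"beta": net_config.beta, "r_cutoff": net_config.r_cutoff, "signed": net_config.signed},
        )
        manifest["stages"]["network"] = {
            "genes": len(net.nodes),
            "edges": net.n_edges(),
            "scale_free_r2": None if np.isnan(r2) else float(r2),
        }
        log.info("network: %d edges among %d genes (scale-free R2 %.3f)", net.n_edges(), len(net.nodes), r2)

        # ---- stage: modules ---------------------------------------------
        partition = modules.detect_modules(
            net,
            cut_height=config.cut_height,
            min_size=config.min_module_size,
            dissimilarity=config.dissimilarity,
        )
        partition.to_tsv(outdir / "partition.tsv")
        modules.module_summary(partition, net).to_csv(
            outdir / "module_summary.tsv", sep="\t", index=False
        )
        manifest["stages"]["modules"] = {
            "n_modules": len(partition.modules),
            "sizes": modules.module_sizes(partition),
        }
        log.info("detected %d modules", len(partition.modules))

        # ---- stage: module network --------------------------------------
        if partition.modules:
            mnet = modnet.build_module_network(net, partition, w_min=config.w_min)
            mnet = modnet.overlay_de(mnet, partition, de_tables)
            if config.gmt is not None:
                if not Path(config.gmt).exists():
                    raise InputError(f"GMT file not found: {config.gmt}")
                collection = enrichment.read_gmt(config.gmt)
                annotations = enrichment.annotate_modules(
                    partition, collection, alpha=config.alpha
                )
                mnet.nodes["annotation"] = [annotations[m] for m in mnet.nodes.index]
            mnet.to_tsv(outdir / "module_nodes.tsv", outdir / "module_edges.tsv")
            manifest["stages"]["module_network"] = {"edges": len(mnet.edges)}

        # ---- stage: metabolomics ----------------------------------------
        table = None
        if config.metabolites is not None:
            if config.metabolite_groups is None:
                raise InputError("metabolite table given without a sample-group sheet")
            table = read_metabolite_table(config.metabolites, config.metabolite_groups)
        elif config.simulate_metabolites:
            from coexnet.simulate import default_metabolite_panel

            panel = default_metabolite_panel()
            effect_set = set(list(panel)[::3])  # every third analyte shifted
            table, _ = simulate_metabolites(
                effect_metabolites=effect_set,
                effect_log2fc=1.0,
                seed=config.seed + 1000,
            )
            write_metabolite_table(table, outdir / "metabolites.tsv", outdir / "metabolite_groups.tsv")
        if table is not None:
            result = metabolomics.anova_per_metabolite(table)
            result.to_csv(outdir / "metabolite_results.tsv", sep="\t")
            summary = metabolomics.class_fold_change_summary(
                result, reference_group=table.group_names[0], alpha=config.alpha
            )
            summary.to_csv(outdir / "metabolite_class_summary.tsv", sep="\t", index=False)
            scores, var_frac = metabolomics.pca_scores(table)
            scores.rename_axis("sample").to_csv(outdir / "metabolite_pca_scores.tsv", sep="\t")
            manifest["stages"]["metabolomics"] = {
                "n_metabolites": len(result),
                "significant_raw": int((result["p"] < config.alpha).sum()),
                "significant_bonferroni": int((result["bonferroni_p"] < config.alpha).sum()),
                "pc1_variance_fraction": float(var_frac[0]),
            }
            log.info(
                "metabolomics: %d/%d significant after Bonferroni",
                manifest["stages"]["metabolomics"]["significant_bonferroni"],
                len(result),
            )
    except (ConfigError, InputError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        done = ", ".join(manifest["stages"])
        raise StageError(f"pipeline failed after stages [{done}]: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def read_metabolite_table(conc_path, groups_path) -> metabolomics.MetaboliteTable:
    """Read a metabolite TSV (metabolite, class, sample columns) + group sheet."""
    raw = pd.read_csv(conc_path, sep="\t", index_col=0)
    if "class" not in raw.columns:
        raise InputError("metabolite table needs a 'class' column")
    classes = raw["class"]
    conc = raw.drop(columns=["class"]).astype(float)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return metabolomics.MetaboliteTable(concentrations=conc, classes=classes, groups=groups)


def write_metabolite_table(table, conc_path, groups_path) -> None:
    out = table.concentrations.copy()
    out.insert(0, "class", table.classes.loc[out.index])
    out.rename_axis("metabolite").to_csv(conc_path, sep="\t")
    table.groups.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")
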