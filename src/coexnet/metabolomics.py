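"""Differential abundance of a targeted metabolite panel.

Concentrations (uM) are log2-transformed (zeros replaced by half the
smallest positive measurement) and compared across cell-line groups by
one-way fixed-effects ANOVA per metabolite, with Bonferroni correction over
the full panel. Class-level summaries average log2 ratios against a
reference group, and PCA of the scaled log concentrations visualises
group separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.decomposition import PCA

COMPOUND_CLASSES = ("AA", "BA", "AC", "PC", "SM", "H1")


@dataclass
class MetaboliteTable:
    """Metabolite x sample concentrations with class and group labels."""

    concentrations: pd.DataFrame
    classes: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("negative concentrations")
        missing = set(self.concentrations.index) - set(self.classes.index)
        if missing:
            raise ValueError(f"metabolites without class labels: {sorted(missing)[:5]}")
        missing = set(self.concentrations.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        if self.groups.loc[self.concentrations.columns].nunique() < 2:
            raise ValueError("need at least two groups")

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.concentrations.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def log2_matrix(self) -> pd.DataFrame:
        """log2 concentrations; zeros replaced by half the smallest positive value."""
        mat = self.concentrations.to_numpy(dtype=float).copy()
        pos = mat[mat > 0]
        if pos.size == 0:
            raise ValueError("no positive concentrations")
        mat[mat == 0] = pos.min() / 2.0
        return pd.DataFrame(
            np.log2(mat), index=self.concentrations.index, columns=self.concentrations.columns
        )


def anova_per_metabolite(
    table: MetaboliteTable, log_transform: bool = True, reference_group: str | None = None
) -> pd.DataFrame:
    """One-way ANOVA of each metabolite across groups.

    Returns a DataFrame indexed by metabolite with F, p, bonferroni_p,
    ``degenerate`` flag (all observations equal: p set to 1), per-group
    means (raw uM) and log2 ratios of each group mean to the reference
    (default: the first group).
    """
    groups = table.groups.loc[table.concentrations.columns]
    names = table.group_names
    if reference_group is None:
        reference_group = names[0]
    if reference_group not in names:
        raise ValueError(f"unknown reference group {reference_group!r}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least two replicates")

    data = table.log2_matrix() if log_transform else table.concentrations.astype(float)
    cols_of = {g: [s for s in data.columns if groups[s] == g] for g in names}
    rows = []
    for met in data.index:
        arrs = [data.loc[met, cols_of[g]].to_numpy() for g in names]
        pooled = np.concatenate(arrs)
        degenerate = np.allclose(pooled, pooled[0])
        if degenerate:
            stat_f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat_f, p = f_oneway(*arrs)
            if not np.isfinite(p):
                stat_f, p = 0.0, 1.0
                degenerate = True
        raw_means = {
            g: float(table.concentrations.loc[met, cols_of[g]].mean()) for g in names
        }
        ref_mean = raw_means[reference_group]
        ratios = {
            f"log2_ratio_{g}": (
                float(np.log2(raw_means[g] / ref_mean)) if ref_mean > 0 and raw_means[g] > 0 else np.nan
            )
            for g in names
        }
        rows.append(
            {
                "metabolite": met,
                "class": table.classes[met],
                "F": float(stat_f),
                "p": float(p),
                "degenerate": degenerate,
                **{f"mean_{g}": raw_means[g] for g in names},
                **ratios,
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["bonferroni_p"] = bonferroni_adjust(out["p"].to_numpy(), m=len(out))
    return out


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m*p) elementwise."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tested p-values")
    return np.minimum(1.0, m * p)


def pca_scores(
    table: MetaboliteTable, log_transform: bool = True, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on principal components of the metabolite profiles.

    Metabolites are centred (and by default scaled to unit variance, since
    compound classes span orders of magnitude in uM); samples are projected
    onto the orthonormal components. Returns (scores, explained variance
    fractions).
    """
    data = (table.log2_matrix() if log_transform else table.concentrations).to_numpy().T
    if np.allclose(data.std(axis=0), 0):
        raise ValueError("constant matrix: PCA undefined")
    data = data - data.mean(axis=0)
    if scale:
        sd = data.std(axis=0, ddof=1)
        data = data[:, sd > 0] / sd[sd > 0]
    n_comp = min(data.shape) - (1 if data.shape[0] <= data.shape[1] else 0)
    n_comp = max(min(n_comp, data.shape[0] - 1, data.shape[1]), 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(data)
    frame = pd.DataFrame(
        scores,
        index=table.concentrations.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    frame["group"] = table.groups.loc[frame.index]
    return frame, pca.explained_variance_ratio_


def class_fold_change_summary(
    result: pd.DataFrame,
    reference_group: str,
    alpha: float = 0.05,
    use_bonferroni: bool = True,
) -> pd.DataFrame:
    """Mean log2 ratio vs the reference per compound class and group.

    Rows are (class, group); ``mean_log2_ratio`` averages all member
    metabolites, ``mean_log2_ratio_significant`` only those passing the
    (Bonferroni by default) significance threshold — NaN when a class has
    no significant member.
    """
    ratio_cols = [c for c in result.columns if c.startswith("log2_ratio_")]
    groups = [c.removeprefix("log2_ratio_") for c in ratio_cols]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in results")
    pcol = "bonferroni_p" if use_bonferroni else "p"
    sig = result[pcol] < alpha
    rows = []
    for cls, sub in result.groupby("class", sort=True):
        for g, col in zip(groups, ratio_cols):
            if g == reference_group:
                continue
            sub_sig = sub[sig.loc[sub.index]]
            rows.append(
                {
                    "class": cls,
                    "group": g,
                    "n_metabolites": len(sub),
                    "n_significant": len(sub_sig),
                    "mean_log2_ratio": float(sub[col].mean()),
                    "mean_log2_ratio_significant": (
                        float(sub_sig[col].mean()) if len(sub_sig) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
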