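"""Library normalisation and expression filtering.

Between-sample normalisation uses the trimmed mean of M-values (TMM):
for each sample against a reference, gene-wise log2 ratios of
library-size-scaled counts (M-values) are doubly trimmed — 30% on the
M-values and 5% on the average log abundances (A-values) — and averaged
with inverse asymptotic-variance weights; the exponentiated mean is the
sample's scaling factor, renormalised so factors have geometric mean 1.

Expression filtering retains a gene if its mean CPM in at least one
cell line reaches ``min_cpm`` (default 5 reads per million).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample design sheet.

    ``design`` is indexed by sample id with columns ``cell_line``,
    ``time_min`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        # keep the design aligned with the count columns
        self.design = self.design.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        self.design.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts=counts, design=design)


@dataclass
class NormalizedExpression:
    """log2-CPM matrix with the TMM factors that produced it."""

    log2_cpm: pd.DataFrame
    tmm_factors: pd.Series
    effective_lib_sizes: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2_cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2_cpm.columns)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # asymptotic (delta-method) variance of M
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """TMM normalisation factors, geometric mean 1.

    The reference defaults to the sample whose upper-quartile CPM is
    closest to the mean upper quartile across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    zero = np.where(libs == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero sample(s): {[counts.sample_ids[i] for i in zero]}"
        )
    if counts.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if ref_sample is None:
        uq = np.array([np.quantile(mat[:, j] / libs[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref_sample)
    log_f = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx])
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0**log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def cpm(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million, optionally on TMM-effective library sizes."""
    libs = counts.lib_sizes().astype(float)
    if factors is not None:
        libs = libs * factors
    return counts.counts / libs * 1e6


def filter_low_expression(
    counts: CountMatrix,
    min_cpm: float = 5.0,
    grouping: str = "cell_line",
    factors: pd.Series | None = None,
) -> CountMatrix:
    """Keep genes whose mean CPM reaches ``min_cpm`` in >=1 sample group.

    Group means are taken over raw-library CPM by default (pass TMM
    ``factors`` to use effective library sizes instead). Gene order is
    preserved; an empty result raises a warning, not an error.
    """
    if grouping not in counts.design.columns:
        raise ValueError(f"design has no column {grouping!r}")
    c = cpm(counts, factors)
    group_means = c.T.groupby(counts.design[grouping]).mean().T
    keep = (group_means >= min_cpm).any(axis=1)
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(counts=counts.counts.loc[keep], design=counts.design)


def log_cpm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> NormalizedExpression:
    """log2 counts-per-million on TMM-effective library sizes.

    log2_cpm = log2((count + prior) / (effective lib size + 2*prior) * 1e6).
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.sample_ids)
    if (factors <= 0).any():
        raise ValueError("normalisation factors must be positive")
    eff = counts.lib_sizes().astype(float) * factors.loc[counts.sample_ids]
    mat = np.log2(
        (counts.counts.to_numpy(dtype=float) + prior_count)
        / (eff.to_numpy() + 2.0 * prior_count)[None, :]
        * 1e6
    )
    return NormalizedExpression(
        log2_cpm=pd.DataFrame(mat, index=counts.gene_ids, columns=counts.sample_ids),
        tmm_factors=factors.loc[counts.sample_ids],
        effective_lib_sizes=eff,
    )
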