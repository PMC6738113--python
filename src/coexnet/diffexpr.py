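"""Negative-binomial GLM differential expression and qPCR quantification.

Per-gene counts are modelled as NB(mean, phi) with a log link and
log-library-size offsets. A single common dispersion phi is estimated by
maximising the Cox-Reid adjusted profile likelihood summed over genes
(bounded 1-D search on log phi); contrasts are tested with a
likelihood-ratio test against the chi-square(1) reference. Genes are called
differentially expressed when |log2FC| > 1 and the Benjamini-Hochberg
adjusted p-value is < 0.05 (both strict).

The IRLS fitter is vectorised across genes: each iteration solves all
per-gene weighted least-squares systems as one stacked batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import gammaln
from scipy.stats import chi2

LN2 = math.log(2.0)

_MAX_ITER = 50
_DEV_TOL = 1e-8
_ETA_CLIP = 30.0


@dataclass
class Contrast:
    """A named linear contrast over design-matrix coefficients."""

    name: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not self.coefficients.any():
            raise ValueError("contrast vector is all zero")


def _as_matrix(counts) -> tuple[np.ndarray, list[str]]:
    """Accept a CountMatrix, DataFrame or ndarray of gene x sample counts."""
    if hasattr(counts, "counts"):
        return counts.counts.to_numpy(dtype=float), list(counts.counts.index)
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene residual deviance of the NB (or Poisson when phi=0) model."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi > 0:
        r = 1.0 / phi
        term2 = (y + r) * np.log((y + r) / (mu + r))
        unit = 2.0 * (term1 - term2)
    else:
        unit = 2.0 * (term1 - (y - mu))
    return unit.sum(axis=-1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    max_iter: int = _MAX_ITER,
    tol: float = _DEV_TOL,
):
    """Fit NB log-link GLMs to every gene at once by IRLS.

    Parameters
    ----------
    y : (G, N) counts, X : (N, p) design, offset : (N,) or (G, N) log
    effective library sizes, phi : common NB dispersion (0 = Poisson).

    Returns ``(beta (G,p), mu (G,N), deviance (G,), converged (G,))``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    G, N = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, N))

    # initialise from an unweighted LS fit to shifted log counts
    pinv = np.linalg.pinv(X)
    beta = (np.log(y + 0.5) - offset) @ pinv.T

    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    mu = np.empty_like(y)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = eta - offset + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
        b = np.einsum("ni,gn->gi", X, w * z, optimize=True)
        A[:, np.arange(p), np.arange(p)] += 1e-10  # guard near-singular systems
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        active = ~converged
        beta[active] = beta_new[active]
        eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = nb_deviance(y, mu, phi)
        converged = converged | (np.abs(dev - dev_new) < tol * (np.abs(dev_new) + 1.0))
        dev = dev_new
        if converged.all():
            break
    return beta, mu, dev, converged


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB2 log-likelihood (Poisson at phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    if phi > 0:
        r = 1.0 / phi
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    else:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    return ll.sum(axis=-1)


def _cox_reid_apl(y, X, offset, phi) -> float:
    """Cox-Reid adjusted profile log-likelihood, summed over genes."""
    beta, mu, _, _ = fit_nb_glm(y, X, offset, phi)
    ll = nb_loglik(y, mu, phi)
    w = mu / (1.0 + phi * mu)
    info = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
    sign, logdet = np.linalg.slogdet(info)
    logdet = np.where(sign > 0, logdet, np.inf)
    return float(np.sum(ll - 0.5 * logdet))


def estimate_dispersion(
    counts,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    bounds: tuple[float, float] = (1e-8, 10.0),
) -> float:
    """Common NB dispersion maximising the Cox-Reid APL over all genes."""
    y, _ = _as_matrix(counts)
    X = np.asarray(design, dtype=float)
    if y.shape[1] - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom")
    if offsets is None:
        offsets = np.log(y.sum(axis=0))
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    res = optimize.minimize_scalar(
        lambda lp: -_cox_reid_apl(y, X, offsets, math.exp(lp)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    phi = math.exp(res.x)
    # the bounded optimiser never lands exactly on the edge; snap to it
    if res.x - lo < 1e-2 and -res.fun <= _cox_reid_apl(y, X, offsets, bounds[0]) + 1e-6:
        phi = bounds[0]
    return phi


def nb_glm_lrt(
    counts,
    design: np.ndarray,
    offsets: np.ndarray,
    phi: float,
    contrast: Contrast,
) -> pd.DataFrame:
    """Likelihood-ratio test of one contrast for every gene.

    The full model is fitted on the design as given; the null model on the
    design projected onto the orthocomplement of the contrast, so the test
    has one degree of freedom. Returns a DataFrame indexed by gene with
    ``log2FC`` (the contrast applied to the fitted coefficients, in log2
    units), ``p`` and a ``converged`` flag; non-converged genes are
    conservatively assigned p = 1.
    """
    y, genes = _as_matrix(counts)
    X = np.asarray(design, dtype=float)
    c = contrast.coefficients
    if c.shape[0] != X.shape[1]:
        raise ValueError("contrast length does not match design columns")
    null_basis = linalg.null_space(c[None, :])
    X0 = X @ null_basis

    beta, _, dev_full, conv_full = fit_nb_glm(y, X, offsets, phi)
    _, _, dev_null, conv_null = fit_nb_glm(y, X0, offsets, phi)
    stat = np.maximum(dev_null - dev_full, 0.0)
    pvals = chi2.sf(stat, df=1)
    log2fc = (beta @ c) / LN2
    ok = conv_full & conv_null
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} gene(s) did not converge; assigned p=1",
            stacklevel=2,
        )
        pvals = np.where(ok, pvals, 1.0)
    return pd.DataFrame(
        {"log2FC": log2fc, "p": pvals, "converged": ok}, index=genes
    ).rename_axis("gene")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaNs are propagated (with a warning) and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn("NaN p-values propagated through BH adjustment", stacklevel=2)
    q = p[~nan_mask]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[~nan_mask] = vals
    return out


def call_de(
    results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and up/down/ns calls.

    A gene is ``up`` iff log2FC > lfc_threshold and FDR < alpha (both
    strict), ``down`` for log2FC < -lfc_threshold, otherwise ``ns``.
    """
    out = results.copy()
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    sig = out["fdr"] < alpha
    out["call"] = np.where(
        sig & (out["log2FC"] > lfc_threshold),
        "up",
        np.where(sig & (out["log2FC"] < -lfc_threshold), "down", "ns"),
    )
    return out


def ddcq_fold_change(cq: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the 2^-ddCq method.

    ``cq`` is a long table with columns condition (control/treated),
    replicate, gene, role (target/reference) and cq. Per condition and
    replicate, dCq = Cq_target - mean(Cq_references); ddCq per treated
    replicate is its dCq minus the mean control dCq; fold change = 2^-ddCq.

    Returns ``(per_replicate, summary)`` DataFrames, one row per target
    gene in the summary.
    """
    required = {"condition", "replicate", "gene", "role", "cq"}
    if not required.issubset(cq.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    if not np.isfinite(cq["cq"]).all():
        raise ValueError("non-finite Cq values")
    conditions = set(cq["condition"])
    if not {"control", "treated"}.issubset(conditions):
        raise ValueError("both control and treated conditions are required")
    refs = cq[cq["role"] == "reference"]
    for cond in ("control", "treated"):
        if refs[refs["condition"] == cond].empty:
            raise ValueError(f"no reference genes in condition {cond!r}")

    ref_means = (
        refs.groupby(["condition", "replicate"])["cq"].mean().rename("ref_cq")
    )
    targets = cq[cq["role"] == "target"].copy()
    if targets.empty:
        raise ValueError("no target genes in Cq table")
    targets = targets.join(ref_means, on=["condition", "replicate"])
    targets["dcq"] = targets["cq"] - targets["ref_cq"]

    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        control_dcq = sub.loc[sub["condition"] == "control", "dcq"].mean()
        treated = sub[sub["condition"] == "treated"]
        for _, row in treated.iterrows():
            ddcq = row["dcq"] - control_dcq
            rows.append((gene, int(row["replicate"]), ddcq, 2.0**-ddcq))
    per_rep = pd.DataFrame(rows, columns=["gene", "replicate", "ddcq", "fold_change"])
    summary = (
        per_rep.groupby("gene")
        .agg(ddcq_mean=("ddcq", "mean"), n_replicates=("replicate", "count"))
        .reset_index()
    )
    summary["fold_change"] = 2.0 ** -summary["ddcq_mean"]
    return per_rep, summary
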