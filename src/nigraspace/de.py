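"""Negative-binomial Wald differential expression between ROI groups.

A deliberately transparent NB-GLM pipeline: median-of-ratios size factors,
method-of-moments gene-wise dispersions shrunk toward a mean–dispersion
trend, and a log-link NB GLM per gene (intercept + group contrast + optional
unwanted-variation covariates) fitted by iteratively reweighted least
squares, vectorized across genes. The Wald statistic is beta/se with a
two-sided normal p-value and Benjamini–Hochberg adjustment. There is no
Cox–Reid adjustment, fold-change shrinkage, outlier replacement, or
independent filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .normalize import UnwantedFactors

LN2 = np.log(2.0)
PRIOR_DF = 6.0  # empirical-Bayes prior weight of the mean-dispersion trend
MAX_ITER = 60
TOL = 1e-8

DE_COLUMNS = [
    "gene", "baseMean", "log2FC", "se", "wald", "p", "padj", "direction", "converged",
]


@dataclass
class DesignSpec:
    """One two-group contrast, optionally within a quadrant stratum.

    ``contrast`` is (test group, reference group); ``covariates`` are ROI × k
    unwanted-variation loadings entering the GLM as nuisance terms.
    """

    contrast: tuple[str, str]
    covariates: pd.DataFrame | None = None
    stratum: str | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.contrast) != 2:
            raise ValueError("contrast must be (test, reference)")
        if self.contrast[0] == self.contrast[1]:
            warnings.warn("contrast of a group with itself; expect no signal")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if isinstance(self.covariates, UnwantedFactors):
            self.covariates = self.covariates.loadings
        if self.covariates is not None and self.covariates.shape[1] == 0:
            self.covariates = None


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any ROI are excluded from the reference
    geometric means; if no gene is expressed everywhere, falls back to
    upper-quartile ratios with a warning.
    """
    X = counts.counts.to_numpy(dtype=float)
    if not X.any():
        raise ValueError("all-zero count matrix")
    usable = (X > 0).all(axis=1)
    if usable.any():
        logX = np.log(X[usable])
        log_geomean = logX.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logX - log_geomean, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all ROIs; falling back to upper-quartile size factors"
        )
        uq = np.array(
            [np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan for col in X.T]
        )
        if np.isnan(uq).any():
            raise ValueError("some ROIs have no nonzero counts")
        factors = uq
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.rois, name="size_factor")


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit the parametric trend a1 + a0/mean on genes with positive raw
    dispersion; fall back to the median when too few genes inform the fit."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 10:
        fallback = float(np.median(disp[ok])) if ok.any() else 0.0
        return np.full_like(mean, max(fallback, 0.0))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(A, disp[ok], rcond=None)
    a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a1 + a0 / np.maximum(mean, 1e-8)
    return trend


def estimate_dispersions(
    counts: CountMatrix,
    factors: pd.Series,
    design_cells: pd.Series,
) -> pd.Series:
    """Gene-wise NB dispersions (variance = mu + alpha * mu^2).

    Method-of-moments within each design cell on size-factor-scaled counts,
    pooled across cells weighted by residual df, then shrunk toward the
    fitted mean–dispersion trend with gene weight proportional to residual
    df against a fixed prior df. Genes with zero variance in every cell are
    degenerate and get dispersion 0.
    """
    if counts.shape[1] < 3:
        raise ValueError("need ≥ 3 ROIs to estimate dispersions")
    sf = factors.reindex(counts.rois).to_numpy()
    Y = counts.counts.to_numpy(dtype=float) / sf[None, :]
    cells = design_cells.reindex(counts.rois).to_numpy()

    n_genes = Y.shape[0]
    num = np.zeros(n_genes)
    weight = 0.0
    grand_mean = Y.mean(axis=1)
    any_var = np.zeros(n_genes, dtype=bool)
    for cell in dict.fromkeys(cells):
        idx = cells == cell
        n_c = int(idx.sum())
        if n_c < 2:
            continue
        mu_c = Y[:, idx].mean(axis=1)
        var_c = Y[:, idx].var(axis=1, ddof=1)
        any_var |= var_c > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = np.where(mu_c > 0, (var_c - mu_c) / np.maximum(mu_c, 1e-12) ** 2, 0.0)
        num += (n_c - 1) * np.clip(a_c, 0.0, None)
        weight += n_c - 1
    if weight == 0:
        raise ValueError("no design cell has ≥ 2 ROIs")
    raw = num / weight

    trend = _dispersion_trend(grand_mean, raw)
    df_resid = counts.shape[1] - len(dict.fromkeys(cells))
    shrunk = (df_resid * raw + PRIOR_DF * trend) / (df_resid + PRIOR_DF)

    degenerate = ~any_var
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) with constant counts: dispersion set to 0")
        shrunk[degenerate] = 0.0
    return pd.Series(shrunk, index=counts.genes, name="dispersion")


def _irls_nb(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene NB IRLS. Returns (beta, se, converged)."""
    n_genes, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((n_genes, p))
    base = np.maximum((Y * np.exp(-offset)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(base)
    converged = np.zeros(n_genes, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    A = np.empty((n_genes, p, p))
    for _ in range(MAX_ITER):
        eta = beta @ X.T + offset[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A[:] = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True) + ridge
        b = np.einsum("ni,gn,gn->gi", X, w, z, optimize=True)
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.einsum("gij,gj->gi", np.linalg.pinv(A), b)
        bad = ~np.isfinite(new).all(axis=1)
        new[bad] = beta[bad]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged |= step < TOL
        if converged.all():
            break
    eta = beta @ X.T + offset[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha[:, None] * mu)
    A[:] = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True) + ridge
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(A)
        se = np.sqrt(np.maximum(np.einsum("gii->gi", cov), 0.0))
    return beta, se, converged


def nb_wald_test(
    counts: CountMatrix,
    meta: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series | None,
    design: DesignSpec,
) -> pd.DataFrame:
    """Per-gene NB Wald test for ``design.contrast`` (test vs reference).

    The GLM has log link with log-size-factor offsets and columns
    [intercept, group, covariates…]. log2FC/se are reported on the log2
    scale; p is two-sided normal on beta/se; padj is BH across tested genes.
    Non-convergent genes are flagged with p set to 1.
    """
    test, ref = design.contrast
    m = meta.set_index("roi_id").loc[counts.rois]
    mask = m["group"].isin([test, ref])
    if design.stratum is not None:
        mask &= m["quadrant"] == design.stratum
    rois = list(m.index[mask])
    groups = m.loc[rois, "group"]
    n_test, n_ref = int((groups == test).sum()), int((groups == ref).sum())
    if test == ref:
        n_test = n_ref = int(len(rois))
    if n_test < 2 or n_ref < 2:
        raise ValueError(
            f"contrast {test} vs {ref}"
            + (f" in quadrant {design.stratum}" if design.stratum else "")
            + f" needs ≥ 2 ROIs per group (got {n_test}, {n_ref})"
        )

    sub = counts.subset_rois(rois)
    Y = sub.counts.to_numpy(dtype=float)
    sf = factors.reindex(rois).to_numpy()
    offset = np.log(sf)

    cols = [np.ones(len(rois)), (groups == test).to_numpy(dtype=float)]
    if test == ref:
        cols[1] = np.zeros(len(rois))  # degenerate self-contrast: no group column signal
    if design.covariates is not None:
        cov = design.covariates.reindex(rois)
        if cov.isna().any().any():
            raise ValueError("covariates missing for some ROIs in the contrast")
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    X = np.column_stack(cols)

    if dispersions is None:
        cells = pd.Series(groups.to_numpy(), index=rois)
        dispersions = estimate_dispersions(sub, factors.reindex(rois), cells)
    alpha_g = dispersions.reindex(sub.genes).fillna(0.0).to_numpy()

    base_mean = (Y / sf[None, :]).mean(axis=1)
    testable = base_mean > 0

    beta = np.zeros((len(sub.genes), X.shape[1]))
    se = np.full((len(sub.genes), X.shape[1]), np.nan)
    conv = np.zeros(len(sub.genes), dtype=bool)
    if testable.any():
        beta_t, se_t, conv_t = _irls_nb(Y[testable], X, offset, alpha_g[testable])
        beta[testable] = beta_t
        se[testable] = se_t
        conv[testable] = conv_t
    n_fail = int(testable.sum() - conv[testable].sum())
    if n_fail:
        warnings.warn(f"{n_fail} gene(s) did not converge; p set to 1")

    log2fc = beta[:, 1] / LN2
    se2 = se[:, 1] / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se[:, 1] > 0, beta[:, 1] / se[:, 1], 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvals[~conv] = 1.0
    pvals[~testable] = 1.0
    log2fc[~testable] = 0.0

    padj = np.ones_like(pvals)
    tested = testable & conv
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])

    direction = np.where(
        (padj < design.alpha) & (log2fc > 0),
        "up",
        np.where((padj < design.alpha) & (log2fc < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": sub.genes,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "se": se2,
            "wald": wald,
            "p": pvals,
            "padj": padj,
            "direction": direction,
            "converged": conv,
        },
        columns=DE_COLUMNS,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(de: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """(upregulated, downregulated) gene lists at the padj threshold."""
    sig = de[de["padj"] < alpha]
    up = sorted(sig.loc[sig["log2FC"] > 0, "gene"])
    down = sorted(sig.loc[sig["log2FC"] < 0, "gene"])
    return up, down
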