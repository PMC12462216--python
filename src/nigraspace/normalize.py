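"""ROI-level QC filtering, between-lane normalization, and removal of
unwanted variation (RUV) from control genes.

The normalization follows the between-lane family: upper-quartile scaling
(default), full-quantile normalization, or median scaling. RUV is the
control-gene factor-analysis variant: unwanted factors are the leading
singular directions of the row-centered log-expression of control genes,
returned as ROI-level covariates for the downstream count model rather than
used to overwrite the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

DEFAULT_MIN_NUCLEI = 90


@dataclass
class NormalizedMatrix:
    """Normalized expression values (same shape as the input counts) plus the
    per-ROI scale factors that were applied (1.0 for full-quantile)."""

    values: pd.DataFrame
    method: str
    scale: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def rois(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class UnwantedFactors:
    """ROI × k loadings of estimated unwanted-variation factors.

    Columns are mean-centered; k = 0 yields an empty loading matrix.
    """

    k: int
    loadings: pd.DataFrame

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be ≥ 0")
        if self.loadings.shape[1] != self.k:
            raise ValueError("loadings must have k columns")
        if self.k and not np.all(np.isfinite(self.loadings.to_numpy())):
            raise ValueError("loadings must be finite")


def filter_rois(
    counts: CountMatrix,
    meta: pd.DataFrame,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop ROIs whose nuclei count does not exceed ``min_nuclei``.

    Genes are never filtered. Raises if no ROI survives.
    """
    absent = set(counts.rois) - set(meta["roi_id"])
    if absent:
        raise ValueError(f"metadata does not cover ROIs: {sorted(absent)}")
    nuc = meta.set_index("roi_id")["nuclei_count"]
    keep = [r for r in counts.rois if nuc[r] > min_nuclei]
    if not keep:
        raise ValueError(f"no ROI has nuclei count > {min_nuclei}")
    if len(keep) < 2:
        raise ValueError("fewer than 2 ROIs survive the nuclei filter")
    meta_kept = meta[meta["roi_id"].isin(keep)].reset_index(drop=True)
    return counts.subset_rois(keep), meta_kept


def _nonzero_quantile(col: np.ndarray, q: float, roi: str) -> float:
    nz = col[col > 0]
    if nz.size == 0:
        raise ValueError(f"ROI {roi!r} has no nonzero counts; cannot normalize")
    val = float(np.percentile(nz, q))
    if val <= 0:
        raise ValueError(f"ROI {roi!r} has zero normalization quantile")
    return val


def between_lane_normalize(
    counts: CountMatrix | NormalizedMatrix | pd.DataFrame,
    which: str = "upper",
) -> NormalizedMatrix:
    """Between-lane normalization of a genes × ROIs matrix.

    ``upper``: scale each column so its nonzero upper quartile equals the
    geometric mean of per-column upper quartiles (idempotent).
    ``full``: full-quantile — each column's sorted values are replaced by the
    row-wise mean of sorted columns; ties share the mean of their positions.
    ``median``: as ``upper`` with the nonzero median.
    """
    if isinstance(counts, CountMatrix):
        df = counts.counts.astype(float)
    elif isinstance(counts, NormalizedMatrix):
        df = counts.values.astype(float)
    else:
        df = pd.DataFrame(counts).astype(float)

    if which in ("upper", "median"):
        q = 75.0 if which == "upper" else 50.0
        quant = np.array([_nonzero_quantile(df[r].to_numpy(), q, r) for r in df.columns])
        target = float(np.exp(np.mean(np.log(quant))))
        scale = target / quant
        values = df * scale
        return NormalizedMatrix(values, which, pd.Series(scale, index=df.columns))
    if which == "full":
        X = df.to_numpy()
        order = np.argsort(X, axis=0, kind="mergesort")
        sorted_X = np.take_along_axis(X, order, axis=0)
        mean_sorted = sorted_X.mean(axis=1)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            col = np.empty(X.shape[0])
            col[order[:, j]] = mean_sorted
            # ties within the original column share the mean of their positions
            s = pd.Series(col).groupby(X[:, j]).transform("mean")
            out[:, j] = s.to_numpy()
        values = pd.DataFrame(out, index=df.index, columns=df.columns)
        return NormalizedMatrix(values, which, pd.Series(1.0, index=df.columns))
    raise ValueError(f"unknown normalization method {which!r}")


def select_empirical_controls(
    counts: CountMatrix,
    meta: pd.DataFrame,
    n_controls: int,
) -> list[str]:
    """Empirical control genes for RUV: the ``n_controls`` genes that are
    least group-associated in a first-pass differential-expression test and
    have above-median mean expression.

    With more than two groups the first-pass p-value per gene is the minimum
    Wald p over every (group vs reference) contrast, the reference being the
    first group in metadata order.
    """
    from . import de as de_mod  # deferred: avoids import at module load in CLI paths

    if n_controls == 0:
        return []
    if n_controls >= len(counts.genes):
        raise ValueError("n_controls must be < number of genes")

    groups = list(dict.fromkeys(meta["group"]))
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups for the first-pass test")
    reference = groups[0]
    sf = de_mod.size_factors(counts)
    min_p = pd.Series(1.0, index=counts.genes)
    for test in groups[1:]:
        design = de_mod.DesignSpec(contrast=(test, reference))
        res = de_mod.nb_wald_test(counts, meta, sf, None, design)
        min_p = np.minimum(min_p, res.set_index("gene")["p"].reindex(min_p.index))

    mean_expr = (counts.counts / sf).mean(axis=1)
    eligible = mean_expr[mean_expr > mean_expr.median()].index
    # largest first-pass p first; stable sort so gene order breaks ties
    ranked = min_p.loc[eligible].sort_values(ascending=False, kind="mergesort")
    chosen = list(ranked.index[:n_controls])
    if len(chosen) < n_controls:
        warnings.warn(
            "fewer above-median-expression genes than requested controls; "
            "padding from the remaining genes"
        )
        rest = min_p.drop(index=chosen).sort_values(ascending=False, kind="mergesort")
        chosen += list(rest.index[: n_controls - len(chosen)])
    return chosen


def estimate_ruv_factors(
    norm: NormalizedMatrix,
    controls: list[str],
    k: int,
) -> UnwantedFactors:
    """Estimate k unwanted-variation factors from control genes.

    SVD of the row-centered log(norm + 1) control-gene submatrix; the ROI-side
    singular vectors (scaled by their singular values) are the loadings,
    mean-centered per factor.
    """
    rois = norm.rois
    if k == 0:
        return UnwantedFactors(0, pd.DataFrame(index=rois))
    missing = set(controls) - set(norm.genes)
    if missing:
        raise ValueError(f"control genes absent from matrix: {sorted(missing)}")
    max_k = min(len(controls), len(rois) - 1)
    if k > max_k:
        raise ValueError(f"k={k} exceeds feasible rank {max_k}")
    X = np.log1p(norm.values.loc[list(controls)].to_numpy())
    X = X - X.mean(axis=1, keepdims=True)  # center each control gene across ROIs
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    load = vt[:k].T * s[:k]
    load = load - load.mean(axis=0, keepdims=True)
    cols = [f"W{i + 1}" for i in range(k)]
    return UnwantedFactors(k, pd.DataFrame(load, index=rois, columns=cols))
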