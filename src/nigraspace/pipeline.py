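"""End-to-end orchestration: QC → normalization → RUV → differential
expression → enrichment → network propagation, with quadrant-stratified
contrasts, DEG-overlap summaries and a reproducible run manifest.

All intermediate artifacts are plain files (TSV/CSV/JSON), so every stage's
output is a valid input for the next stage's readers and runs are
stage-restartable and byte-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import DesignSpec, estimate_dispersions, nb_wald_test, significant_genes, size_factors
from .enrich import fisher_enrich, venn_overlap
from .io import (
    GROUPS,
    QUADRANTS,
    CountMatrix,
    read_count_matrix,
    read_edge_list,
    read_gmt,
    read_metadata,
    validate_metadata,
)
from .netprop import PropagationConfig, propagate_degs, select_key_genes
from .normalize import (
    DEFAULT_MIN_NUCLEI,
    between_lane_normalize,
    estimate_ruv_factors,
    filter_rois,
    select_empirical_controls,
)

logger = logging.getLogger("nigraspace")


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML."""

    counts: str
    meta: str
    network: str
    gene_sets: dict[str, str] = field(default_factory=dict)  # collection name -> GMT path
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("MSAP", "HC"), ("PD", "HC")])
    groups: tuple[str, ...] = GROUPS
    quadrants: tuple[str, ...] = QUADRANTS
    quadrant_mode: bool = False
    min_nuclei: int = DEFAULT_MIN_NUCLEI
    norm_method: str = "upper"
    ruv_k: int = 1
    n_controls: int = 500
    alpha: float = 0.05
    restart_rate: float = 0.7
    prob_quantile: float = 0.9
    bc_quantile: float = 0.9
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for test, ref in self.contrasts:
            if test not in self.groups or ref not in self.groups:
                raise ValueError(f"contrast ({test}, {ref}) references undeclared groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        for key in ("groups", "quadrants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_inputs(cfg: RunConfig):
    counts = read_count_matrix(cfg.counts)
    meta = read_metadata(cfg.meta, groups=cfg.groups, quadrants=cfg.quadrants)
    validate_metadata(meta, counts, groups=cfg.groups, quadrants=cfg.quadrants)
    network = read_edge_list(cfg.network)
    collections = {name: read_gmt(path) for name, path in cfg.gene_sets.items()}
    return counts, meta, network, collections


def _prepare(cfg: RunConfig, counts: CountMatrix, meta: pd.DataFrame):
    """Shared upstream stages: ROI filter, normalization, controls, RUV."""
    counts, meta = filter_rois(counts, meta, cfg.min_nuclei)
    norm = between_lane_normalize(counts, cfg.norm_method)
    controls = select_empirical_controls(counts, meta, cfg.n_controls) if cfg.ruv_k else []
    k = min(cfg.ruv_k, len(controls)) if controls else 0
    ruv = estimate_ruv_factors(norm, controls, k)
    sf = size_factors(counts)
    return counts, meta, norm, ruv, sf


def run_contrast(
    cfg: RunConfig,
    contrast: tuple[str, str],
    prepared=None,
    network=None,
    collections=None,
    outdir: Path | None = None,
) -> dict:
    """Execute one contrast end-to-end and write its tables.

    Returns a manifest fragment with row counts per stage.
    """
    t0 = time.perf_counter()
    if prepared is None:
        counts0, meta0, network, collections = _load_inputs(cfg)
        prepared = _prepare(cfg, counts0, meta0)
    counts, meta, norm, ruv, sf = prepared
    test, ref = contrast
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{test}_vs_{ref}"
    entry: dict = {"contrast": list(contrast)}

    design = DesignSpec(
        contrast=contrast,
        covariates=ruv.loadings if ruv.k else None,
        alpha=cfg.alpha,
    )
    cells = pd.Series(meta["group"].to_numpy(), index=meta["roi_id"])
    disp = estimate_dispersions(counts, sf, cells)
    de = nb_wald_test(counts, meta, sf, disp, design)
    de_path = outdir / f"de_{tag}.tsv"
    de.to_csv(de_path, sep="\t", index=False)
    up, down = significant_genes(de, cfg.alpha)
    entry["de_rows"] = len(de)
    entry["n_up"], entry["n_down"] = len(up), len(down)
    logger.info("%s: %d up, %d down DEGs", tag, len(up), len(down))

    if not up and not down:
        logger.info("%s: no significant DEGs; enrichment and propagation skipped", tag)
        entry["skipped"] = "no significant DEGs"
        return entry

    universe = counts.genes
    entry["enrichment"] = {}
    for name, coll in (collections or {}).items():
        for direction, genes in (("up", up), ("down", down)):
            if not genes:
                continue
            enr = fisher_enrich(genes, universe, coll)
            path = outdir / f"enrich_{tag}_{name}_{direction}.tsv"
            enr.assign(overlap_genes=enr["overlap_genes"].map(",".join)).to_csv(
                path, sep="\t", index=False
            )
            entry["enrichment"][f"{name}_{direction}"] = int((enr["padj"] < cfg.alpha).sum())

    if network is not None:
        prop_cfg = PropagationConfig(restart_rate=cfg.restart_rate)
        try:
            prop = propagate_degs(de, network, prop_cfg, alpha=cfg.alpha)
            ranked = select_key_genes(prop, cfg.prob_quantile, cfg.bc_quantile)
            ranked.to_csv(outdir / f"netprop_{tag}.tsv", sep="\t", index=False)
            entry["netprop_rows"] = len(ranked)
            entry["n_key_genes"] = int(ranked["key"].sum())
        except ValueError as exc:
            logger.warning("%s: propagation skipped (%s)", tag, exc)
            entry["netprop_skipped"] = str(exc)
    entry["seconds"] = round(time.perf_counter() - t0, 3)
    return entry


def run_quadrants(
    cfg: RunConfig,
    contrast: tuple[str, str],
    prepared=None,
    outdir: Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Independent DE within each quadrant stratum (per-stratum BH).

    Strata with fewer than 2 ROIs per group are skipped with a warning.
    """
    if prepared is None:
        counts0, meta0, _net, _coll = _load_inputs(cfg)
        prepared = _prepare(cfg, counts0, meta0)
    counts, meta, norm, ruv, sf = prepared
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    test, ref = contrast
    results: dict[str, pd.DataFrame] = {}
    for quadrant in cfg.quadrants:
        sub = meta[meta["quadrant"] == quadrant]
        n_test = (sub["group"] == test).sum()
        n_ref = (sub["group"] == ref).sum()
        if n_test < 2 or n_ref < 2:
            logger.warning(
                "quadrant %s skipped for %s vs %s: %d/%d ROIs", quadrant, test, ref, n_test, n_ref
            )
            continue
        design = DesignSpec(
            contrast=contrast,
            covariates=ruv.loadings if ruv.k else None,
            stratum=quadrant,
            alpha=cfg.alpha,
        )
        rois = list(sub["roi_id"])
        cells = pd.Series(sub["group"].to_numpy(), index=rois)
        disp = estimate_dispersions(counts.subset_rois(rois), sf.reindex(rois), cells)
        de = nb_wald_test(counts, meta, sf, disp, design)
        de.to_csv(outdir / f"de_{test}_vs_{ref}_{quadrant}.tsv", sep="\t", index=False)
        results[quadrant] = de
    return results


def run_all(cfg: RunConfig) -> dict:
    """Run every configured contrast (plus quadrant strata and the DEG-overlap
    summary), writing tables and a JSON manifest under ``cfg.outdir``."""
    t0 = time.perf_counter()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts0, meta0, network, collections = _load_inputs(cfg)
    prepared = _prepare(cfg, counts0, meta0)

    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
        "inputs": {
            "counts": _sha256(cfg.counts),
            "meta": _sha256(cfg.meta),
            "network": _sha256(cfg.network),
            **{f"gmt:{n}": _sha256(p) for n, p in cfg.gene_sets.items()},
        },
        "stages": [],
    }
    deg_lists: dict[str, tuple[list[str], list[str]]] = {}
    for contrast in cfg.contrasts:
        try:
            entry = run_contrast(cfg, contrast, prepared, network, collections, outdir)
        except Exception as exc:  # a failed contrast must not sink the others
            logger.error("contrast %s failed: %s", contrast, exc)
            entry = {"contrast": list(contrast), "error": str(exc)}
            manifest["stages"].append(entry)
            continue
        manifest["stages"].append(entry)
        de = pd.read_csv(outdir / f"de_{contrast[0]}_vs_{contrast[1]}.tsv", sep="\t")
        deg_lists[f"{contrast[0]}_vs_{contrast[1]}"] = significant_genes(de, cfg.alpha)
        if cfg.quadrant_mode:
            quads = run_quadrants(cfg, contrast, prepared, outdir)
            manifest["stages"].append(
                {
                    "contrast": list(contrast),
                    "quadrants": {q: int((t["padj"] < cfg.alpha).sum()) for q, t in quads.items()},
                }
            )
    if len(deg_lists) >= 2:
        venn = venn_overlap(deg_lists)
        (outdir / "venn.json").write_text(json.dumps(venn, indent=1))
        manifest["venn"] = {d: venn[d]["shared"] for d in ("up", "down")}
    manifest["seconds"] = round(time.perf_counter() - t0, 3)
    # atomic-ish: write then rename
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(outdir / "manifest.json")
    return manifest
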