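"""Synthetic GeoMx-like data with known ground truth.

Emulates the study design this pipeline targets: a handful of post-mortem
subjects in three diagnostic groups (healthy control, Parkinson disease,
Parkinsonian-type multiple system atrophy), ~12 regions of interest (ROIs)
per subject/slide spanning four anatomical quadrants of the substantia nigra,
negative-binomial counts with library-size variation, slide-correlated
unwanted variation, and planted group log2 fold-changes. Everything is
deterministic given the seed, so every downstream stage is testable without
downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    QUADRANTS,
    META_COLUMNS,
    CountMatrix,
    GeneSetCollection,
    PPINetwork,
)

# baseline expression: log-normal spanning roughly 3 orders of magnitude
_BASELINE_LOG_MEAN = np.log(50.0)
_BASELINE_LOG_SIGMA = 1.4
# per-gene dispersion jitter around the configured value (log-normal sigma)
_DISPERSION_SIGMA = 0.3
# ROI-level spread of the slide-shared unwanted loading
_UNWANTED_ROI_NOISE = 0.3


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the target design: 3 groups × 2 subjects, 12 ROIs per
    subject (one slide each) balanced over 4 quadrants; ~10% of genes
    differentially expressed at |log2FC| = 2; NB dispersion 0.2; log-normal
    library-size spread 0.3; one slide-correlated unwanted factor.
    """

    n_genes: int = 2000
    n_subjects_per_group: int = 2
    rois_per_subject: int = 12
    groups: tuple[str, ...] = GROUPS
    quadrants: tuple[str, ...] = QUADRANTS
    frac_de: float = 0.1
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    libsize_sigma: float = 0.3
    n_unwanted_factors: int = 1
    unwanted_sigma: float = 0.5
    n_control_genes: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_subjects_per_group", "rois_per_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if not self.quadrants:
            raise ValueError("quadrants must be non-empty")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be ≥ 0")
        if self.libsize_sigma < 0 or self.unwanted_sigma < 0:
            raise ValueError("sigma parameters must be ≥ 0")
        if self.n_unwanted_factors < 0 or self.n_control_genes < 0:
            raise ValueError("counts must be ≥ 0")
        if self.n_genes < 2 * self.n_control_genes:
            raise ValueError("n_genes must be ≥ 2 × n_control_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``de_genes`` maps gene → (contrast label, true log2FC); ``unwanted_loadings``
    is the ROI × factor matrix actually used; ``control_genes`` is a subset of
    the non-DE genes.
    """

    de_genes: dict[str, tuple[str, float]]
    unwanted_loadings: pd.DataFrame
    control_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": {g: [c, lfc] for g, (c, lfc) in self.de_genes.items()},
            "unwanted_loadings": {
                "index": list(self.unwanted_loadings.index),
                "columns": list(self.unwanted_loadings.columns),
                "values": self.unwanted_loadings.to_numpy().tolist(),
            },
            "control_genes": self.control_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        w = payload["unwanted_loadings"]
        return cls(
            de_genes={g: (c, float(l)) for g, (c, l) in payload["de_genes"].items()},
            unwanted_loadings=pd.DataFrame(
                np.asarray(w["values"], dtype=float), index=w["index"], columns=w["columns"]
            ),
            control_genes=list(payload["control_genes"]),
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate counts, ROI metadata, and ground truth.

    Counts are gene-wise negative binomial with mean
    ``mu = s_j * q_g * 2**(x_ij * beta_g + (w @ alpha)_gj)`` where ``s_j`` is
    the ROI library-size factor, ``q_g`` a log-normal baseline, ``x`` the
    group design, and ``w``/``alpha`` the unwanted-factor loadings.
    Quadrants are assigned cyclically within each subject; nuclei counts are
    uniform in [50, 300].
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)

    # --- metadata ------------------------------------------------------
    rows = []
    for group in cfg.groups:
        for s in range(cfg.n_subjects_per_group):
            subject = f"{group}{s + 1}"
            for i in range(cfg.rois_per_subject):
                rows.append(
                    {
                        "roi_id": f"{subject}_R{i + 1:02d}",
                        "subject_id": subject,
                        "group": group,
                        "quadrant": cfg.quadrants[i % len(cfg.quadrants)],
                        "slide_id": f"slide_{subject}",
                        "nuclei_count": int(rng.integers(50, 301)),
                    }
                )
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    rois = list(meta["roi_id"])
    n_rois = len(rois)

    # --- planted differential expression -------------------------------
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    reference = cfg.groups[0]
    targets = list(cfg.groups[1:]) or [reference]
    de_genes: dict[str, tuple[str, float]] = {}
    beta = np.zeros((cfg.n_genes, len(cfg.groups)))  # log2FC per group vs reference
    for j, gi in enumerate(sorted(de_idx)):
        target = targets[j % len(targets)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * cfg.effect_log2fc
        de_genes[genes[gi]] = (f"{target} vs {reference}", lfc)
        beta[gi, cfg.groups.index(target)] = lfc

    # --- control genes: subset of non-DE genes -------------------------
    non_de = np.setdiff1d(np.arange(cfg.n_genes), de_idx)
    ctrl_idx = rng.choice(non_de, size=min(cfg.n_control_genes, len(non_de)), replace=False)
    control_genes = [genes[i] for i in sorted(ctrl_idx)]

    # --- unwanted variation: slide-shared loading ± ROI noise ----------
    k = cfg.n_unwanted_factors
    subjects = meta["subject_id"].to_numpy()
    w = np.zeros((n_rois, k))
    for f in range(k):
        base = {s: rng.normal() for s in dict.fromkeys(subjects)}
        w[:, f] = np.array([base[s] for s in subjects]) + rng.normal(
            0, _UNWANTED_ROI_NOISE, n_rois
        )
    alpha = rng.normal(0.0, cfg.unwanted_sigma, size=(cfg.n_genes, k)) if k else np.zeros(
        (cfg.n_genes, 0)
    )
    unwanted = pd.DataFrame(w, index=rois, columns=[f"W{f + 1}" for f in range(k)])

    # --- expected counts ------------------------------------------------
    q = rng.lognormal(_BASELINE_LOG_MEAN, _BASELINE_LOG_SIGMA, cfg.n_genes)
    s = rng.lognormal(0.0, cfg.libsize_sigma, n_rois) if cfg.libsize_sigma > 0 else np.ones(n_rois)
    group_idx = np.array([cfg.groups.index(g) for g in meta["group"]])
    log2_effect = beta[:, group_idx]  # genes × rois
    if k:
        log2_effect = log2_effect + alpha @ w.T
    mu = s[None, :] * q[:, None] * np.exp2(log2_effect)

    # --- NB sampling ----------------------------------------------------
    if cfg.nb_dispersion > 0:
        disp = cfg.nb_dispersion * rng.lognormal(0.0, _DISPERSION_SIGMA, cfg.n_genes)
        size = 1.0 / disp  # NB shape; variance = mu + disp * mu^2
        p = size[:, None] / (size[:, None] + mu)
        counts = rng.negative_binomial(size[:, None], p)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=rois))
    truth = SyntheticTruth(de_genes=de_genes, unwanted_loadings=unwanted, control_genes=control_genes)
    return cm, meta, truth


def generate_ppi(
    n_nodes: int, edges_per_node: int, seed: int, genes: list[str] | None = None
) -> PPINetwork:
    """Connected scale-free-like PPI stand-in via preferential attachment.

    Node labels are gene symbols (``genes`` if given, else the synthetic
    naming scheme). The Barabási–Albert process guarantees a connected simple
    graph with no self-loops.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be ≥ 3")
    if edges_per_node < 1 or edges_per_node >= n_nodes:
        raise ValueError("need 1 ≤ edges_per_node < n_nodes for a connected simple graph")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(seed))
    labels = genes if genes is not None else _gene_names(n_nodes)
    if len(labels) < n_nodes:
        raise ValueError("not enough gene labels for the requested node count")
    g = nx.relabel_nodes(g, dict(enumerate(labels[:n_nodes])))
    return PPINetwork(g)


def generate_gene_sets(
    genes: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_set: list[str] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection; optionally one term containing a planted
    set entirely (for enrichment-recovery tests)."""
    if not genes:
        raise ValueError("empty gene universe")
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError("set sizes must satisfy 1 ≤ lo ≤ hi ≤ n_genes")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_sets)))
    terms: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        terms[f"SET_{i + 1:0{width}d}"] = ("random set", members)
    if planted_set is not None:
        if not planted_set:
            raise ValueError("planted_set must be non-empty if given")
        terms["PLANTED"] = ("planted set", list(dict.fromkeys(planted_set)))
    return GeneSetCollection(terms)


def write_dataset(
    outdir: str | Path,
    counts: CountMatrix,
    meta: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write counts (TSV), metadata (CSV) and truth (JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "meta.csv",
        "truth": outdir / "truth.json",
    }
    counts.to_file(paths["counts"])
    meta.to_csv(paths["meta"], index=False)
    truth.to_json(paths["truth"])
    return paths
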