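"""Random-walk-with-restart (RWR) network propagation and betweenness
centrality for hub-gene discovery on a protein–protein interaction network.

Significant differentially expressed genes are mapped onto the network with
their fold changes as seed mass; the walk iterates

    p(t+1) = (1 - r) W' p(t) + r p0

where ``W'`` is the column-normalized adjacency matrix and ``r`` the restart
rate. Topological importance is quantified with betweenness centrality
BC(v) = sum over pairs s != v != t of sigma_st(v) / sigma_st (Brandes
accumulation, unordered-pair convention). Key genes are the significant
DEGs ranking high on both the stationary probability and betweenness.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PPINetwork

SEED_TRANSFORMS = ("abs", "positive-part", "signed-split")


@dataclass
class PropagationConfig:
    """RWR parameters: restart rate r in (0,1), L1 convergence tolerance,
    iteration cap, and how signed log2 fold-changes become seed mass."""

    restart_rate: float = 0.7
    tolerance: float = 1e-8
    max_iter: int = 10_000
    seed_transform: str = "abs"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_rate < 1.0:
            raise ValueError("restart_rate must be strictly inside (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        if self.seed_transform not in SEED_TRANSFORMS:
            raise ValueError(f"seed_transform must be one of {SEED_TRANSFORMS}")


def column_normalize(network: PPINetwork) -> tuple[np.ndarray, list[str]]:
    """Column-stochastic matrix W' of the network (nodes sorted).

    W'_ij = A_ij / deg(j); zero-degree columns become identity columns
    (a self-loop), preserving column-stochasticity without teleporting mass.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    A, nodes = network.adjacency()
    deg = A.sum(axis=0)
    W = np.zeros_like(A)
    pos = deg > 0
    W[:, pos] = A[:, pos] / deg[pos]
    for j in np.flatnonzero(~pos):
        W[j, j] = 1.0
    return W, nodes


def build_seed_vector(
    de: pd.DataFrame,
    network: PPINetwork,
    transform: str = "abs",
    alpha: float = 0.05,
) -> pd.Series:
    """Seed distribution p0 over network nodes from significant DEGs.

    Significant genes (padj < alpha) present in the network receive
    transform(log2FC) mass — |log2FC| by default, max(log2FC, 0) for
    "positive-part" — then the vector is rescaled to sum 1. Unmapped DEGs
    are reported with a warning; zero mappable DEGs is an error.
    """
    sig = de[de["padj"] < alpha]
    if sig.empty:
        raise ValueError("no significant DEGs at the requested alpha")
    nodes = network.nodes
    node_set = set(nodes)
    unmapped = sorted(set(sig["gene"]) - node_set)
    if unmapped:
        warnings.warn(f"{len(unmapped)} significant DEG(s) absent from network: {unmapped[:10]}")
    mapped = sig[sig["gene"].isin(node_set)]
    if mapped.empty:
        raise ValueError(f"no significant DEG maps onto the network; tried {sorted(sig['gene'])[:20]}")
    if transform == "abs":
        mass = mapped["log2FC"].abs()
    elif transform == "positive-part":
        mass = mapped["log2FC"].clip(lower=0.0)
    else:
        raise ValueError(f"unknown seed transform {transform!r}")
    p0 = pd.Series(0.0, index=nodes)
    p0.loc[mapped["gene"].to_numpy()] = mass.to_numpy()
    total = p0.sum()
    if total <= 0:
        raise ValueError("seed vector has zero total mass after transform")
    return p0 / total


def rwr(W: np.ndarray, p0: np.ndarray | pd.Series, config: PropagationConfig | None = None) -> np.ndarray:
    """Iterate the restart walk to its stationary vector.

    Stops when the L1 change drops below the tolerance; conservation
    (sum p == sum p0) is asserted at every iteration within 1e-9, and the
    fixed-point residual of the returned vector is below 10x tolerance.
    """
    cfg = config or PropagationConfig()
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must sum to 1")
    if not np.allclose(W.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("W must be column-stochastic")
    r = cfg.restart_rate
    p = p0.copy()
    for _ in range(cfg.max_iter):
        nxt = (1.0 - r) * (W @ p) + r * p0
        if abs(nxt.sum() - p0.sum()) > 1e-9:
            raise AssertionError("probability mass not conserved during propagation")
        delta = np.abs(nxt - p).sum()
        p = nxt
        if delta < cfg.tolerance:
            return p
    residual = np.abs(p - (1.0 - r) * (W @ p) - r * p0).sum()
    raise RuntimeError(
        f"RWR did not converge in {cfg.max_iter} iterations (L1 residual {residual:.3e})"
    )


def betweenness(network: PPINetwork, normalized: bool = True) -> pd.Series:
    """Betweenness centrality via Brandes accumulation (unweighted BFS).

    Unordered-pair convention: each (s, t) pair is counted once; disconnected
    pairs contribute 0. If ``normalized``, values are divided by
    (n-1)(n-2)/2.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    G = network.graph
    nodes = network.nodes
    adj = {v: list(G.neighbors(v)) for v in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        dist = dict.fromkeys(nodes, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w_ in adj[v]:
                if dist[w_] < 0:
                    dist[w_] = dist[v] + 1
                    queue.append(w_)
                if dist[w_] == dist[v] + 1:
                    sigma[w_] += sigma[v]
                    pred[w_].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w_ = stack.pop()
            for v in pred[w_]:
                delta[v] += sigma[v] / sigma[w_] * (1.0 + delta[w_])
            if w_ != s:
                bc[w_] += delta[w_]
    n = len(nodes)
    out = pd.Series(bc, dtype=float) / 2.0  # each unordered pair visited from both ends
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        out = out / denom if denom > 0 else out * 0.0
    return out.reindex(nodes)


def propagate_degs(
    de: pd.DataFrame,
    network: PPINetwork,
    config: PropagationConfig | None = None,
    alpha: float = 0.05,
    normalized_bc: bool = False,
) -> pd.DataFrame:
    """Full propagation stage: seeds from significant DEGs, RWR, betweenness.

    Betweenness is computed on the induced largest connected component of
    the full network (nodes outside it get 0). With the "signed-split"
    transform, up- and down-seeded walks are run separately and their
    stationary vectors averaged. Returns one row per network node with
    columns gene, log2FC, seed, probability, betweenness, is_deg.
    """
    cfg = config or PropagationConfig()
    W, nodes = column_normalize(network)

    if cfg.seed_transform == "signed-split":
        parts = []
        for direction in ("up", "down"):
            sub = de.copy()
            keep = sub["log2FC"] > 0 if direction == "up" else sub["log2FC"] < 0
            sub = sub[keep | (sub["padj"] >= alpha)]
            try:
                p0 = build_seed_vector(sub, network, "abs", alpha)
            except ValueError:
                continue
            parts.append((p0, rwr(W, p0.to_numpy(), cfg)))
        if not parts:
            raise ValueError("no significant DEG maps onto the network")
        p0 = sum(p for p, _ in parts) / len(parts)
        p = sum(v for _, v in parts) / len(parts)
    else:
        p0 = build_seed_vector(de, network, cfg.seed_transform, alpha)
        p = rwr(W, p0.to_numpy(), cfg)

    bc_full = pd.Series(0.0, index=nodes)
    lcc = network.largest_component()
    bc_full.loc[lcc.nodes] = betweenness(lcc, normalized=normalized_bc)

    sig = set(de.loc[de["padj"] < alpha, "gene"]) & set(nodes)
    lfc = de.set_index("gene")["log2FC"].reindex(nodes).fillna(0.0)
    return pd.DataFrame(
        {
            "gene": nodes,
            "log2FC": lfc.to_numpy(),
            "seed": np.asarray(p0, dtype=float),
            "probability": np.asarray(p, dtype=float),
            "betweenness": bc_full.to_numpy(),
            "is_deg": [g in sig for g in nodes],
        }
    )


def select_key_genes(
    result: pd.DataFrame,
    prob_quantile: float = 0.90,
    bc_quantile: float = 0.90,
) -> pd.DataFrame:
    """Flag key genes: significant DEG nodes at or above both quantile
    thresholds (computed over DEG nodes only), ranked by probability then
    betweenness then symbol."""
    if not 0 <= prob_quantile <= 1 or not 0 <= bc_quantile <= 1:
        raise ValueError("quantiles must be in [0, 1]")
    degs = result[result["is_deg"]]
    if degs.empty:
        raise ValueError("no DEG nodes in propagation result")
    if len(degs) < 10:
        warnings.warn(f"only {len(degs)} DEG nodes; quantile thresholds are unstable")
    p_thr = float(np.quantile(degs["probability"], prob_quantile))
    b_thr = float(np.quantile(degs["betweenness"], bc_quantile))
    out = result.copy()
    out["key"] = (
        out["is_deg"] & (out["probability"] >= p_thr) & (out["betweenness"] >= b_thr)
    )
    out = out.sort_values(
        ["probability", "betweenness", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
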