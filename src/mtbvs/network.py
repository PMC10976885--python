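"""Stability-calibrated conditional-independence networks.

Graphical-LASSO models are fitted on many half-sample subsamples; an edge's
selection proportion across subsamples measures its stability.  The penalty
lambda and the selection-proportion threshold pi are calibrated jointly by
maximizing a stability score -- the negative log-likelihood of the observed
stable-in / stable-out / unstable edge classification under a null in which
all edges are exchangeable -- subject to an upper bound (PFER) on the
expected number of falsely selected edges.  Multiblock panels (e.g. diet +
chemical exposures) are calibrated per block-pair with shared subsamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.covariance import graphical_lasso

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "SelectionProportionTable",
    "CalibratedNetwork",
    "lambda_grid",
    "selection_proportions",
    "stability_score",
    "pfer_bound",
    "calibrate_network",
    "detect_communities",
    "write_network",
]


@dataclass
class StabilityConfig:
    """Stability-selection settings for network calibration."""

    K: int = 100
    subsample_fraction: float = 0.5
    lambda_grid: np.ndarray | None = None  # computed from the data if None
    n_lambda: int = 20
    lambda_ratio: float = 0.01
    pi_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.55, 1.0001, 0.01), 2)
    )
    pfer_max: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        pi = np.asarray(self.pi_grid)
        if np.any(pi <= 0.5) or np.any(pi > 1):
            raise ValueError("pi grid must lie in (0.5, 1]")
        if self.lambda_grid is not None and np.any(np.asarray(self.lambda_grid) <= 0):
            raise ValueError("lambda grid must be strictly positive")


def _standardize(data: np.ndarray) -> np.ndarray:
    sd = data.std(axis=0)
    sd[sd == 0] = 1.0
    return (data - data.mean(axis=0)) / sd


def lambda_grid(data: np.ndarray, n_points: int = 20, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty grid from the empty-graph penalty downwards.

    The largest value is the maximal absolute off-diagonal correlation (the
    smallest penalty that empties every graph); the smallest is ``ratio``
    times that.
    """
    corr = np.corrcoef(_standardize(np.asarray(data, dtype=float)), rowvar=False)
    off = np.abs(corr - np.diag(np.diag(corr)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_points)


@dataclass
class SelectionProportionTable:
    """Edge selection counts over K subsamples, one column per penalty."""

    counts: np.ndarray  # (n_lambda, n_edges) integer counts
    edges: list[tuple[int, int]]
    lambdas: np.ndarray
    K: int
    q_hat: np.ndarray  # mean number of selected edges per subsample, per lambda

    def proportions(self, lam_index: int) -> np.ndarray:
        return self.counts[lam_index] / self.K


def _edge_list(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def _fit_subsample(sub: np.ndarray, lam: float) -> np.ndarray:
    """Nonzero off-diagonal pattern of the penalized precision estimate."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    emp = np.corrcoef(_standardize(sub), rowvar=False)
    p = emp.shape[0]
    with warnings.catch_warnings():
        # near-converged fits on half-samples are fine for support recovery
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            _, prec = graphical_lasso(emp, alpha=lam, max_iter=200)
        except FloatingPointError:
            # heavier regularization of the input correlation, then retry once
            emp = 0.95 * emp + 0.05 * np.eye(p)
            _, prec = graphical_lasso(emp, alpha=lam, max_iter=200)
    adj = np.abs(prec) > 1e-8
    np.fill_diagonal(adj, False)
    return adj


def selection_proportions(
    data,
    lambdas: float | np.ndarray,
    config: StabilityConfig | None = None,
) -> SelectionProportionTable:
    """Count, per candidate edge and penalty, how many of K half-sample
    graphical-LASSO fits select the edge.  Subsamples are shared across
    penalties and seeded."""
    config = config or StabilityConfig()
    config.validate()
    data = np.asarray(data, dtype=float)
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(lambdas <= 0):
        raise ValueError("penalty lambda must be strictly positive")
    n, p = data.shape
    m = int(round(config.subsample_fraction * n))
    if m < p + 1:
        logger.warning(
            "subsample size %d is below the recommended %d (variables + 1)", m, p + 1
        )
    edges = _edge_list(p)
    tri = np.triu_indices(p, k=1)
    rng = np.random.default_rng(config.seed)
    counts = np.zeros((len(lambdas), len(edges)), dtype=int)
    for _ in range(config.K):
        rows = rng.choice(n, size=m, replace=False)
        sub = data[rows]
        for li, lam in enumerate(lambdas):
            adj = _fit_subsample(sub, lam)
            counts[li] += adj[tri].astype(int)
    q_hat = counts.sum(axis=1) / config.K
    return SelectionProportionTable(
        counts=counts, edges=edges, lambdas=lambdas, K=config.K, q_hat=q_hat
    )


def stability_score(counts: np.ndarray, pi: float, K: int) -> float:
    """Stability of an edge classification under the exchangeable null.

    Edges with count >= ceil(K pi) are stably selected, <= floor(K (1-pi))
    stably excluded, otherwise unstable.  Under the null all counts are iid
    Binomial(K, mu) with mu the average selection proportion; the score is
    the negative log-likelihood of the observed classification, so larger
    values mean a classification less compatible with instability.
    """
    if not 0.5 < pi <= 1:
        raise ValueError(f"pi must lie in (0.5, 1], got {pi}")
    counts = np.asarray(counts)
    n_edges = counts.size
    if n_edges == 0:
        return 0.0
    upper = math.ceil(K * pi)
    lower = math.floor(K * (1 - pi))
    n_sel = int((counts >= upper).sum())
    n_exc = int((counts <= lower).sum())
    n_uns = n_edges - n_sel - n_exc
    mu = counts.sum() / (K * n_edges)
    p_sel = float(binom.sf(upper - 1, K, mu))
    p_exc = float(binom.cdf(lower, K, mu))
    p_uns = max(1.0 - p_sel - p_exc, 0.0)
    score = 0.0
    tiny = 1e-300
    for n_cat, p_cat in ((n_sel, p_sel), (n_exc, p_exc), (n_uns, p_uns)):
        if n_cat:
            score -= n_cat * math.log(max(p_cat, tiny))
    return score


def pfer_bound(q_hat: float, pi: float, n_edges: int) -> float:
    """Upper bound on the expected number of falsely selected edges.

    Uses the stability-selection bound q_hat^2 / ((2 pi - 1) N_edges).
    """
    if pi <= 0.5:
        raise ValueError(f"pi must exceed 0.5, got {pi}")
    if n_edges <= 0:
        return 0.0
    return (q_hat**2) / ((2 * pi - 1) * n_edges)


@dataclass
class CalibratedNetwork:
    """Stable edge set with its calibrated hyperparameters."""

    nodes: list[str]
    lam: float | dict[str, float]
    pi: float | dict[str, float]
    score: float | dict[str, float]
    q_hat: float | dict[str, float]
    pfer: float | dict[str, float]
    pfer_max: float
    edges: pd.DataFrame  # node1, node2, selection_proportion, stable
    adjacency: pd.DataFrame
    communities: dict[str, int] | None = None
    modularity: float | None = None

    @property
    def stable_edges(self) -> list[tuple[str, str]]:
        sel = self.edges[self.edges["stable"]]
        return list(zip(sel["node1"], sel["node2"]))

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        G.add_edges_from(self.stable_edges)
        return G

    def degrees(self) -> pd.Series:
        G = self.graph()
        return pd.Series({v: G.degree(v) for v in self.nodes}, name="degree")


def _calibrate_edge_set(
    table: SelectionProportionTable,
    edge_idx: np.ndarray,
    pi_grid: np.ndarray,
    pfer_max: float,
) -> tuple[int, float, float, float, float] | None:
    """Best (lambda index, pi) for one edge set under the PFER constraint."""
    best = None
    n_edges = len(edge_idx)
    for li in range(len(table.lambdas)):
        counts = table.counts[li, edge_idx]
        q_hat = counts.sum() / table.K
        for pi in pi_grid:
            bound = pfer_bound(q_hat, float(pi), n_edges)
            if bound > pfer_max:
                continue
            sc = stability_score(counts, float(pi), table.K)
            key = (sc, table.lambdas[li], pi)
            if best is None or key > best[0]:
                best = (key, li, float(pi), sc, q_hat, bound)
    if best is None:
        return None
    _, li, pi, sc, q_hat, bound = best
    return li, pi, sc, q_hat, bound


def calibrate_network(
    data,
    config: StabilityConfig | None = None,
    blocks: list[str] | np.ndarray | None = None,
    node_names: list[str] | None = None,
    detect: bool = True,
) -> CalibratedNetwork:
    """Grid-search (lambda, pi) maximizing the stability score subject to
    the PFER constraint, then return the stable edge set.

    In multiblock mode (``blocks`` labels every variable) each block-pair
    (within-1, within-2, between, ...) is calibrated by its own stability
    score over the shared subsample fits, with the PFER budget split across
    block-pairs proportionally to their candidate edge counts.
    """
    config = config or StabilityConfig()
    config.validate()
    if isinstance(data, pd.DataFrame):
        node_names = node_names or [str(c) for c in data.columns]
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    p = data.shape[1]
    node_names = node_names or [f"v{j}" for j in range(p)]

    lambdas = (
        np.asarray(config.lambda_grid)
        if config.lambda_grid is not None
        else lambda_grid(data, config.n_lambda, config.lambda_ratio)
    )
    table = selection_proportions(data, lambdas, config)
    edges = table.edges
    n_edges = len(edges)
    pi_grid = np.asarray(config.pi_grid, dtype=float)

    if blocks is None:
        pair_of_edge = np.zeros(n_edges, dtype=int)
        pair_labels = ["all"]
        budgets = {"all": config.pfer_max}
    else:
        blocks = np.asarray(blocks)
        if len(blocks) != p:
            raise ValueError("blocks must label every variable")
        uniq = list(dict.fromkeys(blocks))
        pair_names = {}
        pair_of_edge = np.empty(n_edges, dtype=int)
        for e, (i, j) in enumerate(edges):
            a, b = sorted((uniq.index(blocks[i]), uniq.index(blocks[j])))
            name = (
                f"within-{uniq[a]}" if a == b else f"between-{uniq[a]}-{uniq[b]}"
            )
            if name not in pair_names:
                pair_names[name] = len(pair_names)
            pair_of_edge[e] = pair_names[name]
        pair_labels = list(pair_names)
        sizes = {
            lab: int((pair_of_edge == k).sum()) for k, lab in enumerate(pair_labels)
        }
        budgets = {
            lab: config.pfer_max * sizes[lab] / n_edges for lab in pair_labels
        }

    lam_sel: dict[str, float] = {}
    pi_sel: dict[str, float] = {}
    score_sel: dict[str, float] = {}
    qhat_sel: dict[str, float] = {}
    pfer_sel: dict[str, float] = {}
    stable = np.zeros(n_edges, dtype=bool)
    proportions = np.zeros(n_edges)

    for k, lab in enumerate(pair_labels):
        edge_idx = np.flatnonzero(pair_of_edge == k)
        result = _calibrate_edge_set(table, edge_idx, pi_grid, budgets[lab])
        if result is None:
            logger.warning(
                "no (lambda, pi) pair satisfies the PFER constraint for "
                "edge set '%s'; returning it empty",
                lab,
            )
            lam_sel[lab] = float("nan")
            pi_sel[lab] = float("nan")
            score_sel[lab] = float("nan")
            qhat_sel[lab] = 0.0
            pfer_sel[lab] = 0.0
            continue
        li, pi, sc, q_hat, bound = result
        lam_sel[lab] = float(table.lambdas[li])
        pi_sel[lab] = pi
        score_sel[lab] = sc
        qhat_sel[lab] = q_hat
        pfer_sel[lab] = bound
        props = table.counts[li, edge_idx] / table.K
        proportions[edge_idx] = props
        stable[edge_idx] = props >= pi

    edge_df = pd.DataFrame(
        {
            "node1": [node_names[i] for i, _ in edges],
            "node2": [node_names[j] for _, j in edges],
            "selection_proportion": proportions,
            "stable": stable,
        }
    )
    adj = np.zeros((p, p), dtype=int)
    for e, (i, j) in enumerate(edges):
        if stable[e]:
            adj[i, j] = adj[j, i] = 1
    adjacency = pd.DataFrame(adj, index=node_names, columns=node_names)

    single = blocks is None
    net = CalibratedNetwork(
        nodes=node_names,
        lam=lam_sel["all"] if single else lam_sel,
        pi=pi_sel["all"] if single else pi_sel,
        score=score_sel["all"] if single else score_sel,
        q_hat=qhat_sel["all"] if single else qhat_sel,
        pfer=pfer_sel["all"] if single else pfer_sel,
        pfer_max=config.pfer_max,
        edges=edge_df,
        adjacency=adjacency,
    )
    if detect:
        labels, modularity = detect_communities(net.graph(), seed=config.seed)
        net.communities = labels
        net.modularity = modularity
    return net


def detect_communities(
    graph: nx.Graph | pd.DataFrame | np.ndarray, seed: int = 0
) -> tuple[dict, float]:
    """Louvain communities with unit edge weights; reports modularity.

    An edgeless graph yields one singleton community per node and
    modularity 0 by convention.
    """
    if not isinstance(graph, nx.Graph):
        adj = pd.DataFrame(graph)
        G = nx.from_pandas_adjacency(adj)
    else:
        G = graph
    if G.number_of_edges() == 0:
        return {v: i for i, v in enumerate(G.nodes)}, 0.0
    parts = nx.community.louvain_communities(G, weight=None, resolution=1, seed=seed)
    labels = {v: i for i, part in enumerate(parts) for v in part}
    modularity = nx.community.modularity(G, parts, weight=None)
    return labels, float(modularity)


def write_network(net: CalibratedNetwork, prefix: str | Path) -> dict[str, Path]:
    """Write the network as edge-list TSV and GraphML."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_df = net.edges.copy()
    if net.communities:
        edge_df["community"] = [
            net.communities.get(a, -1) if net.communities.get(a) == net.communities.get(b)
            else -1
            for a, b in zip(edge_df["node1"], edge_df["node2"])
        ]
    tsv = prefix.with_suffix(".tsv")
    edge_df.to_csv(tsv, sep="\t", index=False)
    G = net.graph()
    for _, row in net.edges.iterrows():
        if row["stable"]:
            G[row["node1"]][row["node2"]]["selection_proportion"] = float(
                row["selection_proportion"]
            )
    if net.communities:
        nx.set_node_attributes(G, net.communities, "community")
    graphml = prefix.with_suffix(".graphml")
    nx.write_graphml(G, graphml)
    return {"edge_list": tsv, "graphml": graphml}
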