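"""Mutual-information objective for clustering-parameter selection.

Members of a genuine regulatory module should have correlated expression
profiles across tissues.  The objective scores a clustering by the ratio

    median(intra-module pairwise MI) / median(inter-module pairwise MI)

with MI(X, Y) = H(X) + H(Y) - H(X, Y) estimated from Gaussian-smoothed
histograms of the (log-transformed) RPKM vectors, H(X) = -sum p ln p in
nats.  The marginal entropies are computed from the marginals of the
smoothed joint histogram, which keeps the plug-in MI non-negative for any
smoothing width.  A grid search over the clustering parameters
{theta, alpha} picks the combination maximizing the ratio.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .msm_clustering import UNASSIGNED, FuzzyClustering, cluster_component

DEFAULT_BINS = 8
DEFAULT_SIGMA = 1.0


def _entropy_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _smooth(counts: np.ndarray, sigma: float) -> np.ndarray:
    if sigma > 0:
        counts = gaussian_filter(counts.astype(float), sigma, mode="constant")
    return counts


def smoothed_entropy(values, bins: int = DEFAULT_BINS,
                     sigma: float = DEFAULT_SIGMA) -> float:
    """Entropy (nats) of a Gaussian-smoothed histogram.

    1-D input: a ``bins``-bin histogram over the data range is smoothed
    with a Gaussian kernel of width ``sigma`` (in bins), renormalized to a
    probability mass function and plugged into H = -sum p ln p.  A 2-D
    array of shape (n, 2) is treated as paired samples and binned jointly.
    Constant input yields entropy 0 (all mass in one cell) with a warning.
    """
    x = np.asarray(values, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.ndim == 1:
        if x.size < 3:
            raise ValueError("entropy estimation needs >= 3 samples")
        if np.ptp(x) == 0:
            warnings.warn("constant input: entropy is 0 (degenerate histogram)")
            return 0.0
        counts, _ = np.histogram(x, bins=bins)
    elif x.ndim == 2 and x.shape[1] == 2:
        if x.shape[0] < 3:
            raise ValueError("entropy estimation needs >= 3 samples")
        counts, _, _ = np.histogram2d(x[:, 0], x[:, 1], bins=bins)
    else:
        raise ValueError("values must be 1-D or an (n, 2) array of pairs")
    counts = _smooth(counts, sigma)
    total = counts.sum()
    if total == 0:
        return 0.0
    return _entropy_from_probs(counts.ravel() / total)


@dataclass
class MIEstimate:
    h_x: float
    h_y: float
    h_xy: float
    mi: float
    bins: int
    sigma: float


def mutual_information(x, y, bins: int = DEFAULT_BINS,
                       sigma: float = DEFAULT_SIGMA) -> MIEstimate:
    """Histogram MI with shared-joint marginals.

    The joint histogram is smoothed with an isotropic Gaussian kernel and
    the marginals are obtained by summing the smoothed joint, so that
    MI = H(X) + H(Y) - H(X, Y) is the mutual information of a proper joint
    distribution and cannot go negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("MI estimation needs >= 3 samples")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    joint = _smooth(joint, sigma)
    total = joint.sum()
    if total == 0:
        return MIEstimate(0.0, 0.0, 0.0, 0.0, bins, sigma)
    joint = joint / total
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    h_x = _entropy_from_probs(px)
    h_y = _entropy_from_probs(py)
    h_xy = _entropy_from_probs(joint.ravel())
    return MIEstimate(h_x=h_x, h_y=h_y, h_xy=h_xy, mi=h_x + h_y - h_xy,
                      bins=bins, sigma=sigma)


@dataclass
class MIRatioReport:
    intra_mis: list
    inter_mis: list
    ratio: float
    defined: bool
    pair_scope: str
    n_intra: int = 0
    n_inter: int = 0

    def __post_init__(self):
        self.n_intra = len(self.intra_mis)
        self.n_inter = len(self.inter_mis)


def node_features(g: nx.Graph, node, pair_scope: str = "gene") -> list[str]:
    """Expressed-feature names attached to a node under the pair scope
    ('gene' = gene names only, the more robust default; 'all' adds
    lncRNA names)."""
    data = g.nodes[node]
    feats = list(data.get("gene_names", []))
    if pair_scope == "all":
        feats += list(data.get("lncrna_names", []))
    elif pair_scope != "gene":
        raise ValueError("pair_scope must be 'gene' or 'all'")
    return feats


def transform_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM + 1) transform applied before histogram binning."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative (RPKM scale)")
    return np.log2(expr + 1.0)


class PairMICache:
    """Lazy cache of pairwise MI values over a fixed expression matrix,
    so a parameter grid search does not recompute pair MIs per cell."""

    def __init__(self, expr: pd.DataFrame, bins: int = DEFAULT_BINS,
                 sigma: float = DEFAULT_SIGMA, log_transform: bool = True):
        self.expr = transform_expression(expr) if log_transform else expr
        self.bins = bins
        self.sigma = sigma
        self._cache: dict[tuple[str, str], float] = {}

    def mi(self, f1: str, f2: str) -> float:
        key = (f1, f2) if f1 <= f2 else (f2, f1)
        if key not in self._cache:
            est = mutual_information(self.expr.loc[key[0]].to_numpy(),
                                     self.expr.loc[key[1]].to_numpy(),
                                     bins=self.bins, sigma=self.sigma)
            self._cache[key] = est.mi
        return self._cache[key]


def mi_ratio(assignment_by_node: dict, g: nx.Graph, expr: pd.DataFrame,
             pair_scope: str = "gene",
             mi_cache: PairMICache | None = None,
             bins: int = DEFAULT_BINS,
             sigma: float = DEFAULT_SIGMA) -> MIRatioReport:
    """Intra/inter-module median-MI ratio of a (possibly fuzzy) clustering.

    ``assignment_by_node`` maps node ids to module ids, with UNASSIGNED
    (or None) marking transition-region nodes, which are excluded from
    both pair sets.  Feature pairs residing on the same node are skipped.
    The report is flagged undefined when either pair set is empty.
    """
    cache = mi_cache or PairMICache(expr, bins=bins, sigma=sigma)
    carriers = []  # (node, module, feature)
    for node, module in assignment_by_node.items():
        if module is None or module == UNASSIGNED:
            continue
        for feat in node_features(g, node, pair_scope):
            if feat in cache.expr.index:
                carriers.append((node, module, feat))

    intra, inter = [], []
    for (n1, m1, f1), (n2, m2, f2) in itertools.combinations(carriers, 2):
        if n1 == n2 or f1 == f2:
            continue
        (intra if m1 == m2 else inter).append(cache.mi(f1, f2))
    if not intra or not inter:
        return MIRatioReport(intra, inter, np.nan, False, pair_scope)
    med_inter = float(np.median(inter))
    if med_inter == 0:
        return MIRatioReport(intra, inter, np.nan, False, pair_scope)
    return MIRatioReport(intra, inter, float(np.median(intra)) / med_inter,
                         True, pair_scope)


def clustering_mi_ratio(clustering: FuzzyClustering, g: nx.Graph,
                        expr: pd.DataFrame, pair_scope: str = "gene",
                        mi_cache: PairMICache | None = None) -> MIRatioReport:
    return mi_ratio(clustering.assignment_by_node(), g, expr,
                    pair_scope=pair_scope, mi_cache=mi_cache)


@dataclass
class GridSearchResult:
    best_alpha: float
    best_theta: float
    best_m: int
    best_ratio: float
    best_clustering: FuzzyClustering
    table: pd.DataFrame = field(repr=False)


DEFAULT_ALPHA_GRID = (100.0, 500.0, 1000.0, 2000.0)
DEFAULT_THETA_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _n_scorable_pairs(g: nx.Graph, expr_index, pair_scope: str) -> int:
    """Feature pairs among all component nodes (same-node pairs excluded):
    the denominator of a grid cell's pair coverage."""
    carriers = []
    for node in g.nodes:
        for feat in node_features(g, node, pair_scope):
            if feat in expr_index:
                carriers.append((node, feat))
    total = 0
    for (n1, f1), (n2, f2) in itertools.combinations(carriers, 2):
        if n1 != n2 and f1 != f2:
            total += 1
    return total


def optimize_parameters(component: nx.Graph, expr: pd.DataFrame,
                        alpha_grid=DEFAULT_ALPHA_GRID,
                        theta_grid=DEFAULT_THETA_GRID,
                        seed: int = 0, pair_scope: str = "gene",
                        min_nodes: int = 20,
                        min_pair_coverage: float = 0.5,
                        mi_cache: PairMICache | None = None) -> GridSearchResult:
    """Grid search of {theta, alpha} maximizing the median-MI ratio.

    Every grid cell runs the full MSM clustering and is scored; the full
    table is returned for audit.  The ratio is meant to rank clusterings
    of the whole component, so cells that classify too few feature pairs
    (coverage below ``min_pair_coverage`` of the scorable pairs — e.g.
    theta = 1 clusterings that assign only the cores) are recorded but
    ineligible for the argmax, unless every defined cell is below the
    floor.  Ties break toward fewer modules, then larger theta.
    """
    alpha_grid = list(alpha_grid)
    theta_grid = list(theta_grid)
    if not alpha_grid or not theta_grid:
        raise ValueError("parameter grids must be non-empty")
    cache = mi_cache or PairMICache(expr)
    total_pairs = _n_scorable_pairs(component, cache.expr.index, pair_scope)
    rows, candidates = [], []
    for alpha in alpha_grid:
        for theta in theta_grid:
            clustering = cluster_component(component, alpha, theta, seed=seed,
                                           min_nodes=min_nodes)
            report = clustering_mi_ratio(clustering, component, expr,
                                         pair_scope=pair_scope, mi_cache=cache)
            coverage = ((report.n_intra + report.n_inter) / total_pairs
                        if total_pairs else 0.0)
            rows.append((alpha, theta, clustering.m, report.n_intra,
                         report.n_inter, coverage,
                         report.ratio if report.defined else np.nan))
            if report.defined:
                candidates.append((coverage, alpha, theta, clustering, report))
    table = pd.DataFrame(rows, columns=["alpha", "theta", "m", "n_intra_pairs",
                                        "n_inter_pairs", "pair_coverage",
                                        "ratio"])
    if not candidates:
        raise ValueError("MI ratio undefined on every grid cell; revise the "
                         "grid or the expression coverage")
    eligible = [c for c in candidates if c[0] >= min_pair_coverage]
    if not eligible:
        eligible = candidates
    best = max(eligible,
               key=lambda c: (c[4].ratio, -c[3].m, c[2]))
    _, alpha, theta, clustering, report = best
    return GridSearchResult(best_alpha=float(alpha), best_theta=float(theta),
                            best_m=clustering.m, best_ratio=report.ratio,
                            best_clustering=clustering, table=table)
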