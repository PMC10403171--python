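"""Assemblage and network metrics.

Implements the simulator's output statistics: weighted Jaccard distances
between assemblages, the Brainerd-Robinson coefficient, an AMOVA-style
PhiST fixation index over individual trait repertoires, Newman modularity
of the band partition on a trait-similarity graph, the clustering-gap
comparison between the interaction network and the material-similarity
network, and two adjacency-matrix comparison functions (median-binarized
edge overlap and Pearson edge correlation).

Count vectors are plain mappings from a trait label (any hashable, here
``(type_id, variant)``) to a non-negative count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .world_model import WorldState

CountVector = Mapping[Hashable, float]


class DegenerateInputError(ValueError):
    """Raised when a metric is undefined for the given input."""


# ---------------------------------------------------------------------
# assemblage similarity coefficients
# ---------------------------------------------------------------------

def weighted_jaccard_similarity(x: CountVector, y: CountVector) -> float:
    """Sum of element-wise minima over sum of element-wise maxima.

    1 for identical count vectors, 0 for disjoint supports.
    """
    labels = set(x) | set(y)
    s_min = 0.0
    s_max = 0.0
    for lab in labels:
        xv = x.get(lab, 0.0)
        yv = y.get(lab, 0.0)
        if xv < 0 or yv < 0:
            raise ValueError("counts must be non-negative")
        if xv <= yv:
            s_min += xv
            s_max += yv
        else:
            s_min += yv
            s_max += xv
    if s_max == 0:
        raise DegenerateInputError(
            "weighted Jaccard undefined for two all-zero count vectors")
    return s_min / s_max


def weighted_jaccard_distance(x: CountVector, y: CountVector) -> float:
    """1 minus the weighted Jaccard similarity: 0 = identical, 1 = disjoint."""
    return 1.0 - weighted_jaccard_similarity(x, y)


def brainerd_robinson(x: CountVector, y: CountVector,
                      as_distance: bool = False) -> float:
    """Brainerd-Robinson coefficient on percentage proportions.

    Similarity = 200 - sum_i |100*x_i/sum(x) - 100*y_i/sum(y)|, ranging from
    200 (proportionally identical) to 0 (disjoint).  With ``as_distance``
    the complement (200 - similarity) is returned.
    """
    tx = sum(x.values())
    ty = sum(y.values())
    if tx <= 0 or ty <= 0:
        raise DegenerateInputError(
            "Brainerd-Robinson undefined for an all-zero count vector")
    dev = 0.0
    for lab in set(x) | set(y):
        dev += abs(100.0 * x.get(lab, 0.0) / tx - 100.0 * y.get(lab, 0.0) / ty)
    sim = min(200.0, max(0.0, 200.0 - dev))  # clamp float drift
    return 200.0 - sim if as_distance else sim


# ---------------------------------------------------------------------
# population-structure statistics on individual repertoires
# ---------------------------------------------------------------------

def phi_st(trait_matrix, groups: Sequence) -> float:
    """AMOVA-style fixation index of trait variation among groups.

    ``trait_matrix`` is an (individuals x traits) presence/absence matrix
    (array-like or DataFrame); ``groups`` assigns each row to a band.  The
    pairwise inter-individual distance is the (binary) Jaccard distance of
    trait sets; the index is sigma2_among / (sigma2_among + sigma2_within)
    from the standard variance-component decomposition of squared
    distances.  1 means all variation lies among groups, 0 none.
    """
    X = np.asarray(trait_matrix, dtype=float)
    groups = np.asarray(groups)
    n = X.shape[0]
    if n != len(groups):
        raise ValueError("one group label per individual required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise DegenerateInputError("PhiST needs at least two groups")
    if counts.min() < 2:
        raise DegenerateInputError("PhiST needs >=2 individuals per group")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero rows
        D = squareform(pdist(X.astype(bool), metric="jaccard"))
    D = np.nan_to_num(D)  # two empty repertoires count as identical
    D2 = D ** 2

    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g, ng in zip(uniq, counts):
        idx = np.flatnonzero(groups == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within

    n_groups = len(uniq)
    df_among = n_groups - 1
    df_within = n - n_groups
    sigma_within = ss_within / df_within
    n0 = (n - (counts ** 2).sum() / n) / df_among
    sigma_among = (ss_among / df_among - sigma_within) / n0
    denom = sigma_among + sigma_within
    if denom == 0:
        return 0.0  # no variation anywhere
    return sigma_among / denom


def repertoire_similarity_graph(world: WorldState, domain: str) -> nx.Graph:
    """Complete person graph weighted by 1 - Jaccard distance of the
    (type_id, variant) repertoires in one domain."""
    g = nx.Graph()
    styles = []
    for p in world.people:
        g.add_node(p.id)
        styles.append({t.style for t in p.traits(domain)})
    n = len(styles)
    for i in range(n):
        si = styles[i]
        for j in range(i + 1, n):
            sj = styles[j]
            union = len(si | sj)
            w = (len(si & sj) / union) if union else 1.0
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def band_modularity(similarity_graph: nx.Graph,
                    partition: Mapping[int, int]) -> float:
    """Newman weighted modularity of the band partition.

    Nodes are people, edge weights their repertoire similarity; evaluates
    whether similar repertoires concentrate within bands.
    """
    if similarity_graph.number_of_nodes() == 0:
        raise DegenerateInputError("modularity undefined on an empty graph")
    labels = sorted({partition[n] for n in similarity_graph.nodes})
    communities = [{n for n in similarity_graph.nodes if partition[n] == lab}
                   for lab in labels]
    return nx.community.modularity(similarity_graph, communities,
                                   weight="weight")


# ---------------------------------------------------------------------
# network comparison
# ---------------------------------------------------------------------

def binarize_at_median(graph: nx.Graph) -> nx.Graph:
    """Keep edges whose weight is at least the median edge weight.

    The at-least convention keeps a uniformly weighted graph intact, so an
    unweighted graph passes through unchanged.
    """
    weights = [d.get("weight", 1.0) for _, _, d in graph.edges(data=True)]
    if not weights:
        return nx.Graph(graph)
    med = float(np.median(weights))
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from((u, v) for u, v, d in graph.edges(data=True)
                       if d.get("weight", 1.0) >= med)
    return out


def clustering_gap(interaction_graph: nx.Graph,
                   similarity_graph: nx.Graph) -> float:
    """Global clustering coefficient (transitivity) of the interaction
    network minus that of the material-similarity network.

    Both graphs are binarized at their own median edge weight first (the
    same treatment on both sides keeps the comparison antisymmetric).  A
    graph with no connected triple contributes 0 (with a warning).
    """
    if set(interaction_graph.nodes) != set(similarity_graph.nodes):
        raise ValueError("graphs must share one node set")
    vals = []
    for g in (binarize_at_median(interaction_graph),
              binarize_at_median(similarity_graph)):
        n_triples = sum(d * (d - 1) for _, d in g.degree())
        if n_triples == 0:
            warnings.warn("graph has no connected triple; transitivity "
                          "taken as 0", stacklevel=2)
            vals.append(0.0)
        else:
            vals.append(nx.transitivity(g))
    return vals[0] - vals[1]


def _offdiag_vector(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    return A[np.triu_indices(A.shape[0], 1)]


def binarized_overlap(A, B) -> float:
    """Proportion of edges shared after median-binarizing each matrix.

    Each adjacency matrix is thresholded at its own median off-diagonal
    value (strictly greater = edge); the result is |shared| / |union| of
    the two edge sets (1.0 when both sets are empty, i.e. identical).
    """
    a = _offdiag_vector(A)
    b = _offdiag_vector(B)
    if a.shape != b.shape:
        raise ValueError("adjacency matrices must have the same shape")
    ea = a > np.median(a)
    eb = b > np.median(b)
    union = np.logical_or(ea, eb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ea, eb).sum() / union)


def edge_correlation(A, B) -> float:
    """Pearson correlation between the edge weights of two networks
    (upper-triangle off-diagonal entries as paired vectors)."""
    a = _offdiag_vector(A)
    b = _offdiag_vector(B)
    if a.shape != b.shape:
        raise ValueError("adjacency matrices must have the same shape")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateInputError(
            "edge correlation undefined when either edge vector is constant")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------
# the 13-metric report
# ---------------------------------------------------------------------

METRIC_NAMES = (
    "assemblage_size_pots", "assemblage_size_points",
    "interactions_hunting", "interactions_learning",
    "interactions_trading", "interactions_visiting",
    "jaccard_band_pots", "jaccard_band_points",
    "jaccard_camp_pots", "jaccard_camp_points",
    "n_traits_pots", "n_traits_points",
    "mean_point_prestige",
)


@dataclass
class MetricsReport:
    """The 13 summary metrics of a run."""

    assemblage_size_pots: int
    assemblage_size_points: int
    interactions_hunting: int
    interactions_learning: int
    interactions_trading: int
    interactions_visiting: int
    jaccard_band_pots: float
    jaccard_band_points: float
    jaccard_camp_pots: float
    jaccard_camp_points: float
    n_traits_pots: int
    n_traits_points: int
    mean_point_prestige: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def assemblage_counts(world: WorldState, kind: str,
                      level: str = "camp",
                      max_tick: int | None = None) -> dict[int, dict]:
    """Per-camp (or per-band, pooled over camps) style count vectors of the
    deposited assemblages."""
    out: dict[int, dict] = {}
    if level == "camp":
        keys = [c.id for c in world.camps]
        key_of = {c.id: c.id for c in world.camps}
    elif level == "band":
        keys = [b.id for b in world.bands]
        key_of = {c.id: c.band_id for c in world.camps}
    else:
        raise ValueError(f"unknown level {level!r}")
    for k in keys:
        out[k] = {}
    for camp in world.camps:
        vec = out[key_of[camp.id]]
        for obj, dep_tick in camp.assemblage:
            if obj.kind != kind:
                continue
            if max_tick is not None and dep_tick > max_tick:
                continue
            style = obj.trait.style
            vec[style] = vec.get(style, 0) + 1
    return out


def mean_pairwise_jaccard(vectors: dict[int, dict]) -> float:
    """Mean weighted Jaccard distance over all entity pairs for which the
    distance is defined (at least one non-empty assemblage); NaN if no
    pair is defined."""
    keys = sorted(vectors)
    vals = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            try:
                vals.append(weighted_jaccard_distance(vectors[a], vectors[b]))
            except DegenerateInputError:
                continue
    return float(np.mean(vals)) if vals else float("nan")


def jaccard_distance_matrix(vectors: dict[int, dict]) -> pd.DataFrame:
    """Symmetric weighted-Jaccard distance matrix between assemblages.

    Undefined pairs (both assemblages empty) are NaN; the diagonal is 0.
    """
    keys = sorted(vectors)
    mat = pd.DataFrame(0.0, index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            try:
                d = weighted_jaccard_distance(vectors[a], vectors[b])
            except DegenerateInputError:
                d = float("nan")
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def distinct_traits(world: WorldState, domain: str) -> int:
    """Number of distinct (type_id, variant) styles across living
    repertoires."""
    styles: set = set()
    for p in world.people:
        styles.update(t.style for t in p.traits(domain))
    return len(styles)


def metrics_report(world: WorldState) -> MetricsReport:
    ledger = world.ledger
    camp_pots = assemblage_counts(world, "pot", "camp")
    camp_points = assemblage_counts(world, "point", "camp")
    band_pots = assemblage_counts(world, "pot", "band")
    band_points = assemblage_counts(world, "point", "band")
    n_pots = sum(sum(v.values()) for v in camp_pots.values())
    n_points = sum(sum(v.values()) for v in camp_points.values())
    return MetricsReport(
        assemblage_size_pots=int(n_pots),
        assemblage_size_points=int(n_points),
        interactions_hunting=ledger.total("hunting"),
        interactions_learning=ledger.total("learning"),
        interactions_trading=ledger.total("trading"),
        interactions_visiting=ledger.total("visiting"),
        jaccard_band_pots=mean_pairwise_jaccard(band_pots),
        jaccard_band_points=mean_pairwise_jaccard(band_points),
        jaccard_camp_pots=mean_pairwise_jaccard(camp_pots),
        jaccard_camp_points=mean_pairwise_jaccard(camp_points),
        n_traits_pots=distinct_traits(world, "pot"),
        n_traits_points=distinct_traits(world, "point"),
        mean_point_prestige=float(np.mean([p.hunt_success
                                           for p in world.people])),
    )
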