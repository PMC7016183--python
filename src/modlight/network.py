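"""Interactome localization statistics for light-up gene lists.

Two statistics quantify whether a gene list is "modular" in a
protein–protein interaction network: the harmonic average shortest-path
distance within the list (disconnected pairs contribute zero reciprocal
distance, so the statistic stays finite-sample friendly and only diverges
when no pair is connected) and the mean pair-normalized betweenness
centrality of the listed genes.  Both are compared against equal-size
uniformly drawn gene sets to form a null distribution.

Shortest paths are unweighted; edge confidence scores are used only for
thresholding at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "GeneNetwork",
    "load_network",
    "harmonic_avg_distance",
    "mean_betweenness",
    "localization_sweep",
    "LocalizationProfile",
    "DEFAULT_CUTOFFS",
]

#: Rank cutoffs swept by powers of two from 100 (upper bound 10,000 excluded:
#: it is not itself a power-of-two step from 100).
DEFAULT_CUTOFFS = (100, 200, 400, 800, 1600, 3200, 6400)


@dataclass
class GeneNetwork:
    """Undirected gene graph with confidence-thresholded edges.

    Isolated nodes listed in the source are retained.  Self-loops are
    dropped and reversed duplicate edges collapse to one.
    """

    graph: nx.Graph
    score_threshold: float = 0.0
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False)
    _betweenness: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))
        self._index = {n: i for i, n in enumerate(self.graph.nodes)}
        self._adjacency = None
        self._betweenness = None

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Sequence[str] = (),
        score_threshold: float = 0.0,
    ) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b, score in edges:
            a, b = str(a), str(b)
            g.add_node(a)
            g.add_node(b)
            if score >= score_threshold and a != b:
                g.add_edge(a, b, score=float(score))
        return cls(g, score_threshold)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def _sparse(self) -> sp.csr_matrix:
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self.graph, nodelist=list(self.graph.nodes), weight=None, format="csr"
            )
        return self._adjacency

    def pairwise_distances(self, genes: Sequence[str]) -> np.ndarray:
        """Unweighted shortest-path distances between the mappable genes.

        Returns a square matrix over the genes present in the network
        (order preserved); unreachable pairs are +inf.
        """
        idx = [self._index[g] for g in genes if g in self._index]
        if not idx:
            return np.empty((0, 0))
        dist = dijkstra(self._sparse(), directed=False, unweighted=True, indices=idx)
        return dist[:, idx]

    def betweenness(self, approx_k: int | None = None, seed: int = 0) -> dict[str, float]:
        """Pair-normalized betweenness centrality, cached after first call.

        ``approx_k`` switches to pivot sampling for large graphs (seeded).
        """
        if self._betweenness is None:
            if approx_k is not None and approx_k < self.n_nodes:
                self._betweenness = nx.betweenness_centrality(
                    self.graph, k=approx_k, normalized=True, seed=seed
                )
            else:
                self._betweenness = nx.betweenness_centrality(self.graph, normalized=True)
        return self._betweenness


def load_network(path, score_threshold: float = 0.0) -> GeneNetwork:
    """Read a STRING-style edge TSV: node1, node2, score.

    A header line is tolerated (detected by a non-numeric third field).
    Edges below the threshold are dropped but their endpoints are kept as
    isolated nodes.
    """
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: malformed score {parts[2]!r}")
            nodes.extend(parts[:2])
            edges.append((parts[0], parts[1], score))
    return GeneNetwork.from_edges(edges, nodes=nodes, score_threshold=score_threshold)


def harmonic_avg_distance(net: GeneNetwork, genes: Iterable[str]) -> float:
    """Harmonic mean shortest-path distance within a gene set.

    H = (number of unordered pairs) / sum of reciprocal distances, where
    disconnected pairs (and genes absent from the network, treated as
    isolated) contribute reciprocal distance 0.  Returns +inf when no pair
    is connected.
    """
    gene_list = sorted(set(genes))
    mappable = [g for g in gene_list if g in net._index]
    if len(gene_list) < 2:
        raise ValueError("need at least 2 genes")
    n_pairs = len(gene_list) * (len(gene_list) - 1) // 2
    if len(mappable) < 2:
        return float("inf")
    dist = net.pairwise_distances(mappable)
    iu = np.triu_indices(len(mappable), k=1)
    d = dist[iu]
    finite = d[np.isfinite(d) & (d > 0)]
    recip_sum = float(np.sum(1.0 / finite))
    if recip_sum == 0.0:
        return float("inf")
    return n_pairs / recip_sum


def mean_betweenness(
    net: GeneNetwork,
    genes: Iterable[str],
    approx_k: int | None = None,
    seed: int = 0,
) -> float:
    """Mean pair-normalized betweenness over a gene set.

    Genes absent from the network count with centrality 0.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ValueError("empty gene set")
    bc = net.betweenness(approx_k=approx_k, seed=seed)
    return float(np.mean([bc.get(g, 0.0) for g in gene_list]))


@dataclass
class LocalizationProfile:
    """Localization of one node's top-ranked genes at one cutoff."""

    layer: int
    node: int
    cutoff: int
    harmonic_distance: float
    mean_betweenness: float
    null_mean: float          # null of the harmonic distance
    null_sd: float
    null_mean_betweenness: float
    null_sd_betweenness: float
    n_null: int

    @property
    def z(self) -> float:
        if self.null_sd == 0:
            return float("nan")
        return (self.harmonic_distance - self.null_mean) / self.null_sd


def _null_distributions(
    net: GeneNetwork,
    size: int,
    n_samples: int,
    rng: np.random.Generator,
    approx_k: int | None,
    with_betweenness: bool,
) -> tuple[np.ndarray, np.ndarray]:
    universe = np.array(net.nodes)
    dists = np.empty(n_samples)
    btws = np.full(n_samples, np.nan)
    for i in range(n_samples):
        draw = rng.choice(universe, size=size, replace=False)
        dists[i] = harmonic_avg_distance(net, draw)
        if with_betweenness:
            btws[i] = mean_betweenness(net, draw, approx_k=approx_k)
    return dists, btws


def localization_sweep(
    net: GeneNetwork,
    lightup_results: Sequence,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    null_samples: int = 50,
    seed: int = 0,
    approx_betweenness_k: int | None = None,
    with_betweenness: bool = True,
) -> list[LocalizationProfile]:
    """Harmonic distance and betweenness of top genes across rank cutoffs.

    The null distribution (equal-size uniform draws from the network's
    nodes) depends only on the cutoff and is shared across nodes.  Cutoffs
    exceeding the gene count are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    profiles: list[LocalizationProfile] = []
    nulls: dict[int, tuple[float, float, float, float]] = {}
    for cutoff in cutoffs:
        if lightup_results and cutoff > len(lightup_results[0].ranked_genes):
            warnings.warn(f"cutoff {cutoff} exceeds gene count; skipped")
            continue
        d, b = _null_distributions(
            net, cutoff, null_samples, rng, approx_betweenness_k, with_betweenness
        )
        finite = d[np.isfinite(d)]
        nulls[cutoff] = (
            float(finite.mean()) if finite.size else float("inf"),
            float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
            float(np.nanmean(b)) if with_betweenness else float("nan"),
            float(np.nanstd(b, ddof=1)) if with_betweenness and len(b) > 1 else float("nan"),
        )
        for res in lightup_results:
            top = res.ranked_genes[:cutoff]
            profiles.append(
                LocalizationProfile(
                    layer=res.layer,
                    node=res.node,
                    cutoff=cutoff,
                    harmonic_distance=harmonic_avg_distance(net, top),
                    mean_betweenness=(
                        mean_betweenness(net, top, approx_k=approx_betweenness_k)
                        if with_betweenness else float("nan")
                    ),
                    null_mean=nulls[cutoff][0],
                    null_sd=nulls[cutoff][1],
                    null_mean_betweenness=nulls[cutoff][2],
                    null_sd_betweenness=nulls[cutoff][3],
                    n_null=null_samples,
                )
            )
    return profiles
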