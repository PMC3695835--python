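"""Y-STR haplotype networks and ASD-based clade dating.

Median-joining (MJ) networks connect observed STR haplotypes through
inferred "median" haplotypes so that the total connection length approaches
the Steiner minimum. Distances are weighted L1 on repeat counts (one
mutational step per repeat unit), the convention for STR data.

Clade age follows the averaged-squared-distance (ASD) estimator: under the
stepwise mutation model the expected squared repeat difference from the
founder haplotype grows linearly, E[ASD] = mu * t, with mu the per-locus
per-generation mutation rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .core import InvalidArgument, StrHaplotype

DEFAULT_MU_LOCUS = 6.9e-4        # per locus per generation (effective rate)
DEFAULT_GENERATION_YEARS = 25.0


@dataclass
class HaplotypeNetwork:
    """Median-joining network over STR haplotypes.

    Nodes are repeat-count tuples; node attributes: ``median`` (bool),
    ``frequency`` (carrier count; 0 for medians). ``length`` is the minimum
    spanning length over the final node set.
    """

    graph: nx.Graph
    loci: tuple[str, ...]
    length: float

    @property
    def median_nodes(self) -> list[tuple[int, ...]]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("median")]

    @property
    def observed_nodes(self) -> list[tuple[int, ...]]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("median")]


def _check_common_loci(haplotypes: Sequence[StrHaplotype]) -> tuple[str, ...]:
    if not haplotypes:
        raise InvalidArgument("at least one haplotype required")
    loci = haplotypes[0].loci
    for h in haplotypes[1:]:
        if h.loci != loci:
            raise InvalidArgument(
                f"inconsistent locus sets: {h.loci} vs {loci}")
    return loci


def _dist(u: tuple[int, ...], v: tuple[int, ...], w: np.ndarray) -> float:
    return float(np.dot(w, np.abs(np.subtract(u, v))))


def _mst_length(nodes: list[tuple[int, ...]], w: np.ndarray) -> float:
    if len(nodes) < 2:
        return 0.0
    g = nx.Graph()
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=_dist(a, b, w))
    return sum(d["weight"] for _, _, d in
               nx.minimum_spanning_edges(g, data=True))


def _feasible_links(nodes: list[tuple[int, ...]], w: np.ndarray,
                    epsilon: float) -> list[tuple]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A pair is linked iff its distance is within epsilon of the minimax path
    weight between the two nodes (epsilon=0 gives the union of all minimum
    spanning trees).
    """
    if len(nodes) == 1:
        return []
    g = nx.Graph()
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=_dist(a, b, w))
    mst = nx.minimum_spanning_tree(g)
    links = []
    for a, b in itertools.combinations(nodes, 2):
        path = nx.shortest_path(mst, a, b)
        minimax = max(mst[u][v]["weight"]
                      for u, v in zip(path[:-1], path[1:]))
        d = g[a][b]["weight"]
        if d <= minimax + epsilon:
            links.append((a, b, d))
    return links


def mj_network(haplotypes: Sequence[StrHaplotype], epsilon: int = 0,
               weights: Optional[Sequence[float]] = None) -> HaplotypeNetwork:
    """Construct a median-joining network.

    Iterates: (i) build the epsilon-relaxed quasi-spanning network over the
    current node set; (ii) propose coordinate-wise medians of node triples
    and accept the one that shrinks the minimum spanning length the most
    (strict decrease required at epsilon=0); (iii) prune medians whose
    removal leaves the spanning length unchanged. Deterministic given input
    order (ties break on node tuples).
    """
    loci = _check_common_loci(haplotypes)
    w = np.ones(len(loci)) if weights is None else np.asarray(weights, float)
    if len(w) != len(loci):
        raise InvalidArgument("weights length != number of loci")

    freq: dict[tuple[int, ...], float] = {}
    for h in haplotypes:
        freq[h.repeats] = freq.get(h.repeats, 0.0) + h.count
    observed = sorted(freq)
    nodes: list[tuple[int, ...]] = list(observed)
    medians: list[tuple[int, ...]] = []

    def current_length() -> float:
        return _mst_length(nodes, w)

    improved = True
    while improved:
        improved = False
        cur = current_length()
        node_set = set(nodes)
        best_gain, best_median = 0.0, None
        for tri in itertools.combinations(sorted(nodes), 3):
            med = tuple(int(np.median([t[i] for t in tri]))
                        for i in range(len(loci)))
            if med in node_set:
                continue
            new_len = _mst_length(nodes + [med], w)
            gain = cur - new_len
            if gain <= 1e-12:  # medians must strictly shorten the network
                continue
            if (gain > best_gain + 1e-12
                    or (abs(gain - best_gain) <= 1e-12
                        and best_median is not None and med < best_median)):
                best_gain, best_median = gain, med
        if best_median is not None:
            nodes.append(best_median)
            medians.append(best_median)
            improved = True

        # prune medians that no longer shorten the network
        pruned = True
        while pruned:
            pruned = False
            cur = current_length()
            for m in list(medians):
                remaining = [x for x in nodes if x != m]
                if _mst_length(remaining, w) <= cur + 1e-12:
                    nodes = remaining
                    medians.remove(m)
                    pruned = True
                    break

    g = nx.Graph()
    for nd in nodes:
        g.add_node(nd, median=nd not in freq, frequency=freq.get(nd, 0.0))
    for a, b, d in _feasible_links(nodes, w, float(epsilon)):
        steps = tuple(int(x) for x in np.subtract(b, a))
        g.add_edge(a, b, weight=d, steps=steps)
    return HaplotypeNetwork(graph=g, loci=loci, length=_mst_length(nodes, w))


def steiner_oracle_length(haplotypes: Sequence[StrHaplotype],
                          weights: Optional[Sequence[float]] = None,
                          max_extra: Optional[int] = None) -> float:
    """Brute-force minimum spanning length allowing Steiner points.

    Exhaustively searches subsets of lattice points inside the coordinate
    bounding box (up to ``n-2`` extra points by default). Exponential: only
    for tiny instances, as an independent check on :func:`mj_network`.
    """
    loci = _check_common_loci(haplotypes)
    w = np.ones(len(loci)) if weights is None else np.asarray(weights, float)
    terminals = sorted({h.repeats for h in haplotypes})
    if len(terminals) == 1:
        return 0.0
    arr = np.array(terminals)
    ranges = [range(arr[:, i].min(), arr[:, i].max() + 1)
              for i in range(arr.shape[1])]
    lattice = [p for p in itertools.product(*ranges) if p not in set(terminals)]
    k_max = max(0, len(terminals) - 2) if max_extra is None else max_extra
    best = _mst_length(terminals, w)
    for k in range(1, k_max + 1):
        for extra in itertools.combinations(lattice, k):
            best = min(best, _mst_length(terminals + list(extra), w))
    return best


def modal_founder(haplotypes: Sequence[StrHaplotype]) -> StrHaplotype:
    """Carrier-frequency-weighted per-locus modal haplotype (ties -> smaller
    repeat count)."""
    loci = _check_common_loci(haplotypes)
    reps = []
    for i in range(len(loci)):
        weight: dict[int, float] = {}
        for h in haplotypes:
            weight[h.repeats[i]] = weight.get(h.repeats[i], 0.0) + h.count
        reps.append(min(weight, key=lambda r: (-weight[r], r)))
    return StrHaplotype(loci, tuple(reps))


def asd_from_founder(haplotypes: Sequence[StrHaplotype],
                     founder: StrHaplotype) -> float:
    """Averaged squared distance: mean over loci of the carrier-weighted mean
    over chromosomes of (repeat - founder repeat)^2."""
    loci = _check_common_loci(haplotypes)
    if founder.loci != loci:
        raise InvalidArgument("founder locus set differs from haplotypes")
    total_w = sum(h.count for h in haplotypes)
    sq = np.zeros(len(loci))
    for h in haplotypes:
        sq += h.count * (np.subtract(h.repeats, founder.repeats) ** 2)
    return float(np.mean(sq / total_w))


def asd_dating(haplotypes: Sequence[StrHaplotype],
               founder: Optional[StrHaplotype] = None,
               mu_locus: float = DEFAULT_MU_LOCUS,
               generation_years: float = DEFAULT_GENERATION_YEARS) -> float:
    """Clade age in years from STR variability around the founder.

    generations = ASD / mu_locus; years = generations * generation_years.
    If no founder is given, the carrier-weighted modal haplotype is used.
    """
    if mu_locus <= 0:
        raise InvalidArgument("mu_locus must be positive")
    if generation_years <= 0:
        raise InvalidArgument("generation_years must be positive")
    if founder is None:
        founder = modal_founder(haplotypes)
    asd = asd_from_founder(haplotypes, founder)
    return asd / mu_locus * generation_years
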