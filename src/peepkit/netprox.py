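"""Disease-module extraction and gene-set proximity on an interaction network.

A *disease module* is the largest connected component formed by a
phenotype-associated gene set within the functional interaction network
(ties broken toward the lexicographically smallest member set).

Proximity between gene sets uses the standard network-medicine "closest"
statistic: for each source gene, the minimum unweighted shortest-path
(hop) distance to any target gene; the summary is the mean of those minima
over mapped, reachable source genes.  The definition is directed —
``closest(A, B)`` need not equal ``closest(B, A)`` — and a gene belonging to
both sets contributes distance 0.  Edge weights present on the network are
deliberately ignored (hop distances only).

``compare_proximity`` evaluates two source sets against the same target,
returns their per-gene distance distributions (whisker-plot data), and can
attach a degree-binned permutation z-score to each: random source sets of
the same size are drawn with the degree distribution of the observed set
preserved (log2 degree bins), and the observed mean distance is standardized
against that null.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .dataio import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseModule:
    genes: frozenset[str]
    unmapped: tuple[str, ...]
    n_components: int


def disease_module(genes: Iterable[str], network: nx.Graph) -> DiseaseModule:
    """Largest connected component of the subgraph induced by ``genes``."""
    genes = set(genes)
    mapped = genes & set(network.nodes)
    unmapped = tuple(sorted(genes - mapped))
    if unmapped:
        log.info("disease module: %d genes not in network", len(unmapped))
    if not mapped:
        raise ValidationError("no input genes are present in the network")
    sub = network.subgraph(mapped)
    components = [sorted(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), c))
    return DiseaseModule(
        genes=frozenset(components[0]), unmapped=unmapped, n_components=len(components)
    )


def _multi_source_bfs(network: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Unweighted hop distances from a set of source nodes (plain BFS;
    independent of any edge weights the graph carries)."""
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        node = queue.popleft()
        d = dist[node] + 1
        for neighbor in network[node]:
            if neighbor not in dist:
                dist[neighbor] = d
                queue.append(neighbor)
    return dist


@dataclass(frozen=True)
class ProximityResult:
    """Directed closest-distance statistics from a source set to a target set."""

    source_set: tuple[str, ...]
    target_set: tuple[str, ...]
    distances: dict[str, int]  # mapped, reachable source genes only
    closest_distance: float
    n_unmapped_source: int
    n_unmapped_target: int
    n_unreachable: int


def closest_distance(
    source_set: Iterable[str], target_set: Iterable[str], network: nx.Graph
) -> ProximityResult:
    """Mean over mapped source genes of the min hop distance to the target set.

    Unmapped genes and source genes unreachable from the target set are
    excluded from the mean and counted in the result.
    """
    source = sorted(set(source_set))
    target = sorted(set(target_set))
    nodes = set(network.nodes)
    mapped_source = [g for g in source if g in nodes]
    mapped_target = [g for g in target if g in nodes]
    if not mapped_source:
        raise ValidationError("no source genes mapped to the network")
    if not mapped_target:
        raise ValidationError("no target genes mapped to the network")
    dist_from_target = _multi_source_bfs(network, mapped_target)
    distances: dict[str, int] = {}
    n_unreachable = 0
    for gene in mapped_source:
        if gene in dist_from_target:
            distances[gene] = dist_from_target[gene]
        else:
            n_unreachable += 1
    if n_unreachable:
        log.info("%d source genes unreachable from the target set", n_unreachable)
    mean = float(np.mean(list(distances.values()))) if distances else float("nan")
    return ProximityResult(
        source_set=tuple(source),
        target_set=tuple(target),
        distances=distances,
        closest_distance=mean,
        n_unmapped_source=len(source) - len(mapped_source),
        n_unmapped_target=len(target) - len(mapped_target),
        n_unreachable=n_unreachable,
    )


def _degree_bins(network: nx.Graph) -> dict[int, list[str]]:
    bins: dict[int, list[str]] = {}
    for node, degree in network.degree():
        key = int(math.log2(degree)) if degree > 0 else -1
        bins.setdefault(key, []).append(node)
    for members in bins.values():
        members.sort()
    return bins


def _permutation_null(
    observed: ProximityResult,
    network: nx.Graph,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Degree-binned permutation null for the closest distance.

    Returns (null mean, null SD, z-score of the observed mean).
    """
    bins = _degree_bins(network)
    degrees = dict(network.degree())
    source_bins = [
        int(math.log2(degrees[g])) if degrees[g] > 0 else -1
        for g in observed.source_set
        if g in degrees
    ]
    target = list(observed.target_set)
    null_means = np.empty(n_permutations)
    for i in range(n_permutations):
        random_set = {
            bins[key][int(rng.integers(len(bins[key])))] for key in source_bins
        }
        null_means[i] = closest_distance(random_set, target, network).closest_distance
    null_mean = float(np.mean(null_means))
    null_sd = float(np.std(null_means, ddof=1)) if n_permutations > 1 else float("nan")
    z = (observed.closest_distance - null_mean) / null_sd if null_sd else float("nan")
    return null_mean, null_sd, float(z)


@dataclass(frozen=True)
class ProximityComparison:
    """Two source sets measured against the same target set."""

    result_a: ProximityResult
    result_b: ProximityResult
    z_a: float | None = None
    z_b: float | None = None
    null_mean_a: float | None = None
    null_mean_b: float | None = None

    @property
    def a_closer(self) -> bool:
        return self.result_a.closest_distance < self.result_b.closest_distance


def compare_proximity(
    set_a: Iterable[str],
    set_b: Iterable[str],
    target_set: Iterable[str],
    network: nx.Graph,
    n_permutations: int = 0,
    seed: int | None = None,
) -> ProximityComparison:
    """Closest distances of two gene sets to a common target, optionally with
    degree-binned permutation z-scores (``n_permutations > 0``)."""
    if n_permutations < 0:
        raise ValidationError("n_permutations must be >= 0")
    result_a = closest_distance(set_a, target_set, network)
    result_b = closest_distance(set_b, target_set, network)
    if n_permutations == 0:
        return ProximityComparison(result_a=result_a, result_b=result_b)
    rng = np.random.default_rng(seed)
    mean_a, _, z_a = _permutation_null(result_a, network, n_permutations, rng)
    mean_b, _, z_b = _permutation_null(result_b, network, n_permutations, rng)
    return ProximityComparison(
        result_a=result_a,
        result_b=result_b,
        z_a=z_a,
        z_b=z_b,
        null_mean_a=mean_a,
        null_mean_b=mean_b,
    )
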