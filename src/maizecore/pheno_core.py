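"""Phenotypic core collection construction by stepwise cluster sampling.

A core collection is a subset of accessions chosen to represent the trait
diversity of the full panel with less redundancy.  The sampler here follows
the stepwise cluster-cut procedure: standardize traits, build a genetic
distance matrix (Euclidean or Mahalanobis), cluster agglomeratively under a
chosen linkage, cut the dendrogram into ``k = round(ratio * n)`` clusters,
and keep one representative per cluster.  Within-cluster allocation is
either *random* (seeded uniform draw) or *deviation* (the member with the
largest sum of squared deviations from its cluster centroid in standardized
trait space — the choice that maximizes retained variance, consistent with
core collections whose trait CVs exceed the source population's).

A strategy grid enumerates the Cartesian product of distance x ratio x
allocation x linkage, mirroring the multi-strategy searches used when
optimizing core sampling schemes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cluster_engine import (
    DistanceMatrix,
    MergeTree,
    agglomerate,
    cut_tree,
    euclidean_distance,
    mahalanobis_distance,
)
from .pheno_stats import TraitMatrix, zstandardize

__all__ = ["SamplingStrategy", "CoreSet", "sample_core", "strategy_grid"]


def round_half_away(x: float) -> int:
    """round() with halves away from zero (so 0.5 -> 1, 2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SamplingStrategy:
    """One point of the sampling-strategy grid."""

    distance: str = "euclidean"        # euclidean | mahalanobis
    ratio: float = 0.2                 # sampling proportion in (0, 1]
    allocation: str = "deviation"      # random | deviation
    linkage: str = "flexible"
    seed: int = 0
    flexible_beta: float = -0.25

    def __post_init__(self) -> None:
        if self.distance not in ("euclidean", "mahalanobis"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.allocation not in ("random", "deviation"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError("ratio must be in (0, 1]")

    def label(self) -> str:
        return f"{self.distance}+{self.ratio:g}+{self.allocation}+{self.linkage}"


@dataclass
class CoreSet:
    """Selected core accessions and the complementary reserve set."""

    selected: list[str]
    reserve: list[str]
    strategy: SamplingStrategy

    def __post_init__(self) -> None:
        if set(self.selected) & set(self.reserve):
            raise ValueError("selected and reserve sets overlap")

    @property
    def all_ids(self) -> list[str]:
        return self.selected + self.reserve


def _distance_for(strategy: SamplingStrategy, X: np.ndarray, ids: list[str]) -> DistanceMatrix:
    if strategy.distance == "euclidean":
        return euclidean_distance(X, ids)
    return mahalanobis_distance(X, ids)


def sample_core(
    tm: TraitMatrix,
    strategy: SamplingStrategy,
    *,
    tree: MergeTree | None = None,
) -> CoreSet:
    """Draw a core collection from ``tm`` under one sampling strategy.

    Traits are z-standardized (missing values mean-imputed) before distance
    computation; ``k = round(ratio * n)`` clusters are cut and one
    representative kept per cluster.  A precomputed ``tree`` for the same
    distance/linkage may be passed to avoid re-clustering across ratios.
    Deviation allocation is deterministic; random allocation depends only on
    ``strategy.seed``.
    """
    n = tm.n
    k = round_half_away(strategy.ratio * n)
    if k < 1:
        raise ValueError("ratio * n < 1: no accession would be selected")
    if k > n:
        raise ValueError("cannot select more accessions than exist")

    z = zstandardize(TraitMatrix(tm.ids, tm.traits, tm.imputed(), dict(tm.direction)))
    X = z.values
    if tree is None:
        D = _distance_for(strategy, X, tm.ids)
        tree = agglomerate(D, strategy.linkage, strategy.flexible_beta)
    labels = cut_tree(tree, k)

    rng = np.random.default_rng(strategy.seed)
    selected: list[str] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 1:
            selected.append(tm.ids[members[0]])
            continue
        if strategy.allocation == "random":
            selected.append(tm.ids[rng.choice(members)])
        else:  # deviation: most deviant member from the cluster centroid
            centroid = X[members].mean(axis=0)
            dev = ((X[members] - centroid) ** 2).sum(axis=1)
            ties = members[dev == dev.max()]
            selected.append(min(tm.ids[t] for t in ties))
    sel_set = set(selected)
    reserve = [a for a in tm.ids if a not in sel_set]
    # preserve panel order in the selected list too
    selected = [a for a in tm.ids if a in sel_set]
    return CoreSet(selected=selected, reserve=reserve, strategy=strategy)


def strategy_grid(
    tm: TraitMatrix,
    distances: list[str],
    ratios: list[float],
    allocations: list[str],
    linkages: list[str],
    seed: int = 0,
) -> list[tuple[SamplingStrategy, CoreSet]]:
    """Enumerate the strategy Cartesian product and sample a core for each.

    Factors are enumerated in deterministic (given) order; trees are cached
    per (distance, linkage) since cutting at a different ratio reuses the
    same merge history.
    """
    for name, factor in (
        ("distances", distances),
        ("ratios", ratios),
        ("allocations", allocations),
        ("linkages", linkages),
    ):
        if not factor:
            raise ValueError(f"empty strategy factor: {name}")
    z = zstandardize(TraitMatrix(tm.ids, tm.traits, tm.imputed(), dict(tm.direction)))
    trees: dict[tuple[str, str], MergeTree] = {}
    out: list[tuple[SamplingStrategy, CoreSet]] = []
    for dist, ratio, alloc, link in itertools.product(distances, ratios, allocations, linkages):
        s = SamplingStrategy(distance=dist, ratio=ratio, allocation=alloc, linkage=link, seed=seed)
        key = (dist, link)
        if key not in trees:
            D = _distance_for(s, z.values, tm.ids)
            trees[key] = agglomerate(D, link, s.flexible_beta)
        out.append((s, sample_core(tm, s, tree=trees[key])))
    return out
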