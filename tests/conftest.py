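"""Shared fixtures: small synthetic panels built at test time."""

import numpy as np
import pandas as pd
import pytest

from maizecore import (
    GenoSimConfig,
    GenotypeMatrix,
    PhenoSimConfig,
    TraitMatrix,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def trait_panel() -> TraitMatrix:
    """100-accession panel with the default 19-trait characterization."""
    return simulate_phenotypes(PhenoSimConfig(n_accessions=100, seed=11))


@pytest.fixture(scope="session")
def small_geno() -> GenotypeMatrix:
    """30 x 80 structured genotype matrix with missing calls."""
    return simulate_genotypes(
        GenoSimConfig(n_accessions=30, n_loci=80, n_subpops=3, missing_rate=0.05, seed=12)
    ).genotypes


def toy_genotypes(calls: np.ndarray, ids=None) -> GenotypeMatrix:
    """Wrap a raw call array in a GenotypeMatrix with a trivial locus map."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    loci = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(L)],
            "chrom": "chr1",
            "pos": np.arange(1, L + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(ids or [f"A{i}" for i in range(n)], loci, calls)


def exact_moments_column(n: int, mean: float, sd: float, seed: int) -> np.ndarray:
    """A column whose sample mean/SD (ddof=1) equal the targets exactly."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def two_part_panel() -> tuple[TraitMatrix, TraitMatrix]:
    """A 19-trait population engineered for exact MD/VD counts.

    The core (50 accessions) and the 50-accession complement are built from
    exactly standardized Gaussian columns so that, core vs full:

    * trait 0: means differ (Welch t significant), variances equal (F = 1);
    * traits 1-15: means exactly equal (t = 0), core variance 99/(49(1+c^2))
      times the full's with c = 5 (F strongly significant);
    * traits 16-18: identical construction in both halves (neither test
      significant).

    Hence exactly 1 of 19 significant t-tests and 15 significant F-tests.
    """
    n_half, m = 50, 19
    core = np.empty((n_half, m))
    comp = np.empty((n_half, m))
    for j in range(m):
        zc = exact_moments_column(n_half, 0.0, 1.0, seed=100 + j)
        zr = exact_moments_column(n_half, 0.0, 1.0, seed=200 + j)
        if j == 0:
            # mean shift of one core-SD; complement variance tuned so the
            # pooled full variance equals the core variance exactly
            sigma, delta = 1.0, 1.0
            var2 = (50 * sigma**2 - 25 * delta**2) / 49.0
            core[:, j] = 10.0 + sigma * zc
            comp[:, j] = 10.0 + delta + np.sqrt(var2) * zr
        elif 1 <= j <= 15:
            core[:, j] = zc            # sd 1
            comp[:, j] = 5.0 * zr      # sd 5, same mean
        else:
            core[:, j] = 3.0 + zc
            comp[:, j] = 3.0 + zr
    traits = [f"t{j}" for j in range(m)]
    core_ids = [f"C{i:03d}" for i in range(n_half)]
    comp_ids = [f"R{i:03d}" for i in range(n_half)]
    full = TraitMatrix(core_ids + comp_ids, traits, np.vstack([core, comp]))
    return TraitMatrix(core_ids, traits, core), full


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random additive tree; returns (leaf names, path-length matrix).

    Built by attaching each new leaf to a uniformly chosen edge, so the
    metric is exactly additive and the realizing tree is unique.
    """
    import networkx as nx

    G = nx.Graph()
    for leaf in ("L0", "L1", "L2"):
        G.add_edge(leaf, "x0", weight=rng.uniform(0.5, 2.0))
    nxt = 1
    for i in range(3, n_leaves):
        u, v = list(G.edges())[rng.integers(0, G.number_of_edges())]
        w = G[u][v]["weight"]
        f = rng.uniform(0.2, 0.8)
        mid = f"x{nxt}"
        nxt += 1
        G.remove_edge(u, v)
        G.add_edge(u, mid, weight=w * f)
        G.add_edge(mid, v, weight=w * (1.0 - f))
        G.add_edge(f"L{i}", mid, weight=rng.uniform(0.5, 2.0))
    leaves = [f"L{i}" for i in range(n_leaves)]
    sp = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = np.array([[sp[a][b] for b in leaves] for a in leaves])
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return leaves, D
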