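"""Genotypic core selection and integration with the phenotypic core.

The genotypic core maximizes the mean entry-to-nearest-entry (E-NE)
distance — the average, over selected accessions, of each entry's distance
to its closest other entry — on the modified Rogers distance.  Large E-NE
spreads the core across the genotype space and suppresses near-duplicates.
The optimizer is a deterministic greedy construction (seeded from the most
distant pair) followed by steepest-ascent single-swap local search; this is
a single-objective surrogate for the multi-objective engines used
interactively in core-collection software.

Diversity retention is reported as allele coverage: the share of
(locus, allele) pairs observed in the full panel that are still observed in
the core.  Finally, phenotypic and genotypic cores are integrated by union,
with the complement kept as the reserve set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster_engine import DistanceMatrix
from .geno_div import MISSING, GenotypeMatrix, diversity_stats

__all__ = [
    "GenoCoreResult",
    "IntegratedCore",
    "modified_rogers_distance",
    "select_geno_core",
    "allele_coverage",
    "integrate_cores",
]


@dataclass
class GenoCoreResult:
    """A genotypic core with its E-NE objective and diversity retention."""

    selected: list[str]
    ratio: float
    objective: float
    allele_coverage_percent: float
    diversity: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class IntegratedCore:
    """Union of phenotypic and genotypic cores plus the reserve set."""

    final: list[str]
    overlap: list[str]
    reserve: list[str]

    @property
    def size(self) -> int:
        return len(self.final)


def modified_rogers_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise modified Rogers distances on call dosages.

    With per-accession alt-allele frequency x = call/2 in {0, 1/2, 1}, the
    biallelic modified Rogers distance reduces to
    ``d(a,b) = sqrt(mean over co-called loci of (x_a - x_b)^2)``, bounded in
    [0, 1] with 1 attained by opposite homozygotes at every locus.  A pair
    with zero co-called loci is rejected.
    """
    x = g.dosage() / 2.0
    n = g.n
    d = np.zeros((n, n))
    for i in range(n):
        diff2 = (x[i] - x) ** 2
        co = ~np.isnan(diff2)
        n_co = co.sum(axis=1)
        zero = np.flatnonzero(n_co == 0)
        zero = zero[zero != i]
        if zero.size:
            j = int(zero[0])
            raise ValueError(
                f"accessions {g.ids[i]!r} and {g.ids[j]!r} share no co-called locus"
            )
        with np.errstate(invalid="ignore"):
            d[i] = np.sqrt(np.nansum(diff2, axis=1) / n_co)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.ids), d)


def _ene_objective(D: np.ndarray, idx: np.ndarray) -> float:
    """Mean entry-to-nearest-entry distance of the subset ``idx``."""
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def select_geno_core(
    g: GenotypeMatrix,
    ratio: float,
    seed: int = 0,
    max_iters: int = 1000,
    distance: DistanceMatrix | None = None,
) -> GenoCoreResult:
    """Select a genotypic core of size ``round(ratio * n)`` maximizing E-NE.

    Greedy construction starts from the maximally distant accession pair and
    repeatedly adds the accession giving the best updated objective; a
    steepest-ascent single-swap search then runs until no improving swap
    exists or ``max_iters`` swaps were applied.  Fully deterministic given
    the inputs (ties break on the smallest index); ``seed`` is recorded in
    the result.
    """
    from .pheno_core import round_half_away

    n = g.n
    k = round_half_away(ratio * n)
    if k < 2:
        raise ValueError("ratio too small: core needs at least 2 entries")
    if k > n:
        raise ValueError("ratio > 1")
    D = (distance or modified_rogers_distance(g)).matrix

    if k == n:
        sel = np.arange(n)
    else:
        # greedy: start from the most distant pair
        iu = np.triu_indices(n, 1)
        best = int(np.argmax(D[iu]))
        sel_list = [int(iu[0][best]), int(iu[1][best])]
        in_sel = np.zeros(n, dtype=bool)
        in_sel[sel_list] = True
        nn = D[np.ix_(sel_list, sel_list)].copy()
        np.fill_diagonal(nn, np.inf)
        nn = nn.min(axis=1)  # nearest-entry distance per selected member
        while len(sel_list) < k:
            cand = np.flatnonzero(~in_sel)
            Dsc = D[np.ix_(sel_list, cand)]              # (|sel|, |cand|)
            new_nn_sum = np.minimum(nn[:, None], Dsc).sum(axis=0)
            cand_nn = Dsc.min(axis=0)
            obj = (new_nn_sum + cand_nn) / (len(sel_list) + 1)
            c = int(cand[np.argmax(obj)])
            nn = np.minimum(nn, D[sel_list, c])
            nn = np.append(nn, D[c, sel_list].min())
            sel_list.append(c)
            in_sel[c] = True
        sel = np.array(sel_list)

        # steepest-ascent single-swap local search
        current = _ene_objective(D, sel)
        swaps = 0
        improved = True
        while improved and swaps < max_iters:
            improved = False
            best_gain, best_swap = 1e-12, None
            outside = np.flatnonzero(~np.isin(np.arange(n), sel))
            for si in range(k):
                trial = sel.copy()
                for c in outside:
                    trial[si] = c
                    val = _ene_objective(D, trial)
                    if val - current > best_gain:
                        best_gain, best_swap = val - current, (si, int(c))
                trial[si] = sel[si]
            if best_swap is not None:
                si, c = best_swap
                sel[si] = c
                current += best_gain
                swaps += 1
                improved = True
        sel = np.sort(sel)

    selected = [g.ids[i] for i in sel]
    coverage = allele_coverage(selected, g)
    try:
        _, panel = diversity_stats(g.subset(selected))
    except ValueError:
        panel = {}
        warnings.warn("core too sparse for diversity statistics")
    return GenoCoreResult(
        selected=selected,
        ratio=ratio,
        objective=_ene_objective(D, sel),
        allele_coverage_percent=coverage,
        diversity=panel,
        seed=seed,
    )


def _alleles_present(g: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """(L, 2) boolean: is the ref / alt allele observed among ``rows``."""
    calls = g.calls[rows]
    ref = ((calls == 0) | (calls == 1)).any(axis=0)
    alt = ((calls == 2) | (calls == 1)).any(axis=0)
    return np.column_stack([ref, alt])


def allele_coverage(core_ids: list[str], g: GenotypeMatrix) -> float:
    """Percent of the panel's observed (locus, allele) pairs kept in the core."""
    if not core_ids:
        raise ValueError("empty core")
    pos = {a: i for i, a in enumerate(g.ids)}
    idx = np.array([pos[a] for a in core_ids])
    full = _alleles_present(g, np.arange(g.n))
    core = _alleles_present(g, idx)
    total = int(full.sum())
    if total == 0:
        raise ValueError("no observed alleles in panel")
    return 100.0 * float((core & full).sum()) / total


def integrate_cores(
    pheno_ids: list[str], geno_ids: list[str], all_ids: list[str]
) -> IntegratedCore:
    """Union of phenotypic and genotypic cores; complement is the reserve.

    Order of ``all_ids`` is preserved in every output list.  Unknown ids are
    rejected.
    """
    universe = set(all_ids)
    unknown = (set(pheno_ids) | set(geno_ids)) - universe
    if unknown:
        raise ValueError(f"unknown accession ids: {sorted(unknown)[:5]}")
    p, q = set(pheno_ids), set(geno_ids)
    final = [a for a in all_ids if a in p or a in q]
    overlap = [a for a in all_ids if a in p and a in q]
    reserve = [a for a in all_ids if a not in p and a not in q]
    return IntegratedCore(final=final, overlap=overlap, reserve=reserve)
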