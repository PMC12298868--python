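"""Synthetic germplasm panels with the structure the pipeline assumes.

No public accession-level dataset accompanies the kind of inbred-line panel
this pipeline targets, so every downstream stage is exercised on simulated
data whose statistical structure matches the study conditions:

* **Phenotypes** — a Gaussian copula with a user-supplied trait correlation
  matrix; each trait column is affinely rescaled so the realized sample
  mean/SD equal the targets exactly, making CV and diversity-index checks
  deterministic.  The default trait set is a published 19-trait maize panel
  characterization (means and SDs as printed).
* **Genotypes** — the Balding–Nichols model: ancestral allele frequency
  p ~ Uniform(range); each of K subpopulations draws its frequency from
  Beta(p(1-F)/F, (1-p)(1-F)/F) with a single differentiation parameter
  F = Fst; inbred accessions are drawn homozygous from their subpopulation
  frequency except heterozygous with a small residual probability
  (default 0.03, giving panel Ho near 0.03); calls are masked missing at a
  per-call rate.  Loci are laid out on chromosomes with random positions.
* **Germination stress indicators** — five latent tolerance groups with
  fixed group means plus Gaussian noise; group sizes follow the configured
  proportions via largest-remainder apportionment, and the true labels are
  returned for recovery tests.
* **Model-selection log-likelihoods** — replicate L(K) tables whose mean is
  piecewise linear with a slope change only at the true K, so the Evanno
  delta-K post-processor has a constructed optimum.

Every generator takes a seed and is bit-reproducible; seeds are recorded in
output metadata.  Known simplifications: no skewness injection (downstream
statistics depend only on moments/correlations), no linkage disequilibrium,
no pedigree, single F for all subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_div import MISSING, GenotypeMatrix
from .pheno_stats import HIGHER, TraitMatrix
from .salt_class import IndicatorMatrix

__all__ = [
    "DEFAULT_TRAITS",
    "PhenoSimConfig",
    "GenoSimConfig",
    "StressSimConfig",
    "GenotypeSimResult",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_germination",
    "simulate_structure_likelihoods",
]

#: (name, mean, sd) for the default 19-trait quantitative characterization
DEFAULT_TRAITS: list[tuple[str, float, float]] = [
    ("growth_period", 148.47, 6.571),
    ("tassel_branch_number", 7.78, 4.314),
    ("plant_height", 203.36, 28.659),
    ("ear_position_height", 76.22, 19.758),
    ("ear_stem_length", 8.95, 3.832),
    ("ear_length", 16.57, 2.935),
    ("ear_thickness", 4.58, 0.515),
    ("ear_row_number", 14.8, 2.533),
    ("row_grain_number", 27.05, 5.989),
    ("ear_type", 2.12, 0.832),
    ("grain_length", 10.24, 1.29),
    ("grain_width", 8.63, 0.938),
    ("grain_thickness", 4.94, 0.632),
    ("grain_type", 1.84, 0.733),
    ("hundred_grain_weight", 28.6, 5.795),
    ("total_grain_per_ear", 99.19, 40.249),
    ("dry_weight_per_ear", 125.49, 50.424),
    ("seed_emergence_rate", 0.79, 0.074),
    ("plot_yield", 1547.0, 875.683),
]


def _default_trait_specs() -> list[tuple[str, float, float, str]]:
    return [(n, m, s, HIGHER) for n, m, s in DEFAULT_TRAITS]


@dataclass
class PhenoSimConfig:
    """Gaussian-copula phenotype simulation settings.

    ``traits`` entries are (name, target_mean, target_sd, direction);
    ``correlation`` is a symmetric PSD matrix with unit diagonal (identity
    when omitted — the real panel's trait correlation matrix is not public,
    so a correlation structure must be user-supplied).
    """

    n_accessions: int = 588
    traits: list[tuple[str, float, float, str]] = field(default_factory=_default_trait_specs)
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        for name, _, sd, _ in self.traits:
            if sd < 0:
                raise ValueError(f"trait {name!r}: target_sd must be >= 0")
        m = len(self.traits)
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (m, m):
                raise ValueError("correlation shape does not match trait count")
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValueError("correlation must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-12):
                raise ValueError("correlation must have unit diagonal")
            lam = np.linalg.eigvalsh(c).min()
            if lam < -1e-10:
                raise ValueError(
                    f"correlation is not positive semidefinite (smallest eigenvalue {lam:.3e})"
                )


def simulate_phenotypes(config: PhenoSimConfig) -> TraitMatrix:
    """Simulate an accession x trait table under a Gaussian copula.

    Each column is affinely rescaled so the realized sample mean and SD
    (``ddof=1``) equal the targets to machine precision; a zero target SD
    yields a constant column at the target mean.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_accessions, len(config.traits)
    z = rng.standard_normal((n, m))
    if config.correlation is not None:
        evals, evecs = np.linalg.eigh(np.asarray(config.correlation, dtype=float))
        factor = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        z = z @ factor.T
    values = np.empty((n, m))
    direction = {}
    names = []
    for j, (name, mean, sd, direc) in enumerate(config.traits):
        names.append(name)
        direction[name] = direc
        if sd == 0.0:
            values[:, j] = mean
            continue
        col = z[:, j]
        realized_sd = col.std(ddof=1)
        if realized_sd == 0.0:  # pathological tiny-n draw
            values[:, j] = mean
            continue
        values[:, j] = (col - col.mean()) / realized_sd * sd + mean
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    return TraitMatrix(ids, names, values, direction)


@dataclass
class GenoSimConfig:
    """Balding–Nichols genotype simulation settings for an inbred panel."""

    n_accessions: int = 588
    n_loci: int = 2000
    n_subpops: int = 6
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    residual_het_rate: float = 0.03
    missing_rate: float = 0.005
    chrom_sizes: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name, p in (("residual_het_rate", self.residual_het_rate),
                        ("missing_rate", self.missing_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.n_subpops < 1 or self.n_accessions < self.n_subpops:
            raise ValueError("need n_accessions >= n_subpops >= 1")
        if self.chrom_sizes is None:
            # ten chromosomes, loci split as evenly as possible
            base, extra = divmod(self.n_loci, 10)
            self.chrom_sizes = [base + (1 if c < extra else 0) for c in range(10)]
        if sum(self.chrom_sizes) != self.n_loci:
            raise ValueError("chrom_sizes must sum to n_loci")


@dataclass
class GenotypeSimResult:
    """Simulated genotypes plus the true subpopulation labels."""

    genotypes: GenotypeMatrix
    subpop: np.ndarray
    subpop_freqs: np.ndarray      # (K, L) per-subpopulation alt frequencies
    config: GenoSimConfig


def simulate_genotypes(config: GenoSimConfig) -> GenotypeSimResult:
    """Simulate a structured inbred SNP panel under Balding–Nichols.

    Ancestral alt frequency p ~ Uniform(ancestral_maf_range); subpopulation
    frequency q ~ Beta(p(1-F)/F, (1-p)(1-F)/F).  An accession in
    subpopulation s is heterozygous with probability ``residual_het_rate``,
    otherwise an alt homozygote with probability q_s, so Ho equals the
    residual rate in expectation.  Calls are masked missing independently.
    """
    rng = np.random.default_rng(config.seed)
    n, L, K, F = config.n_accessions, config.n_loci, config.n_subpops, config.fst
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=L)
    scale = (1.0 - F) / F
    q = rng.beta(p * scale, (1.0 - p) * scale, size=(K, L))
    subpop = np.arange(n) % K
    subpop.sort()
    u = rng.uniform(size=(n, L))
    calls = np.where(u < q[subpop], 2, 0).astype(np.int8)
    if config.residual_het_rate > 0:
        het = rng.uniform(size=(n, L)) < config.residual_het_rate
        calls[het] = 1
    if config.missing_rate > 0:
        miss = rng.uniform(size=(n, L)) < config.missing_rate
        calls[miss] = MISSING

    records = []
    j = 0
    for c, size in enumerate(config.chrom_sizes, start=1):
        if size == 0:
            continue
        span = max(size * 1000, size)
        pos = np.sort(rng.choice(span, size=size, replace=False)) + 1
        for k in range(size):
            records.append(
                {"id": f"snp{j + 1:06d}", "chrom": f"chr{c}", "pos": int(pos[k]),
                 "ref": "A", "alt": "G"}
            )
            j += 1
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    g = GenotypeMatrix(ids, pd.DataFrame(records), calls)
    return GenotypeSimResult(genotypes=g, subpop=subpop, subpop_freqs=q, config=config)


def _default_group_means() -> np.ndarray:
    # five tolerance plateaus, six indicators on a germination-rate-like scale
    base = np.array([0.90, 0.75, 0.55, 0.35, 0.15])
    return np.tile(base[:, None], (1, 6))


def _default_group_proportions() -> tuple[float, ...]:
    # empirical five-group split of a germinated core panel (4/14/47/64/43 of 172)
    return (4 / 172, 14 / 172, 47 / 172, 64 / 172, 43 / 172)


@dataclass
class StressSimConfig:
    """Latent-group germination-indicator simulation settings."""

    n_accessions: int = 172
    n_indicators: int = 6
    group_means: np.ndarray = field(default_factory=_default_group_means)
    noise_sd: float = 0.02
    group_proportions: tuple[float, ...] = field(default_factory=_default_group_proportions)
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_means = np.asarray(self.group_means, dtype=float)
        if self.group_means.shape != (5, self.n_indicators):
            raise ValueError("group_means must be 5 x n_indicators")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.group_proportions) != 5:
            raise ValueError("need 5 group proportions")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")


def _apportion(n: int, proportions) -> np.ndarray:
    """Largest-remainder apportionment of n items to the proportions."""
    quota = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    return counts


def simulate_germination(config: StressSimConfig) -> tuple[IndicatorMatrix, np.ndarray]:
    """Simulate stress indicators with latent tolerance groups.

    Group sizes follow largest-remainder apportionment of the proportions;
    indicator value = group mean + Gaussian noise.  Returns the indicator
    matrix and the true group index (0 = most tolerant) per accession.
    """
    rng = np.random.default_rng(config.seed)
    counts = _apportion(config.n_accessions, config.group_proportions)
    labels = np.repeat(np.arange(5), counts)
    values = config.group_means[labels] + rng.normal(
        0.0, config.noise_sd, size=(config.n_accessions, config.n_indicators)
    )
    ids = [f"ACC{i + 1:04d}" for i in range(config.n_accessions)]
    names = [f"indicator_{j + 1}" for j in range(config.n_indicators)]
    im = IndicatorMatrix(ids, names, values, {n: HIGHER for n in names})
    return im, labels


def simulate_structure_likelihoods(
    true_k: int,
    k_range: tuple[int, int] = (1, 10),
    reps: int = 3,
    seed: int = 0,
    base_logl: float = -60000.0,
    slope_before: float = 2000.0,
    slope_after: float = 200.0,
    noise_sd: float = 20.0,
) -> pd.DataFrame:
    """Replicate L(K) table with a slope change only at ``true_k``.

    Mean log-likelihood rises steeply up to the true number of
    subpopulations and flattens beyond it; per-replicate Gaussian noise
    gives the Evanno denominator a non-zero SD.  Requires >= 3 replicates.
    """
    kmin, kmax = k_range
    if not kmin <= true_k <= kmax:
        raise ValueError("true_k outside k_range")
    if reps < 3:
        raise ValueError("delta-K needs >= 3 replicates for the SD")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(kmin, kmax + 1):
        mean = (
            base_logl
            + slope_before * (min(k, true_k) - kmin)
            + slope_after * max(0, k - true_k)
        )
        for rep in range(1, reps + 1):
            rows.append({"K": k, "rep": rep, "logL": mean + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)
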