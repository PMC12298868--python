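"""Descriptive statistics and diversity measures for quantitative trait tables.

The trait table is the phenotypic half of a germplasm characterization:
``n`` accessions scored for ``m`` quantitative traits (plant architecture,
ear morphology, grain characteristics, yield).  This module provides the
summaries a germplasm curator reports per trait — moments, coefficient of
variation (CV), the Shannon–Weaver genetic diversity index (GDI) over
frequency classes — plus trait correlation, PCA on the correlation matrix,
and z-standardization used upstream of distance computation.

Conventions used throughout the package:

* sample standard deviation (``ddof=1``) everywhere, including z-scores;
* kurtosis is excess kurtosis (normal distribution = 0), bias-corrected;
* missing trait values are excluded pairwise for raw summaries and
  mean-imputed only for PCA / distance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitMatrix",
    "PCAResult",
    "summarize_traits",
    "shannon_weaver_gdi",
    "correlate_traits",
    "pca_traits",
    "zstandardize",
]

HIGHER = "higher"
LOWER = "lower"


@dataclass
class TraitMatrix:
    """Accessions x quantitative traits, NaN for missing values.

    ``direction`` records, per trait, whether larger values are favourable
    (``"higher"``) or unfavourable (``"lower"``); it is only consulted by
    membership-function scoring, not by the statistics here.
    """

    ids: list[str]
    traits: list[str]
    values: np.ndarray
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.ids) != n or len(self.traits) != m:
            raise ValueError("id/trait labels do not match value shape")
        if len(set(self.ids)) != n:
            raise ValueError("accession ids must be unique")
        if len(set(self.traits)) != m:
            raise ValueError("trait names must be unique")
        if m < 1:
            raise ValueError("need at least one trait")
        if np.isnan(self.values).all(axis=0).any():
            raise ValueError("all-missing trait column")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.traits)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, direction: dict[str, str] | None = None) -> "TraitMatrix":
        return cls(
            ids=[str(i) for i in df.index],
            traits=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            direction=dict(direction or {}),
        )

    def subset(self, ids: list[str]) -> "TraitMatrix":
        """Row subset preserving the order of ``ids``."""
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"unknown accession ids: {missing[:5]}")
        idx = [pos[a] for a in ids]
        return TraitMatrix(list(ids), list(self.traits), self.values[idx], dict(self.direction))

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "accession"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "TraitMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_dataframe(df)

    def imputed(self) -> np.ndarray:
        """Values with missing entries replaced by the trait mean."""
        x = self.values.copy()
        col_means = np.nanmean(x, axis=0)
        nan_r, nan_c = np.where(np.isnan(x))
        x[nan_r, nan_c] = col_means[nan_c]
        return x


@dataclass
class PCAResult:
    """Eigendecomposition summary of a trait correlation/covariance matrix."""

    loadings: pd.DataFrame        # m traits x c components
    eigenvalues: np.ndarray
    contribution_percent: np.ndarray
    cumulative_percent: np.ndarray


def summarize_traits(tm: TraitMatrix) -> pd.DataFrame:
    """Per-trait descriptive statistics, CV% and Shannon–Weaver GDI.

    CV% = 100 * sd / mean; undefined (NaN, flagged in the ``flags`` column)
    when the trait mean is zero.  A constant trait has sd = 0 and CV = 0,
    with skewness/kurtosis undefined.
    """
    rows = []
    for j, name in enumerate(tm.traits):
        x = tm.values[:, j]
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValueError(f"trait {name!r} has fewer than 2 observations")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        flags = []
        if sd == 0.0:
            skew = kurt = np.nan
            flags.append("constant")
        else:
            skew = float(stats.skew(x, bias=False))
            kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        if mean == 0.0:
            cv = np.nan
            flags.append("cv-undefined-zero-mean")
        elif sd == 0.0:
            cv = 0.0
        else:
            cv = 100.0 * sd / abs(mean)
        rows.append(
            {
                "trait": name,
                "mean": mean,
                "median": float(np.median(x)),
                "variance": sd * sd,
                "sd": sd,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "skewness": skew,
                "kurtosis": kurt,
                "cv_percent": cv,
                "gdi": shannon_weaver_gdi(x),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def gdi_class_edges(mean: float, sd: float) -> np.ndarray:
    """Boundaries of the 10 frequency classes: mean ± {2, 1.5, ..., 0.5, 0} sd.

    Class 1 is (-inf, mean - 2 sd); classes 2..9 are half-sd steps; class 10
    is [mean + 2 sd, inf).  This is the scheme conventional in germplasm
    diversity studies of quantitative traits.
    """
    return mean + sd * np.arange(-2.0, 2.5, 0.5)


def shannon_weaver_gdi(values, edges: np.ndarray | None = None) -> float:
    """Shannon–Weaver diversity index H' = -sum p_i ln p_i over trait classes.

    Values are binned into 10 classes centred on the mean in half-sd steps
    (see :func:`gdi_class_edges`); ``edges`` overrides the class boundaries.
    A constant trait occupies a single class and has H' = 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if edges is None:
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            return 0.0
        edges = gdi_class_edges(mean, sd)
    classes = np.searchsorted(edges, x, side="right")
    counts = np.bincount(classes)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def correlate_traits(tm: TraitMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Missing values are excluded pairwise; each pair needs >= 3 complete
    observations.  Zero-variance traits yield NaN entries (flagged via
    warning) rather than a silent 0.
    """
    m = tm.m
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = tm.values[:, i], tm.values[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3:
                raise ValueError(
                    f"traits {tm.traits[i]!r}/{tm.traits[j]!r}: fewer than 3 paired observations"
                )
            a, b = xi[ok], xj[ok]
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn(
                    f"zero-variance trait in pair ({tm.traits[i]}, {tm.traits[j]}); correlation undefined"
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=tm.traits, columns=tm.traits)
    pdf = pd.DataFrame(p, index=tm.traits, columns=tm.traits)
    return rdf, pdf


def pca_traits(tm: TraitMatrix, standardize: bool = True) -> PCAResult:
    """PCA of the trait table via eigendecomposition.

    With ``standardize`` (the default) the correlation matrix is decomposed,
    so eigenvalues sum to the number of traits; otherwise the covariance
    matrix.  Missing values are mean-imputed first.  Loadings are
    eigenvectors scaled by sqrt(eigenvalue); components are ordered by
    descending eigenvalue and contribution_percent = 100 * lambda / sum.
    """
    x = tm.imputed()
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn("dropping zero-variance traits before correlation PCA")
        x = x[:, keep]
        names = [t for t, k in zip(tm.traits, keep) if k]
        mat = np.corrcoef(x, rowvar=False)
        if mat.ndim == 0:  # single trait
            mat = np.array([[1.0]])
    else:
        names = list(tm.traits)
        mat = np.cov(x, rowvar=False, ddof=1)
        mat = np.atleast_2d(mat)
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for c in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, c]))
        if evecs[k, c] < 0:
            evecs[:, c] *= -1.0
    loadings = evecs * np.sqrt(evals)
    contrib = 100.0 * evals / evals.sum()
    cols = [f"PC{i + 1}" for i in range(len(evals))]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=names, columns=cols),
        eigenvalues=evals,
        contribution_percent=contrib,
        cumulative_percent=np.cumsum(contrib),
    )


def zstandardize(tm: TraitMatrix) -> TraitMatrix:
    """Z-score each trait (sample sd); zero-variance traits are dropped."""
    x = tm.values
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [t for t, k in zip(tm.traits, keep) if not k]
        warnings.warn(f"dropping zero-variance traits: {dropped}")
    z = (x[:, keep] - mean[keep]) / sd[keep]
    traits = [t for t, k in zip(tm.traits, keep) if k]
    return TraitMatrix(list(tm.ids), traits, z, {t: tm.direction.get(t, HIGHER) for t in traits})
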