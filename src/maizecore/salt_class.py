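"""Membership-function scoring and stress-tolerance classification.

Germination-stage stress screening scores each accession on a handful of
physiological indicators (germination potential, germination rate, seedling
length, ...).  Indicators are put on a common [0, 1] scale with the min-max
membership function

    U = (x - min) / (max - min)          (higher values favourable)
    U = (max - x) / (max - min)          (lower values favourable)

and combined into a comprehensive evaluation value D per accession as a
weighted mean of memberships.  Weights are either equal or derived from a
PCA of the indicator matrix (per-indicator squared loadings weighted by each
component's eigenvalue share, normalized to sum 1) so that indicators
carrying more of the joint variance weigh more.  Accessions are then
clustered on D (Ward linkage, 1-D Euclidean distances) into five tolerance
groups labelled I..V by descending group mean D — highly tolerant, tolerant,
moderately tolerant, sensitive, highly sensitive; the tolerant set is
groups I-III.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_engine import DistanceMatrix, agglomerate, cut_tree
from .pheno_stats import HIGHER, LOWER, TraitMatrix, pca_traits

__all__ = [
    "IndicatorMatrix",
    "MembershipTable",
    "ToleranceGroups",
    "TOLERANCE_CATEGORIES",
    "membership",
    "comprehensive_d",
    "classify_tolerance",
]

#: tolerance category per group label, best to worst mean D
TOLERANCE_CATEGORIES = {"I": "HT", "II": "T", "III": "MT", "IV": "S", "V": "HS"}
GROUP_LABELS = list(TOLERANCE_CATEGORIES)


@dataclass
class IndicatorMatrix:
    """Accession x stress-indicator values with per-indicator direction."""

    ids: list[str]
    indicators: list[str]
    values: np.ndarray
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, q = self.values.shape
        if len(self.ids) != n or len(self.indicators) != q:
            raise ValueError("labels do not match value shape")
        if q < 1:
            raise ValueError("need at least one indicator")
        if np.isnan(self.values).all(axis=0).any():
            raise ValueError("all-missing indicator column")
        for name in self.indicators:
            d = self.direction.setdefault(name, HIGHER)
            if d not in (HIGHER, LOWER):
                raise ValueError(f"direction for {name!r} must be 'higher' or 'lower'")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.indicators)

    @classmethod
    def read_csv(cls, path, direction: dict[str, str] | None = None) -> "IndicatorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            dict(direction or {}),
        )

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "accession"
        df.to_csv(path)


@dataclass
class MembershipTable:
    """Memberships U, indicator weights w (sum 1) and D = U w per accession."""

    U: pd.DataFrame
    weights: pd.Series
    D: pd.Series

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        u = self.U.to_numpy()
        if np.nanmin(u) < -1e-12 or np.nanmax(u) > 1.0 + 1e-12:
            raise ValueError("memberships outside [0, 1]")


@dataclass
class ToleranceGroups:
    """Group label per accession plus group-level summaries."""

    labels: pd.Series                 # accession -> I..V
    group_mean_d: pd.Series           # I..V -> mean D, descending
    tolerant_ids: list[str]           # members of groups I, II, III

    def category(self) -> pd.Series:
        """HT/T/MT/S/HS category per accession."""
        return self.labels.map(TOLERANCE_CATEGORIES)


def membership(im: IndicatorMatrix) -> pd.DataFrame:
    """Min-max membership values per indicator, honouring direction.

    Constant indicators are undefined under min-max scaling and are dropped
    with a warning.
    """
    cols = {}
    for j, name in enumerate(im.indicators):
        x = im.values[:, j]
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"indicator {name!r} is constant; dropped from membership table")
            continue
        u = (x - lo) / (hi - lo)
        if im.direction.get(name, HIGHER) == LOWER:
            u = 1.0 - u
        cols[name] = u
    if not cols:
        raise ValueError("no non-constant indicator")
    return pd.DataFrame(cols, index=im.ids)


def _pca_contribution_weights(U: pd.DataFrame) -> pd.Series:
    """Indicator weights from PCA: eigenvalue-share-weighted squared loadings."""
    tm = TraitMatrix([str(i) for i in U.index], list(U.columns), U.to_numpy())
    pc = pca_traits(tm, standardize=True)
    share = pc.contribution_percent / 100.0
    raw = (pc.loadings.to_numpy() ** 2 * share[None, :]).sum(axis=1)
    w = raw / raw.sum()
    return pd.Series(w, index=U.columns)


def comprehensive_d(U: pd.DataFrame, weights="pca_contribution") -> MembershipTable:
    """Weighted comprehensive evaluation value D per accession.

    ``weights`` is ``"equal"``, ``"pca_contribution"`` (the default), or an
    explicit per-indicator vector (normalized to sum 1).  Missing
    memberships are excluded from an accession's weighted mean with the
    weights renormalized over its observed indicators.
    """
    q = U.shape[1]
    if isinstance(weights, str):
        if weights == "equal":
            w = pd.Series(np.full(q, 1.0 / q), index=U.columns)
        elif weights == "pca_contribution":
            w = _pca_contribution_weights(U)
        else:
            raise ValueError(f"unknown weighting scheme {weights!r}")
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=U.columns)
        if w.sum() <= 0:
            raise ValueError("weights must have positive sum")
        w = w / w.sum()
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise AssertionError("internal error: weights failed to normalize")
    u = U.to_numpy()
    mask = ~np.isnan(u)
    wm = mask * w.to_numpy()[None, :]
    denom = wm.sum(axis=1)
    if (denom == 0).any():
        raise ValueError("accession with no observed indicator")
    d = np.nansum(u * wm, axis=1) / denom
    return MembershipTable(U=U, weights=w, D=pd.Series(d, index=U.index, name="D"))


def classify_tolerance(D: pd.Series, n_groups: int = 5) -> ToleranceGroups:
    """Cluster comprehensive D values into ordered tolerance groups.

    Ward agglomeration on 1-D Euclidean distances of D, cut into
    ``n_groups`` clusters; groups are labelled I..V by descending mean D, so
    group I always holds the most tolerant accessions.  Requires
    ``n >= n_groups``.
    """
    if n_groups != 5:
        labels_pool = [f"G{i + 1}" for i in range(n_groups)]
    else:
        labels_pool = GROUP_LABELS
    if len(D) < n_groups:
        raise ValueError(
            f"need at least {n_groups} accessions to form {n_groups} groups; lower k"
        )
    ids = [str(i) for i in D.index]
    x = D.to_numpy(dtype=float)[:, None]
    dist = np.abs(x - x.T)
    np.fill_diagonal(dist, 0.0)
    tree = agglomerate(DistanceMatrix(ids, dist), "ward")
    raw = cut_tree(tree, n_groups)
    means = pd.Series(
        [x[raw == c, 0].mean() for c in range(n_groups)], index=range(n_groups)
    )
    order = means.sort_values(ascending=False, kind="stable").index
    mapping = {int(c): labels_pool[rank] for rank, c in enumerate(order)}
    labels = pd.Series([mapping[int(c)] for c in raw], index=D.index, name="group")
    group_mean_d = pd.Series(
        {labels_pool[rank]: float(means[c]) for rank, c in enumerate(order)},
        name="mean_D",
    )
    tolerant = [a for a, g in zip(ids, labels) if g in labels_pool[: min(3, n_groups)]]
    return ToleranceGroups(labels=labels, group_mean_d=group_mean_d, tolerant_ids=tolerant)
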