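"""Evaluation of a core collection against its source population.

The standard representativeness statistics for trait-based core collections
are computed per trait and aggregated over the ``m`` traits:

* **MD%** — mean difference percentage: share of traits whose core vs full
  means differ significantly (two-sample Welch t-test at ``alpha``);
* **VD%** — variance difference percentage: share of traits whose variances
  differ significantly (two-sided variance-ratio F-test);
* **CR%** — coincidence rate of range: mean over traits of
  ``range_core / range_full`` x 100;
* **VR%** — variable rate of CV: mean over traits of ``CV_core / CV_full``
  x 100.

A representative core has small MD and large CR; the conventional verdict is
MD < 20% and CR > 80%.  The core and the full panel are compared as
independent samples even though the core is a subset — the convention of
this evaluation literature.  No multiple-testing correction is applied: MD
and VD are defined on the raw per-trait tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pheno_stats import PCAResult, TraitMatrix, pca_traits

__all__ = ["CoreEvaluation", "evaluate_core", "rank_strategies", "compare_pca"]


@dataclass
class CoreEvaluation:
    """MD/VD/CR/VR summary plus the per-trait test table."""

    md_percent: float
    vd_percent: float
    cr_percent: float
    vr_percent: float
    per_trait: pd.DataFrame
    alpha: float = 0.05
    md_limit: float = 20.0
    cr_limit: float = 80.0
    excluded_traits: list[str] = field(default_factory=list)
    label: str = ""

    @property
    def verdict(self) -> bool:
        """Pass iff MD below its limit and CR above its limit."""
        return self.md_percent < self.md_limit and self.cr_percent > self.cr_limit

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "md_percent": self.md_percent,
            "vd_percent": self.vd_percent,
            "cr_percent": self.cr_percent,
            "vr_percent": self.vr_percent,
            "alpha": self.alpha,
            "verdict": "pass" if self.verdict else "fail",
            "excluded_traits": list(self.excluded_traits),
        }


def _f_test_two_sided(var1: float, var2: float, df1: int, df2: int) -> tuple[float, float]:
    """Variance-ratio F statistic and two-sided p-value."""
    if var2 == 0.0:
        return np.inf if var1 > 0 else 1.0, 0.0 if var1 > 0 else 1.0
    F = var1 / var2
    p = 2.0 * min(stats.f.cdf(F, df1, df2), stats.f.sf(F, df1, df2))
    return float(F), float(min(p, 1.0))


def evaluate_core(
    core: TraitMatrix,
    full: TraitMatrix,
    alpha: float = 0.05,
    md_limit: float = 20.0,
    cr_limit: float = 80.0,
    label: str = "",
) -> CoreEvaluation:
    """Compare a core collection with the full population trait by trait.

    ``core`` must cover a subset of ``full``'s accessions and the identical
    trait list.  Traits whose full-population range or CV is zero (or whose
    mean is zero, making CV undefined) are excluded from CR/VR with a
    warning and the trait count adjusted.
    """
    if list(core.traits) != list(full.traits):
        raise ValueError("core and full must share the same trait list")
    if not set(core.ids) <= set(full.ids):
        raise ValueError("core accessions are not a subset of the full panel")

    rows = []
    excluded: list[str] = []
    for j, trait in enumerate(full.traits):
        xc = core.values[:, j]
        xf = full.values[:, j]
        xc, xf = xc[~np.isnan(xc)], xf[~np.isnan(xf)]
        t_stat, t_p = stats.ttest_ind(xc, xf, equal_var=False)
        vc, vf = np.var(xc, ddof=1), np.var(xf, ddof=1)
        f_stat, f_p = _f_test_two_sided(vc, vf, len(xc) - 1, len(xf) - 1)
        rng_f = np.ptp(xf)
        mean_c, mean_f = np.mean(xc), np.mean(xf)
        cv_f = np.std(xf, ddof=1) / abs(mean_f) if mean_f != 0 else np.nan
        cv_c = np.std(xc, ddof=1) / abs(mean_c) if mean_c != 0 else np.nan
        if rng_f == 0 or not np.isfinite(cv_f) or cv_f == 0:
            warnings.warn(f"trait {trait!r} excluded from CR/VR (zero range or undefined CV)")
            excluded.append(trait)
            range_ratio = cv_ratio = np.nan
        else:
            range_ratio = np.ptp(xc) / rng_f
            cv_ratio = cv_c / cv_f
        rows.append(
            {
                "trait": trait,
                "t_statistic": float(t_stat),
                "t_pvalue": float(t_p),
                "f_statistic": f_stat,
                "f_pvalue": f_p,
                "range_ratio": range_ratio,
                "cv_ratio": cv_ratio,
            }
        )
    table = pd.DataFrame(rows).set_index("trait")
    m = len(full.traits)
    md = 100.0 * float((table["t_pvalue"] < alpha).sum()) / m
    vd = 100.0 * float((table["f_pvalue"] < alpha).sum()) / m
    kept = table.dropna(subset=["range_ratio"])
    if kept.empty:
        raise ValueError("no trait usable for CR/VR")
    cr = 100.0 * float(kept["range_ratio"].mean())
    vr = 100.0 * float(kept["cv_ratio"].mean())
    return CoreEvaluation(
        md_percent=md,
        vd_percent=vd,
        cr_percent=cr,
        vr_percent=vr,
        per_trait=table,
        alpha=alpha,
        md_limit=md_limit,
        cr_limit=cr_limit,
        excluded_traits=excluded,
        label=label,
    )


def rank_strategies(evals: list[CoreEvaluation]) -> list[CoreEvaluation]:
    """Order evaluations best-first.

    Primary key: passing verdict; then ascending MD; ties by descending CR,
    then descending VR, then descending VD.  The sort is stable, so input
    order breaks any remaining ties deterministically.
    """
    if not evals:
        raise ValueError("need at least one evaluation")
    return sorted(
        evals,
        key=lambda e: (
            not e.verdict,
            e.md_percent,
            -e.cr_percent,
            -e.vr_percent,
            -e.vd_percent,
        ),
    )


def compare_pca(
    core: TraitMatrix, full: TraitMatrix, n_components: int = 5
) -> tuple[PCAResult, PCAResult, float]:
    """Correlation-matrix PCA of core and full tables.

    Returns (core result, full result, delta) where delta is the difference
    in cumulative contribution of the top ``n_components`` components
    (core minus full), in percentage points.  A positive delta indicates the
    core packs more of its trait variance into the leading components.
    """
    if list(core.traits) != list(full.traits):
        raise ValueError("core and full must share the same trait list")
    pc_core = pca_traits(core, standardize=True)
    pc_full = pca_traits(full, standardize=True)
    c = min(n_components, len(pc_core.cumulative_percent), len(pc_full.cumulative_percent))
    delta = float(pc_core.cumulative_percent[c - 1] - pc_full.cumulative_percent[c - 1])
    return pc_core, pc_full, delta
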