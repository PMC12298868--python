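"""End-to-end pipeline: simulate -> characterize -> core -> classify.

Runs the whole analysis in dependency order on synthetic (or user-supplied)
inputs and writes every stage artifact plus a JSON run manifest recording
inputs, parameters and seeds, so a rerun with the same config reproduces
byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core_eval import evaluate_core, rank_strategies
from .geno_core import integrate_cores, select_geno_core
from .geno_div import diversity_stats, evanno_delta_k, filter_loci, genotype_pca, write_genotypes
from .pheno_core import strategy_grid
from .pheno_stats import correlate_traits, pca_traits, summarize_traits
from .salt_class import classify_tolerance, comprehensive_d, membership
from .synthdata import (
    GenoSimConfig,
    PhenoSimConfig,
    StressSimConfig,
    simulate_genotypes,
    simulate_germination,
    simulate_phenotypes,
    simulate_structure_likelihoods,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds, grid factors and simulation sizes for one pipeline run."""

    seed: int = 0
    n_accessions: int = 200
    n_loci: int = 1000
    n_subpops: int = 6
    # phenotypic strategy grid
    distances: list[str] = field(default_factory=lambda: ["euclidean", "mahalanobis"])
    ratios: list[float] = field(default_factory=lambda: [0.15, 0.2])
    allocations: list[str] = field(default_factory=lambda: ["random", "deviation"])
    linkages: list[str] = field(default_factory=lambda: ["flexible", "ward", "group_average"])
    # thresholds
    alpha: float = 0.05
    maf_min: float = 0.01
    pms_max: float = 0.01
    md_limit: float = 20.0
    cr_limit: float = 80.0
    # genotypic core
    geno_ratio: float = 0.15
    # salt-alkali classification
    weights: str = "pca_contribution"
    # stress-treatment metadata (recorded only; chemistry is not modelled)
    stress_solution: str = "NaCl:Na2SO4:NaHCO3:Na2CO3 = 1:9:9:1, 150 mmol/L Na+"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min out of range")
        if not 0 < self.pms_max <= 1:
            raise ValueError("pms_max out of range")
        if not 0 < self.geno_ratio <= 1:
            raise ValueError("geno_ratio out of range")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage in order and return the run manifest.

    Stages: simulate inputs; phenotype statistics; strategy-grid core
    sampling with MD/VD/CR/VR evaluation and ranking; SNP filtering and
    diversity; delta-K model selection; genotypic core selection; core
    integration; membership-function tolerance classification of the
    integrated core.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": "0.1.0",
        "config": asdict(config),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stage 1: simulate ------------------------------------------------
    stage = "simulate"
    try:
        tm = simulate_phenotypes(PhenoSimConfig(n_accessions=config.n_accessions, seed=config.seed))
        gres = simulate_genotypes(
            GenoSimConfig(
                n_accessions=config.n_accessions,
                n_loci=config.n_loci,
                n_subpops=config.n_subpops,
                seed=config.seed + 1,
            )
        )
        lk = simulate_structure_likelihoods(true_k=config.n_subpops, seed=config.seed + 2)
        tm.write_csv(out / "phenotypes.csv")
        write_genotypes(gres.genotypes, out / "genotypes.vcf", fmt="vcf")
        lk.to_csv(out / "structure_logl.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_accessions": tm.n,
            "n_loci": gres.genotypes.n_loci,
            "seed": config.seed,
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail(stage, exc)

    # --- stage 2: phenotype statistics ------------------------------------
    stage = "pheno_stats"
    try:
        summary = summarize_traits(tm)
        summary.to_csv(out / "trait_summary.csv")
        r, _p = correlate_traits(tm)
        r.to_csv(out / "trait_correlation.csv")
        pc = pca_traits(tm)
        manifest["stages"][stage] = {
            "status": "ok",
            "cv_percent_range": [float(summary["cv_percent"].min()), float(summary["cv_percent"].max())],
            "gdi_range": [float(summary["gdi"].min()), float(summary["gdi"].max())],
            "pca_cumulative_top5": float(pc.cumulative_percent[min(4, len(pc.cumulative_percent) - 1)]),
        }
    except Exception as exc:
        fail(stage, exc)

    # --- stage 3: strategy grid + evaluation ------------------------------
    stage = "pheno_core"
    try:
        grid = strategy_grid(
            tm, config.distances, config.ratios, config.allocations, config.linkages,
            seed=config.seed,
        )
        evals = []
        by_label = {}
        for s, core in grid:
            ev = evaluate_core(
                tm.subset(core.selected), tm,
                alpha=config.alpha, md_limit=config.md_limit, cr_limit=config.cr_limit,
                label=s.label(),
            )
            evals.append(ev)
            by_label[s.label()] = core
        ranked = rank_strategies(evals)
        best = ranked[0]
        pheno_core = by_label[best.label]
        import pandas as pd

        pd.DataFrame([e.to_dict() for e in ranked]).to_csv(out / "strategy_ranking.csv", index=False)
        pd.Series(pheno_core.selected, name="accession").to_csv(out / "pheno_core_ids.csv", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_strategies": len(grid),
            "best_strategy": best.label,
            "best_md_percent": best.md_percent,
            "best_cr_percent": best.cr_percent,
            "pheno_core_size": len(pheno_core.selected),
        }
    except Exception as exc:
        fail(stage, exc)

    # --- stage 4: genotype diversity --------------------------------------
    stage = "geno_stats"
    try:
        gfilt, counts = filter_loci(gres.genotypes, config.maf_min, config.pms_max)
        locus_stats, panel = diversity_stats(gfilt)
        locus_stats.to_csv(out / "locus_stats.csv")
        var_pct, scores, _ = genotype_pca(gfilt, n_components=5)
        scores.to_csv(out / "genotype_pca_scores.csv")
        dk, best_k = evanno_delta_k(lk)
        dk.to_csv(out / "delta_k.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "filter_counts": counts,
            "panel_he": panel["he"],
            "panel_ho": panel["ho"],
            "panel_shannon_i": panel["shannon_i"],
            "pca_pc1_percent": float(var_pct[0]),
            "delta_k_argmax": best_k,
        }
    except Exception as exc:
        fail(stage, exc)

    # --- stage 5: genotypic core ------------------------------------------
    stage = "geno_core"
    try:
        gcore = select_geno_core(gfilt, config.geno_ratio, seed=config.seed)
        import pandas as pd

        pd.Series(gcore.selected, name="accession").to_csv(out / "geno_core_ids.csv", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "geno_core_size": len(gcore.selected),
            "objective_ene": gcore.objective,
            "allele_coverage_percent": gcore.allele_coverage_percent,
            "core_diversity": gcore.diversity,
        }
    except Exception as exc:
        fail(stage, exc)

    # --- stage 6: integration ---------------------------------------------
    stage = "integrate"
    try:
        integrated = integrate_cores(pheno_core.selected, gcore.selected, tm.ids)
        import pandas as pd

        pd.Series(integrated.final, name="accession").to_csv(out / "integrated_core_ids.csv", index=False)
        pd.Series(integrated.reserve, name="accession").to_csv(out / "reserve_ids.csv", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "final_size": integrated.size,
            "overlap_size": len(integrated.overlap),
            "reserve_size": len(integrated.reserve),
            "final_percent": 100.0 * integrated.size / tm.n,
        }
    except Exception as exc:
        fail(stage, exc)

    # --- stage 7: salt-alkali classification ------------------------------
    stage = "salt_classify"
    try:
        im, _truth = simulate_germination(
            StressSimConfig(n_accessions=integrated.size, seed=config.seed + 3)
        )
        # indicator rows follow the integrated core's accession order
        im.ids = list(integrated.final)
        U = membership(im)
        mt = comprehensive_d(U, weights=config.weights)
        groups = classify_tolerance(mt.D)
        import pandas as pd

        report = pd.DataFrame({"D": mt.D, "group": groups.labels, "category": groups.category()})
        report.to_csv(out / "tolerance_groups.csv")
        counts = groups.labels.value_counts().sort_index()
        manifest["stages"][stage] = {
            "status": "ok",
            "group_counts": {str(k): int(v) for k, v in counts.items()},
            "tolerant_count": len(groups.tolerant_ids),
            "weights": {k: float(v) for k, v in mt.weights.items()},
            "stress_solution": config.stress_solution,
        }
    except Exception as exc:
        fail(stage, exc)

    _write_json(out / "manifest.json", manifest)
    return manifest
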