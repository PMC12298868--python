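"""Genotype I/O, filtering, diversity statistics, GSC, density, PCA, delta-K."""

import numpy as np
import pandas as pd
import pytest

from maizecore import (
    MISSING,
    diversity_stats,
    evanno_delta_k,
    filter_loci,
    genotype_pca,
    group_composition,
    gsc_matrix,
    read_genotypes,
    simulate_structure_likelihoods,
    snp_density,
    write_genotypes,
)

from conftest import toy_genotypes


class TestIO:
    @pytest.mark.parametrize("fmt,ext", [("vcf", "vcf"), ("hapmap_tsv", "hmp.txt")])
    def test_round_trip_preserves_calls(self, small_geno, tmp_path, fmt, ext):
        path = tmp_path / f"panel.{ext}"
        write_genotypes(small_geno, path, fmt=fmt)
        back = read_genotypes(path, fmt=fmt)
        assert back.ids == small_geno.ids
        assert np.array_equal(back.calls, small_geno.calls)
        assert list(back.loci["pos"]) == list(small_geno.loci["pos"])

    def test_both_formats_agree(self, small_geno, tmp_path):
        write_genotypes(small_geno, tmp_path / "a.vcf", fmt="vcf")
        write_genotypes(small_geno, tmp_path / "a.hmp", fmt="hapmap_tsv")
        g1 = read_genotypes(tmp_path / "a.vcf", fmt="vcf")
        g2 = read_genotypes(tmp_path / "a.hmp", fmt="hapmap_tsv")
        assert np.array_equal(g1.calls, g2.calls)

    def test_phased_and_unphased_equal(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        )
        body = "chr1\t10\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0|1\n"
        path = tmp_path / "phase.vcf"
        path.write_text(header + body)
        g = read_genotypes(path, fmt="vcf")
        assert list(g.calls[:, 0]) == [1, 1]

    def test_multiallelic_dropped_with_warning(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        )
        body = (
            "chr1\t10\tm1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
            "chr1\t20\tb1\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(header + body)
        with pytest.warns(UserWarning, match="multi-allelic"):
            g = read_genotypes(path, fmt="vcf")
        assert g.n_loci == 1 and g.loci["id"].iloc[0] == "b1"

    def test_malformed_hapmap_reports_line(self, tmp_path):
        good = toy_genotypes(np.array([[0, 1], [2, 0]]))
        path = tmp_path / "bad.hmp"
        write_genotypes(good, path, fmt="hapmap_tsv")
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("AA", "AX", 1)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 3"):
            read_genotypes(path, fmt="hapmap_tsv")


class TestFilter:
    def test_monomorphic_removed(self):
        g = toy_genotypes(np.array([[0, 0, 2], [0, 1, 0], [0, 2, 1], [0, 0, 1]]))
        gf, counts = filter_loci(g, maf_min=0.01, pms_max=1.1)
        assert counts["kept"] == 2 and list(gf.loci["id"]) == ["s1", "s2"]

    def test_maf_hand_count_threshold(self):
        # 100 accessions: 1 het (maf 0.005) removed; 3 hets (0.015) kept
        one = np.zeros((100, 1), dtype=np.int8)
        one[0, 0] = 1
        three = np.zeros((100, 1), dtype=np.int8)
        three[:3, 0] = 1
        g = toy_genotypes(np.hstack([one, three]))
        gf, _ = filter_loci(g, maf_min=0.01, pms_max=1.1)
        assert list(gf.loci["id"]) == ["s1"]

    def test_vacuous_thresholds_keep_polymorphic(self, small_geno):
        gf, counts = filter_loci(small_geno, maf_min=0.0, pms_max=1.1)
        assert counts["kept"] == counts["input"] - counts["removed_maf"]
        _, counts2 = filter_loci(gf, maf_min=0.0, pms_max=1.1)
        assert counts2["kept"] == counts2["input"]  # idempotent

    def test_idempotent_at_default_thresholds(self, small_geno):
        gf, _ = filter_loci(small_geno)
        gff, counts = filter_loci(gf)
        assert counts["kept"] == gf.n_loci
        assert np.array_equal(gf.calls, gff.calls)


class TestDiversity:
    def test_hand_counted_locus(self):
        g = toy_genotypes(np.array([[0], [1], [2], [1]]))
        table, panel = diversity_stats(g)
        row = table.iloc[0]
        assert row["maf"] == pytest.approx(0.5)
        assert row["he"] == pytest.approx(0.5)
        assert row["ho"] == pytest.approx(0.5)
        assert row["shannon_i"] == pytest.approx(np.log(2))
        assert panel["n_loci"] == 1

    def test_boundary_loci(self):
        g = toy_genotypes(np.array([[0, 1], [0, 1], [0, 1]]))
        table, _ = diversity_stats(g)
        mono, het = table.iloc[0], table.iloc[1]
        assert mono["he"] == 0.0 and mono["shannon_i"] == 0.0
        assert het["ho"] == 1.0 and het["he"] == pytest.approx(0.5)

    def test_bounds_on_simulated_panel(self, small_geno):
        table, panel = diversity_stats(small_geno)
        assert ((table["he"] >= 0) & (table["he"] <= 0.5 + 1e-12)).all()
        assert ((table["shannon_i"] >= 0) & (table["shannon_i"] <= np.log(2) + 1e-12)).all()
        assert 0.0 <= panel["ho"] <= 1.0


class TestGSC:
    def test_identical_and_opposite(self):
        g = toy_genotypes(np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]]))
        gsc = gsc_matrix(g)
        assert gsc.iloc[0, 1] == pytest.approx(1.0)
        assert gsc.iloc[0, 2] == pytest.approx((0 + 0 + 1) / 3)

    def test_opposite_homozygotes_zero(self):
        g = toy_genotypes(np.array([[0, 0, 0], [2, 2, 2]]))
        assert gsc_matrix(g).iloc[0, 1] == 0.0

    def test_matches_hand_count_oracle_with_missing(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        calls[rng.random(size=calls.shape) < 0.2] = MISSING
        g = toy_genotypes(calls)
        gsc = gsc_matrix(g)
        score = {0: 1.0, 1: 0.5, 2: 0.0}
        for a in range(5):
            for b in range(5):
                vals = [
                    score[abs(int(calls[a, l]) - int(calls[b, l]))]
                    for l in range(8)
                    if calls[a, l] != MISSING and calls[b, l] != MISSING
                ]
                assert gsc.iloc[a, b] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_locus_order_invariance_and_duplicate_effect(self, small_geno):
        perm = np.random.default_rng(1).permutation(small_geno.n_loci)
        g2 = toy_genotypes(small_geno.calls[:, perm], ids=list(small_geno.ids))
        base = gsc_matrix(small_geno).to_numpy()
        assert np.allclose(gsc_matrix(g2).to_numpy(), base, atol=1e-12, equal_nan=True)
        # duplicating the accession with the highest mean similarity can only
        # raise the panel mean (its added pairs all sit at or above the mean)
        iu = np.triu_indices(base.shape[0], 1)
        np.fill_diagonal(base, np.nan)
        star = int(np.nanargmax(np.nanmean(base, axis=1)))
        dup = toy_genotypes(
            np.vstack([small_geno.calls, small_geno.calls[star : star + 1]]),
            ids=list(small_geno.ids) + ["dup"],
        )
        np.fill_diagonal(base, 1.0)
        dup_m = gsc_matrix(dup).to_numpy()
        iu2 = np.triu_indices(dup_m.shape[0], 1)
        assert np.nanmean(dup_m[iu2]) >= np.nanmean(base[iu]) - 1e-12


class TestDensity:
    def test_constructed_map_exact(self):
        calls = np.zeros((2, 6), dtype=np.int8)
        g = toy_genotypes(calls)
        g.loci["chrom"] = ["chr1"] * 4 + ["chr2"] * 2
        g.loci["pos"] = [1, 2, 150, 160, 5, 210]
        counts, windows = snp_density(g, window=100)
        assert counts["chr1"] == 4 and counts["chr2"] == 2
        w1 = windows[windows["chrom"] == "chr1"]["count"].tolist()
        assert w1 == [2, 2]
        w2 = windows[windows["chrom"] == "chr2"]["count"].tolist()
        assert w2 == [1, 0, 1]  # middle window covers no locus

    def test_zero_window_rejected(self, small_geno):
        with pytest.raises(ValueError, match="window"):
            snp_density(small_geno, window=0)


class TestGenotypePCA:
    def test_clonal_groups_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=40).astype(np.int8)
        b = rng.integers(0, 3, size=40).astype(np.int8)
        calls = np.vstack([np.tile(a, (6, 1)), np.tile(b, (6, 1))])
        g = toy_genotypes(calls)
        var_pct, scores, _ = genotype_pca(g, n_components=3)
        assert var_pct[0] >= 99.0
        pc1 = scores["PC1"].to_numpy()
        assert np.ptp(np.sign(pc1[:6])) == 0 and np.sign(pc1[0]) != np.sign(pc1[-1])

    def test_duplicate_rows_identical_scores(self, small_geno):
        dup = toy_genotypes(
            np.vstack([small_geno.calls, small_geno.calls[:1]]),
            ids=list(small_geno.ids) + ["dup"],
        )
        _, scores, _ = genotype_pca(dup, n_components=4)
        assert np.allclose(scores.iloc[0], scores.iloc[-1], atol=1e-9)


class TestEvannoDeltaK:
    def test_matches_hand_computation(self):
        rows = []
        logl = {
            1: [-100.0, -101.0, -99.0],
            2: [-80.0, -82.0, -78.0],
            3: [-70.0, -71.0, -69.0],
            4: [-68.0, -69.0, -67.0],
            5: [-67.0, -68.5, -65.5],
        }
        for k, vals in logl.items():
            rows += [{"K": k, "rep": r + 1, "logL": v} for r, v in enumerate(vals)]
        table, best = evanno_delta_k(pd.DataFrame(rows))
        means = {k: np.mean(v) for k, v in logl.items()}
        sds = {k: np.std(v, ddof=1) for k, v in logl.items()}
        for k in (2, 3, 4):
            expected = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
            got = float(table.loc[table["K"] == k, "delta_k"].iloc[0])
            assert got == pytest.approx(expected, abs=1e-9)
        assert best == 3  # largest curvature relative to replicate spread

    def test_constructed_kink_recovered(self):
        table = simulate_structure_likelihoods(true_k=6, reps=3, seed=0)
        _, best = evanno_delta_k(table)
        assert best == 6

    def test_linear_likelihood_flat_delta(self):
        rng = np.random.default_rng(0)
        rows = [
            {"K": k, "rep": r, "logL": -100.0 + 10.0 * k}
            for k in range(1, 7)
            for r in range(3)
        ]
        table = pd.DataFrame(rows)
        table["logL"] += rng.normal(0, 1e-9, len(table))
        out, _ = evanno_delta_k(table)
        assert np.allclose(out["l_second_abs"].iloc[1:-1], 0.0, atol=1e-6)

    def test_requires_replicates_and_contiguity(self):
        rows = [{"K": k, "rep": r, "logL": -1.0} for k in (1, 2, 3) for r in (1, 2)]
        with pytest.raises(ValueError, match="replicates"):
            evanno_delta_k(pd.DataFrame(rows))
        rows = [{"K": k, "rep": r, "logL": -1.0} for k in (1, 2, 5) for r in (1, 2, 3)]
        with pytest.raises(ValueError, match="contiguous"):
            evanno_delta_k(pd.DataFrame(rows))


def test_group_composition_percentages():
    labels = ["Lan"] * 308 + ["BSSS"] * 114 + ["TSPT"] * 70 + ["LRC"] * 53 + ["P"] * 21 + ["X"] * 22
    comp = group_composition(labels)
    assert comp.loc["Lan", "count"] == 308
    assert round(float(comp.loc["Lan", "percent"]), 2) == 52.38
    assert comp["count"].sum() == 588
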