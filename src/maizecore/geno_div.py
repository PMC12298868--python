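"""SNP genotype I/O, filtering and diversity statistics.

Genotypes are biallelic SNP calls for inbred-line panels, coded per
accession x locus as 0 (ref homozygote), 1 (heterozygote), 2 (alt
homozygote) or -1 (missing).  The module covers the molecular half of a
germplasm characterization:

* VCF (GT-only subset) and HapMap-like TSV readers/writers;
* locus filtering on minor allele frequency (MAF) and per-locus missing
  rate (PMS), strict inequalities;
* per-locus diversity statistics — expected heterozygosity
  He = 1 - p^2 - q^2, observed heterozygosity Ho, and Shannon's information
  index I = -(p ln p + q ln q), each bounded for a biallelic locus
  (He <= 0.5, I <= ln 2) — with panel values as unweighted locus means;
* identity-by-state genetic similarity coefficients (GSC);
* per-chromosome SNP counts and windowed density;
* genotype PCA on the mean-imputed, centered call matrix;
* Evanno delta-K post-processing of replicate model-based clustering
  log-likelihood tables (the model fitting itself is upstream software;
  only its L(K) output table is consumed here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "filter_loci",
    "diversity_stats",
    "gsc_matrix",
    "snp_density",
    "genotype_pca",
    "evanno_delta_k",
    "group_composition",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Accession x locus biallelic SNP calls with a chromosome/position map.

    ``loci`` is a DataFrame with columns (id, chrom, pos, ref, alt);
    positions are 1-based.  ``calls`` is an (n, L) int8 array in
    {0, 1, 2, MISSING}.
    """

    ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = self.calls.shape
        if len(self.ids) != n:
            raise ValueError("accession ids do not match call rows")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(self.loci) != L:
            raise ValueError("locus table does not match call columns")
        required = {"id", "chrom", "pos", "ref", "alt"}
        if not required <= set(self.loci.columns):
            raise ValueError(f"locus table needs columns {sorted(required)}")
        if (self.loci["pos"].to_numpy() < 0).any():
            raise ValueError("negative positions")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("invalid call codes (expected 0/1/2/missing)")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"unknown accession ids: {missing[:5]}")
        idx = [pos[a] for a in ids]
        return GenotypeMatrix(list(ids), self.loci.reset_index(drop=True), self.calls[idx])

    def dosage(self) -> np.ndarray:
        """Calls as float with missing -> NaN."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x

    def allele_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus alt-allele frequency p and called-sample count.

        Allele counting: each het contributes one alt allele, each alt
        homozygote two, over ``2 * n_called`` chromosomes.
        """
        called = self.calls != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        return p, n_called


# ---------------------------------------------------------------------------
# I/O: minimal VCF (GT field only) and HapMap-like TSV
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def write_genotypes(g: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    """Write a genotype matrix as minimal VCF or HapMap-like TSV."""
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "hapmap_tsv":
        _write_hapmap(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF (via cyvcf2) or HapMap-like TSV.

    Multi-allelic records are dropped (count reported via warning); phased
    and unphased calls are treated identically.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "hapmap_tsv":
        return _read_hapmap(path)
    raise ValueError(f"unknown format {fmt!r}")


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.ids) + "\n")
        loci = g.loci
        for j in range(g.n_loci):
            rec = loci.iloc[j]
            gts = "\t".join(_VCF_GT[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['id']}\t{rec['ref']}\t{rec['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    records, columns = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        codes = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=unknown
        codes[codes == 3] = MISSING
        columns.append(codes)
        records.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if n_multi:
        warnings.warn(f"dropped {n_multi} multi-allelic loci")
    if not records:
        raise ValueError("no biallelic loci in VCF")
    calls = np.column_stack(columns)
    return GenotypeMatrix(ids, pd.DataFrame(records), calls)


def _write_hapmap(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + g.ids) + "\n")
        loci = g.loci
        for j in range(g.n_loci):
            rec = loci.iloc[j]
            ref, alt = str(rec["ref"]), str(rec["alt"])
            geno = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            row = [
                str(rec["id"]), f"{ref}/{alt}", str(rec["chrom"]), str(int(rec["pos"])),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ] + [geno[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = df.columns[:11]
    ids = list(df.columns[11:])
    records, columns = [], []
    n_multi = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        alleles = str(row[1]).split("/")
        if len(alleles) != 2:
            n_multi += 1
            continue
        ref, alt = alleles
        code = {ref + ref: 0, ref + alt: 1, alt + ref: 1, alt + alt: 2, "NN": MISSING}
        try:
            codes = np.array([code[str(c)] for c in row[11:]], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"malformed genotype at line {lineno}: {exc}") from exc
        columns.append(codes)
        records.append(
            {"id": str(row[0]), "chrom": str(row[2]), "pos": int(row[3]), "ref": ref, "alt": alt}
        )
    if n_multi:
        warnings.warn(f"dropped {n_multi} non-biallelic loci")
    if not records:
        raise ValueError(f"no biallelic loci in {path} (columns: {list(meta_cols)[:3]}...)")
    return GenotypeMatrix(ids, pd.DataFrame(records), np.column_stack(columns))


# ---------------------------------------------------------------------------
# Filtering and diversity
# ---------------------------------------------------------------------------

def filter_loci(
    g: GenotypeMatrix, maf_min: float = 0.01, pms_max: float = 0.01
) -> tuple[GenotypeMatrix, dict]:
    """Keep loci with MAF > ``maf_min`` and missing rate < ``pms_max``.

    Both inequalities are strict.  MAF is computed on non-missing calls as
    ``min(p, 1 - p)`` with allele counting (a het counts one alt allele).
    Returns the filtered matrix and a counts dict.
    """
    p, n_called = g.allele_freqs()
    miss = (g.calls == MISSING).mean(axis=0)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    all_missing = n_called == 0
    keep = (~all_missing) & (maf > maf_min) & (miss < pms_max)
    counts = {
        "input": g.n_loci,
        "kept": int(keep.sum()),
        "removed_maf": int(((~all_missing) & ~(maf > maf_min)).sum()),
        "removed_missing": int(((~all_missing) & (maf > maf_min) & ~(miss < pms_max)).sum()),
        "removed_all_missing": int(all_missing.sum()),
    }
    out = GenotypeMatrix(
        list(g.ids), g.loci.loc[keep].reset_index(drop=True), g.calls[:, keep]
    )
    return out, counts


def diversity_stats(g: GenotypeMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-locus MAF/PMS/He/Ho/Shannon-I plus unweighted panel means.

    Loci with fewer than 2 called accessions are excluded from the table.
    """
    p, n_called = g.allele_freqs()
    ok = n_called >= 2
    if not ok.any():
        raise ValueError("no locus with >= 2 called accessions")
    p = p[ok]
    q = 1.0 - p
    he = 1.0 - p**2 - q**2
    ho = (g.calls[:, ok] == 1).sum(axis=0) / (g.calls[:, ok] != MISSING).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -(
            np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0)
        )
    table = pd.DataFrame(
        {
            "locus": g.loci.loc[ok, "id"].to_numpy(),
            "maf": np.minimum(p, q),
            "missing_rate": (g.calls[:, ok] == MISSING).mean(axis=0),
            "he": he,
            "ho": ho,
            "shannon_i": shannon,
        }
    ).set_index("locus")
    panel = {
        "he": float(he.mean()),
        "ho": float(ho.mean()),
        "shannon_i": float(shannon.mean()),
        "n_loci": int(ok.sum()),
    }
    return table, panel


def gsc_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state genetic similarity coefficients between accessions.

    Per co-called locus, similarity is 1 for identical codes, 0.5 when the
    codes differ by one (one shared allele), 0 for opposite homozygotes —
    i.e. ``1 - |x_a - x_b| / 2``.  GSC is the mean over co-called loci; a
    pair with no co-called locus is NaN (flagged via warning).
    """
    if g.n < 2:
        raise ValueError("need at least 2 accessions")
    x = g.dosage()
    n = g.n
    out = np.ones((n, n))
    for i in range(n):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
            sim = np.nanmean(1.0 - np.abs(x[i] - x) / 2.0, axis=1)
        out[i] = sim
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    if np.isnan(out).any():
        warnings.warn("accession pairs with zero co-called loci: GSC undefined (NaN)")
    return pd.DataFrame(out, index=g.ids, columns=g.ids)


def snp_density(g: GenotypeMatrix, window: int) -> tuple[pd.Series, pd.DataFrame]:
    """Per-chromosome SNP counts and counts per half-open window.

    Windows are ``[start, start + window)`` from position 1 (1-based
    coordinates).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    chrom = g.loci["chrom"]
    counts = chrom.value_counts().sort_index()
    counts.name = "n_snps"
    rows = []
    for c, sub in g.loci.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        n_windows = int((pos.max() - 1) // window) + 1
        idx = (pos - 1) // window
        binned = np.bincount(idx, minlength=n_windows)
        for w, k in enumerate(binned):
            rows.append({"chrom": c, "window_start": w * window + 1, "count": int(k)})
    return counts, pd.DataFrame(rows)


def genotype_pca(g: GenotypeMatrix, n_components: int = 10):
    """PCA of the call matrix (per-locus mean-imputed, column-centered).

    Returns (variance_explained_percent, scores DataFrame, fitted sklearn
    PCA).  Accessions with identical calls get identical scores.
    """
    if g.n_loci < 2:
        raise ValueError("need at least 2 loci for genotype PCA")
    x = g.dosage()
    col_means = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_means[nan_c]
    n_components = min(n_components, g.n - 1, g.n_loci)
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    var_pct = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return var_pct, pd.DataFrame(scores, index=g.ids, columns=cols), pca


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno delta-K from a replicate log-likelihood table.

    ``table`` has columns (K, rep, logL) with >= 3 replicates per K over a
    contiguous K range of >= 3 values.  For interior K:
    ``delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`` with L the replicate
    mean.  Returns the per-K table and the argmax K.  Zero replicate SD at
    an interior K yields an infinite delta-K (flagged via warning).
    """
    required = {"K", "rep", "logL"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    grp = table.groupby("K")["logL"]
    mean_l = grp.mean()
    sd_l = grp.std(ddof=1)
    n_rep = grp.count()
    ks = mean_l.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need at least 3 K values")
    if not np.array_equal(ks, np.arange(ks.min(), ks.max() + 1)):
        raise ValueError("K range must be contiguous")
    if (n_rep < 3).any():
        raise ValueError("need >= 3 replicates per K for the SD")
    lbar = mean_l.to_numpy(dtype=float)
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(lbar)
    lsecond = np.full(len(ks), np.nan)
    lsecond[1:-1] = np.abs(lbar[2:] - 2.0 * lbar[1:-1] + lbar[:-2])
    sd = sd_l.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = lsecond / sd
    if np.isinf(delta[1:-1]).any():
        warnings.warn("zero replicate SD at an interior K: delta-K infinite there")
    out = pd.DataFrame(
        {
            "K": ks,
            "mean_logL": lbar,
            "sd_logL": sd,
            "l_prime": lprime,
            "l_second_abs": lsecond,
            "delta_k": delta,
        }
    )
    interior = out.iloc[1:-1]
    best_k = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return out, best_k


def group_composition(labels) -> pd.DataFrame:
    """Counts and percentages per group label (panel bookkeeping).

    E.g. heterotic-group composition of a panel: 308 of 588 accessions in
    one pool is 52.38%.
    """
    s = pd.Series(list(labels))
    counts = s.value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / len(s)}
    ).rename_axis("group")
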