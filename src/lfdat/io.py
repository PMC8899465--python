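"""Readers and writers for genotype, phenotype and result files.

Genotypes are accepted as VCF (uncompressed text, or anything cyvcf2 can
open when it is installed), PLINK ``.raw``-style additive tables, or a plain
CSV matrix with a sidecar positions file.  Longitudinal phenotypes are
accepted wide (one column per time point) or long (subject, time, value).
SNP coordinates are 1-based base pairs on input and affinely mapped to
[0, 1] internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeRegion, LongitudinalPhenotype

log = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    contig: str
    start: int  # 1-based inclusive
    end: int
    region_id: str = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.region_id is None:
            self.region_id = f"{self.contig}:{self.start}-{self.end}"


def _normalize_positions(pos_bp: np.ndarray, region: RegionSpec = None):
    pos_bp = np.asarray(pos_bp, float)
    if region is not None:
        lo, hi = float(region.start), float(region.end)
    else:
        lo, hi = pos_bp.min(), pos_bp.max()
    span = hi - lo
    if span <= 0:  # single SNP or degenerate region
        return np.full_like(pos_bp, 0.5)
    return (pos_bp - lo) / span


def _finalize(
    subject_ids, pos_bp, G, snp_ids, region: RegionSpec = None, maf_min: float = None
):
    G = np.asarray(G, float)
    pos_bp = np.asarray(pos_bp, float)
    # mean-impute missing genotypes per SNP
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        col_mean = np.nanmean(G, axis=0)
        if np.any(np.isnan(col_mean)):
            raise ValueError("SNP with all genotypes missing")
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
        log.warning("mean-imputed %d missing genotype calls", n_missing)
    p = G.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(G.shape[1], dtype=bool)
    if maf_min is not None:
        keep &= maf >= maf_min
        dropped = int((~keep).sum())
        if dropped:
            log.info("MAF filter %.4g removed %d SNPs", maf_min, dropped)
    if not keep.any():
        raise ValueError("no SNPs left after filtering")
    order = np.argsort(pos_bp[keep], kind="mergesort")
    pos_bp = pos_bp[keep][order]
    G = G[:, keep][:, order]
    if np.any(np.diff(pos_bp) <= 0):
        # collapse exact duplicates by keeping the first
        uniq = np.concatenate([[True], np.diff(pos_bp) > 0])
        pos_bp, G = pos_bp[uniq], G[:, uniq]
    return GenotypeRegion(
        subject_ids=np.asarray(subject_ids),
        positions=_normalize_positions(pos_bp, region),
        G=G,
        positions_bp=pos_bp,
        region_id=region.region_id if region is not None else "region",
    )


# -- VCF -----------------------------------------------------------------


def _read_vcf_text(path, region: RegionSpec = None):
    samples, rows, positions = None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if samples is None:
                raise ValueError("malformed VCF: data before #CHROM header")
            parts = line.split("\t")
            chrom, pos, _id, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                log.info("skipping multiallelic site %s:%d", chrom, pos)
                continue
            if region is not None and (
                chrom != region.contig or not (region.start <= pos <= region.end)
            ):
                continue
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            row = []
            for field in parts[9:]:
                gt = field.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row.append(np.nan)  # half-calls and missing treated as missing
                else:
                    row.append(float(sum(int(a) for a in alleles)))
            rows.append(row)
            positions.append(pos)
    if samples is None:
        raise ValueError("malformed VCF: missing #CHROM header")
    if not rows:
        raise ValueError("empty region: no biallelic records found")
    return samples, np.asarray(positions, float), np.asarray(rows, float).T


def _read_vcf(path, region: RegionSpec = None):
    path = str(path)
    try:
        from cyvcf2 import VCF  # optional accelerated reader
    except ImportError:
        VCF = None
    if VCF is not None and (path.endswith(".gz") or path.endswith(".bcf")):
        vcf = VCF(path)
        samples = list(vcf.samples)
        query = f"{region.contig}:{region.start}-{region.end}" if region else None
        rows, positions = [], []
        for var in vcf(query) if query else vcf:
            if len(var.ALT) != 1:
                continue
            dosage = np.asarray(var.gt_types, float)  # 0,1,3 copies; 2 = unknown
            geno = np.where(dosage == 2, np.nan, np.where(dosage == 3, 2.0, dosage))
            rows.append(geno)
            positions.append(var.POS)
        if not rows:
            raise ValueError("empty region: no biallelic records found")
        return samples, np.asarray(positions, float), np.asarray(rows, float).T
    return _read_vcf_text(path, region)


# -- PLINK .raw ----------------------------------------------------------


def _read_plink_raw(path, positions_path=None):
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    subjects = df["IID"].to_numpy() if "IID" in df.columns else np.arange(len(df))
    G = df[snp_cols].to_numpy(dtype=float)
    if positions_path is not None:
        pos = _read_positions(positions_path, snp_cols)
    else:
        pos = np.arange(1, len(snp_cols) + 1, dtype=float)  # ordinal fallback
    return subjects, pos, G, snp_cols


def _read_positions(path, snp_ids):
    tab = pd.read_csv(path)
    cols = {c.lower(): c for c in tab.columns}
    if "snp" in cols and "pos" in cols:
        mapping = dict(zip(tab[cols["snp"]].astype(str), tab[cols["pos"]].astype(float)))
        return np.array([mapping[str(s)] for s in snp_ids], float)
    return tab.iloc[:, -1].to_numpy(dtype=float)


# -- CSV matrix ----------------------------------------------------------


def _read_csv_matrix(path, positions_path=None):
    df = pd.read_csv(path, index_col=0)
    subjects = df.index.to_numpy()
    snp_ids = list(df.columns)
    G = df.to_numpy(dtype=float)
    if positions_path is not None:
        pos = _read_positions(positions_path, snp_ids)
    else:
        pos = np.arange(1, len(snp_ids) + 1, dtype=float)
    return subjects, pos, G, snp_ids


def read_genotypes(
    path,
    format: str = "auto",
    region: RegionSpec = None,
    positions_path=None,
    maf_min: float = None,
) -> GenotypeRegion:
    """Read an additive genotype matrix for one region.

    ``format`` is one of ``vcf``, ``plink_raw``, ``csv`` or ``auto``
    (extension-based).  Only biallelic SNPs are kept (multiallelic records
    are skipped with a log line); missing genotypes are mean-imputed per
    SNP; ``maf_min`` optionally drops SNPs below a minor-allele-frequency
    threshold.
    """
    path = str(path)
    if format == "auto":
        if path.endswith((".vcf", ".vcf.gz", ".bcf")):
            format = "vcf"
        elif path.endswith(".raw"):
            format = "plink_raw"
        else:
            format = "csv"
    if format == "vcf":
        samples, pos, G = _read_vcf(path, region)
        return _finalize(samples, pos, G, None, region, maf_min)
    if format == "plink_raw":
        subjects, pos, G, snps = _read_plink_raw(path, positions_path)
        return _finalize(subjects, pos, G, snps, region, maf_min)
    if format == "csv":
        subjects, pos, G, snps = _read_csv_matrix(path, positions_path)
        return _finalize(subjects, pos, G, snps, region, maf_min)
    raise ValueError(f"unknown genotype format {format!r}")


# -- phenotypes ----------------------------------------------------------


def read_phenotypes(path, layout: str = "auto") -> LongitudinalPhenotype:
    """Read a longitudinal trait table.

    Wide layout: first column subject id, remaining columns one per time
    point (numeric headers are used as the time grid).  Long layout:
    columns (subject, time, value).  Subjects missing any time point are
    dropped with a logged count; duplicate (subject, time) rows are an
    error.
    """
    df = pd.read_csv(path)
    if layout == "auto":
        lowered = [c.lower() for c in df.columns]
        layout = "long" if len(df.columns) == 3 and "time" in lowered else "wide"
    if layout == "long":
        df.columns = [c.lower() for c in df.columns]
        sub, tim, val = df.columns[:3]
        if df.duplicated([sub, tim]).any():
            raise ValueError("duplicate (subject, time) rows in long phenotype table")
        wide = df.pivot(index=sub, columns=tim, values=val)
    elif layout == "wide":
        wide = df.set_index(df.columns[0])
        wide.columns = [float(c) for c in wide.columns]
    else:
        raise ValueError(f"unknown phenotype layout {layout!r}")
    wide = wide.sort_index(axis=1)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        log.warning("dropped %d subjects with incomplete time series", dropped)
    if complete.empty:
        raise ValueError("no subjects with complete time series")
    return LongitudinalPhenotype(
        subject_ids=complete.index.to_numpy(),
        time_grid=np.asarray(list(complete.columns), float),
        Y=complete.to_numpy(dtype=float),
    )


def align_subjects(geno: GenotypeRegion, pheno: LongitudinalPhenotype):
    """Subset and reorder both datasets to their shared subjects."""
    g_ids = geno.subject_ids.astype(str)
    p_ids = pheno.subject_ids.astype(str)
    shared = [s for s in g_ids if s in set(p_ids)]
    if not shared:
        raise ValueError("no shared subjects between genotypes and phenotypes")
    gi = {s: i for i, s in enumerate(g_ids)}
    pi = {s: i for i, s in enumerate(p_ids)}
    g_idx = np.array([gi[s] for s in shared])
    p_idx = np.array([pi[s] for s in shared])
    geno2 = GenotypeRegion(
        subject_ids=geno.subject_ids[g_idx],
        positions=geno.positions,
        G=geno.G[g_idx],
        maf_param=geno.maf_param,
        positions_bp=geno.positions_bp,
        region_id=geno.region_id,
    )
    pheno2 = LongitudinalPhenotype(
        subject_ids=geno.subject_ids[g_idx],
        time_grid=pheno.time_grid,
        Y=pheno.Y[p_idx],
    )
    return geno2, pheno2


# -- writers -------------------------------------------------------------


def write_vcf(geno: GenotypeRegion, path, contig: str = "1") -> None:
    """Write genotypes as a minimal uncompressed VCF (synthetic contig)."""
    if geno.positions_bp is not None:
        pos_bp = geno.positions_bp.astype(int)
    else:
        pos_bp = np.round(geno.positions * 1000).astype(int) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in geno.subject_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for l in range(geno.L):
            calls = "\t".join(gt_map[int(round(g))] for g in geno.G[:, l])
            fh.write(f"{contig}\t{pos_bp[l]}\tsnp{l + 1}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def write_phenotypes(pheno: LongitudinalPhenotype, path, layout: str = "wide") -> None:
    if layout == "wide":
        df = pd.DataFrame(pheno.Y, columns=[f"{t:g}" for t in pheno.time_grid])
        df.insert(0, "subject", pheno.subject_ids)
        df.to_csv(path, index=False)
    elif layout == "long":
        rows = [
            {"subject": s, "time": t, "value": v}
            for s, row in zip(pheno.subject_ids, pheno.Y)
            for t, v in zip(pheno.time_grid, row)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def write_genotypes_csv(geno: GenotypeRegion, path, positions_path=None) -> None:
    df = pd.DataFrame(geno.G, columns=[f"snp{l + 1}" for l in range(geno.L)])
    df.insert(0, "subject", geno.subject_ids)
    df.to_csv(path, index=False)
    if positions_path is not None:
        pos = geno.positions_bp if geno.positions_bp is not None else np.round(geno.positions * 1000) + 1
        pd.DataFrame({"snp": [f"snp{l + 1}" for l in range(geno.L)], "pos": pos}).to_csv(
            positions_path, index=False
        )


def write_results_tsv(rows, path) -> None:
    """Per-region association table: region_id, n_snps, p_t1..p_tQ+1."""
    if not rows:
        raise ValueError("no result rows to write")
    n_times = len(rows[0]["p_by_time"])
    header = ["region_id", "n_snps"] + [f"p_t{q + 1}" for q in range(n_times)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fields = [str(row["region_id"]), str(row["n_snps"])] + [
                f"{p:.6g}" for p in row["p_by_time"]
            ]
            fh.write("\t".join(fields) + "\n")
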