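"""Genotype data model and SNP-panel construction.

Dosages always count the panel-wide *minor* allele, so a value of 2 means two
copies of the less frequent allele. Missing calls are ``nan`` until
:func:`impute_mean` replaces them with the per-variant mean dosage, after which
dosages may be fractional in [0, 2].

Panel construction mirrors common resequencing practice: keep biallelic SNPs
with strictly less than 5% missing calls and strictly more than 5% minor
allele frequency, then mean-impute the remainder.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "load_vcf",
    "load_dosage_tsv",
    "write_dosage_tsv",
    "write_variant_metadata",
    "write_vcf",
    "filter_variants",
    "impute_mean",
]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with its panel-level summary statistics."""

    chrom: str
    pos: int  # 1-based, bp
    ref: str
    alt: str
    maf: float
    missing_rate: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf out of [0, 0.5]: {self.maf}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError(f"missing_rate out of [0, 1]: {self.missing_rate}")

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}_{self.ref}/{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants, dosages counting the minor allele."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # n_samples x n_variants, float, nan = missing
    imputed: bool = False

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.imputed and np.isnan(self.dosages).any():
            raise ValueError("imputed matrix may not contain missing values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.vid for v in self.variants]


def _summarize_column(col: np.ndarray) -> tuple[float, float]:
    """(maf, missing_rate) of one minor-oriented dosage column."""
    obs = col[~np.isnan(col)]
    missing_rate = 1.0 - obs.size / col.size
    maf = float(obs.mean() / 2.0) if obs.size else 0.0
    return min(maf, 0.5), missing_rate


def _orient_minor(dosages: np.ndarray, refs: list[str], alts: list[str]):
    """Flip columns so the dosage counts the observed minor allele."""
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            dosages[:, j] = 2.0 - col
            refs[j], alts[j] = alts[j], refs[j]
    return dosages, refs, alts


def _build(sample_ids, chroms, poss, refs, alts, dosages, imputed=False,
           sort=True) -> GenotypeMatrix:
    dosages, refs, alts = _orient_minor(np.asarray(dosages, float), list(refs), list(alts))
    records = []
    for j, (c, p, r, a) in enumerate(zip(chroms, poss, refs, alts)):
        maf, miss = _summarize_column(dosages[:, j])
        records.append(VariantRecord(str(c), int(p), r, a, maf, miss))
    if sort:
        order = sorted(range(len(records)), key=lambda j: (records[j].chrom, records[j].pos))
        records = [records[j] for j in order]
        dosages = dosages[:, order]
    return GenotypeMatrix(list(sample_ids), records, dosages, imputed=imputed)


def load_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF, keeping only biallelic SNP records.

    Genotype calls are converted to alternate-allele counts and then recoded so
    dosages count the panel-wide minor allele. Multiallelic sites, indels and
    symbolic alleles are dropped silently (the biallelic-SNP contract).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains zero samples")
    chroms, poss, refs, alts, cols = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or not var.ALT[0].isalpha():
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown->3 in cyvcf2 is UNKNOWN, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(dose)
    if not cols:
        raise ValueError(f"VCF {path} contains no biallelic SNP records")
    dosages = np.column_stack(cols)
    return _build(samples, chroms, poss, refs, alts, dosages)


def load_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the TSV dosage dialect: header of 'chrom:pos_ref/alt' ids, first
    column the sample id, 'NA' for missing."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    chroms, poss, refs, alts = [], [], [], []
    for vid in df.columns:
        loc, alleles = vid.split("_")
        chrom, pos = loc.rsplit(":", 1)
        ref, alt = alleles.split("/")
        chroms.append(chrom)
        poss.append(int(pos))
        refs.append(ref)
        alts.append(alt)
    dosages = df.to_numpy(dtype=float)
    imputed = not np.isnan(dosages).any() and not np.all(np.isin(dosages[~np.isnan(dosages)], [0.0, 1.0, 2.0]))
    return _build([str(s) for s in df.index], chroms, poss, refs, alts, dosages,
                  imputed=imputed, sort=False)


def write_dosage_tsv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(g.variant_ids()) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = ["NA" if np.isnan(v) else f"{v:g}" for v in g.dosages[i]]
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def write_variant_metadata(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tmaf\tmissing_rate\n")
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.maf:.6g}\t{v.missing_rate:.6g}\n")


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with GT fields.

    Only defined for unimputed matrices (dosages in {0,1,2} or missing); the
    written ALT allele is the minor allele so a round-trip through
    :func:`load_vcf` reproduces the dosage matrix exactly.
    """
    obs = g.dosages[~np.isnan(g.dosages)]
    if not np.all(np.isin(obs, [0.0, 1.0, 2.0])):
        raise ValueError("write_vcf requires integral (unimputed) dosages")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms_seen = []
        for v in g.variants:
            if v.chrom not in chroms_seen:
                chroms_seen.append(v.chrom)
        for c in chroms_seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, v in enumerate(g.variants):
            calls = ["./." if np.isnan(d) else gt_map[d] for d in g.dosages[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def filter_variants(g: GenotypeMatrix, max_missing: float = 0.05,
                    min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep variants with missing_rate < max_missing and maf > min_maf.

    Both inequalities are strict. Order is preserved and the operation is
    idempotent. Raises if every variant fails.
    """
    if g.imputed:
        raise ValueError("filter before imputation: filtering an imputed matrix is not supported")
    keep = [j for j, v in enumerate(g.variants)
            if v.missing_rate < max_missing and v.maf > min_maf]
    if not keep:
        raise ValueError("all variants removed by filtering: empty panel")
    return GenotypeMatrix(
        list(g.sample_ids),
        [g.variants[j] for j in keep],
        g.dosages[:, keep].copy(),
        imputed=False,
    )


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the variant's mean observed dosage."""
    d = g.dosages.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [g.variants[j].vid for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"variants with zero observed calls cannot be mean-imputed: {bad[:5]}")
    col_means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = col_means[idx[1]]
    return GenotypeMatrix(list(g.sample_ids), list(g.variants), d, imputed=True)
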