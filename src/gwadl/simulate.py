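"""Structured-population genotype and phenotype simulation with known truth.

Genotypes follow the Balding-Nichols model: each locus has an ancestral
frequency p ~ U(0.05, 0.95) and per-deme frequencies drawn from
Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst); individual dosages are Binomial(2, f)
draws at their deme's frequency. Linkage disequilibrium is emulated by
arranging markers in blocks: within a block each column copies the previous
one, redrawing each individual's genotype with a small switch probability, so
correlation decays geometrically along the block.

Phenotypes combine a sparse set of large-effect QTNs with a polygenic
background of many tiny effects, replicated over r common-garden blocks with
residual noise calibrated so the realized individual-observation heritability
hits its target. "Confounded" null markers — zero causal effect but strongly
deme-differentiated allele frequencies — are planted to exercise the
structure-correction machinery; the default frequencies (0.77 vs 0.016)
mirror the kind of east/west stratification seen in range-wide poplar
collections.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._utils import derive_seed
from .geno import GenotypeMatrix, VariantRecord, write_dosage_tsv, write_vcf
from .pheno import PhenotypeTable, heritability_from_components

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes",
           "simulate_phenotypes", "simulate_dataset", "export_fixture",
           "hudson_fst"]


@dataclass
class SimConfig:
    n_individuals: int = 313
    deme_proportions: tuple[float, float] = (0.5, 0.5)
    fst: float = 0.1
    n_snps: int = 5000
    n_chromosomes: int = 10
    marker_spacing_bp: int = 10_000
    ld_block_len: int = 20
    ld_switch_prob: float = 0.05
    n_qtns: int = 8
    qtn_effects: tuple | None = None  # fixed effects; None = standard-normal draws
    polygenic_fraction: float = 0.15  # share of genetic variance from background
    n_polygenic: int = 1000
    h2_indiv: float = 0.47
    r: int = 3
    deme_shift: float = 0.0  # trait offset between demes, in genetic-SD units
    confounded_markers: tuple = ()  # (freq_deme1, freq_deme2) pairs, zero effect
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.deme_proportions) - 1.0) > 1e-9:
            raise ValueError("deme proportions must sum to 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie strictly in (0, 1)")
        if not (0.0 < self.h2_indiv <= 1.0):
            raise ValueError("target h2_indiv must lie in (0, 1]")
        if not (0.0 <= self.polygenic_fraction <= 1.0):
            raise ValueError("polygenic_fraction must lie in [0, 1]")

    @property
    def h2_geno(self) -> float:
        """Line-level heritability implied by the individual target and r."""
        return heritability_from_components(
            self.h2_indiv, 1.0 - self.h2_indiv, self.r).h2_geno


@dataclass
class SimTruth:
    deme: np.ndarray                      # per-individual deme label (0/1)
    ancestral_freq: np.ndarray            # per-locus, pre-orientation
    deme_freqs: np.ndarray                # n_demes x n_snps, minor-oriented
    confounded_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    qtn_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    qtn_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    polygenic_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    polygenic_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    genetic_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    vg: float = np.nan                    # realized genetic variance
    ve: float = np.nan                    # residual variance per observation
    h2_indiv: float = np.nan              # realized, from vg and ve
    h2_geno: float = np.nan


def _deme_labels(cfg: SimConfig) -> np.ndarray:
    n1 = int(round(cfg.n_individuals * cfg.deme_proportions[0]))
    return np.array([0] * n1 + [1] * (cfg.n_individuals - n1))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a structured genotype panel; returns the matrix plus ground truth."""
    rng = np.random.default_rng(derive_seed(cfg.seed, 1))
    n = cfg.n_individuals
    deme = _deme_labels(cfg)
    n_demes = 2
    m_core = cfg.n_snps - len(cfg.confounded_markers)
    if m_core < 1:
        raise ValueError("n_snps too small for the confounded-marker list")
    a_scale = (1.0 - cfg.fst) / cfg.fst

    dos = np.empty((n, cfg.n_snps))
    anc = np.empty(cfg.n_snps)
    dfreq = np.empty((n_demes, cfg.n_snps))

    block_len = max(cfg.ld_block_len, 1)
    j = 0
    while j < m_core:
        L = min(block_len, m_core - j)
        p = rng.uniform(0.05, 0.95)
        f = rng.beta(p * a_scale, (1.0 - p) * a_scale, size=n_demes)
        f = np.clip(f, 1e-4, 1.0 - 1e-4)
        col = rng.binomial(2, f[deme]).astype(float)
        for t in range(L):
            if t > 0:
                switch = rng.random(n) < cfg.ld_switch_prob
                if switch.any():
                    col = col.copy()
                    col[switch] = rng.binomial(2, f[deme[switch]])
            dos[:, j + t] = col
            anc[j + t] = p
            dfreq[:, j + t] = f
        j += L

    for ci, (f1, f2) in enumerate(cfg.confounded_markers):
        jj = m_core + ci
        f = np.array([f1, f2], dtype=float)
        dos[:, jj] = rng.binomial(2, f[deme])
        anc[jj] = float(f.mean())
        dfreq[:, jj] = f
    confounded_idx = np.arange(m_core, cfg.n_snps)

    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = np.nan

    # orient to the panel-wide minor allele, keeping truth bookkeeping in sync
    pooled = np.nanmean(dos, axis=0) / 2.0
    flip = pooled > 0.5
    dos[:, flip] = 2.0 - dos[:, flip]
    dfreq[:, flip] = 1.0 - dfreq[:, flip]
    anc[flip] = 1.0 - anc[flip]

    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chromosomes))
    variants = []
    for jj in range(cfg.n_snps):
        chrom = f"Chr{jj // per_chrom + 1:02d}"
        pos = (jj % per_chrom + 1) * cfg.marker_spacing_bp
        col = dos[:, jj]
        obs = col[~np.isnan(col)]
        maf = min(float(obs.mean() / 2.0), 0.5) if obs.size else 0.0
        miss = 1.0 - obs.size / n
        ref, alt = ("A", "T") if not flip[jj] else ("T", "A")
        variants.append(VariantRecord(chrom, pos, ref, alt, maf, miss))

    g = GenotypeMatrix([f"g{i:04d}" for i in range(n)], variants, dos,
                       imputed=False)
    truth = SimTruth(deme=deme, ancestral_freq=anc, deme_freqs=dfreq,
                     confounded_indices=confounded_idx)
    return g, truth


def simulate_phenotypes(g: GenotypeMatrix, truth: SimTruth, cfg: SimConfig,
                        trait: str = "trait1") -> tuple[PhenotypeTable, SimTruth]:
    """Replicated phenotypes with sparse + polygenic architecture.

    The residual variance is set from the *realized* genetic variance so the
    realized individual-observation heritability matches the target in
    expectation; the line-level heritability then follows from r.
    """
    import pandas as pd

    rng = np.random.default_rng(derive_seed(cfg.seed, 2))
    n, m = g.dosages.shape
    D = np.nan_to_num(g.dosages, nan=1.0)
    eligible = np.setdiff1d(np.arange(m), truth.confounded_indices)

    sparse_share = 1.0 - cfg.polygenic_fraction
    gv = np.zeros(n)
    qtn_idx = np.empty(0, int)
    beta = np.empty(0)
    if cfg.n_qtns > 0 and sparse_share > 0:
        qtn_idx = np.sort(rng.choice(eligible, size=cfg.n_qtns, replace=False))
        beta = (np.asarray(cfg.qtn_effects, float) if cfg.qtn_effects is not None
                else rng.normal(0.0, 1.0, cfg.n_qtns))
        # equalize-ish leverage: scale each effect by its column sd so no QTN
        # is silenced by low MAF
        sd = D[:, qtn_idx].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        g_sparse = D[:, qtn_idx] @ (beta / sd)
        vs = g_sparse.var()
        if vs > 0:
            scale = np.sqrt(sparse_share / vs)
            beta = beta / sd * scale
            g_sparse = g_sparse * scale
        gv = gv + g_sparse
    poly_idx = np.empty(0, int)
    poly_beta = np.empty(0)
    if cfg.polygenic_fraction > 0 and cfg.n_polygenic > 0:
        pool = np.setdiff1d(eligible, qtn_idx)
        poly_idx = np.sort(rng.choice(pool, size=min(cfg.n_polygenic, pool.size),
                                      replace=False))
        poly_beta = rng.normal(0.0, 1.0, poly_idx.size)
        g_poly = D[:, poly_idx] @ poly_beta
        vp = g_poly.var()
        if vp > 0:
            scale = np.sqrt(cfg.polygenic_fraction / vp)
            poly_beta = poly_beta * scale
            g_poly = g_poly * scale
        gv = gv + g_poly

    vg = float(gv.var())
    if vg == 0:
        if cfg.h2_indiv >= 1.0:
            raise ValueError("h2_indiv = 1 is unreachable with no genetic variance")
        ve = 1.0  # pure-noise trait: unit residual variance
    else:
        ve = vg * (1.0 - cfg.h2_indiv) / cfg.h2_indiv
    if cfg.deme_shift != 0.0:
        shift_sd = np.sqrt(vg) if vg > 0 else 1.0
        gv_env = cfg.deme_shift * shift_sd * (truth.deme - truth.deme.mean())
    else:
        gv_env = 0.0

    rows = []
    noise_sd = np.sqrt(ve)
    pheno_mean = gv + gv_env
    for b in range(1, cfg.r + 1):
        e = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        vals = pheno_mean + e
        for i, sid in enumerate(g.sample_ids):
            rows.append((sid, f"block{b}", trait, vals[i]))
    table = PhenotypeTable(pd.DataFrame(rows, columns=list(PhenotypeTable.COLUMNS)))

    est = heritability_from_components(vg if vg > 0 else 0.0, ve, cfg.r)
    truth.qtn_indices = qtn_idx
    truth.qtn_effects = beta
    truth.polygenic_indices = poly_idx
    truth.polygenic_effects = poly_beta
    truth.genetic_values = gv
    truth.vg = vg
    truth.ve = float(ve)
    truth.h2_indiv = est.h2_indiv
    truth.h2_geno = est.h2_geno
    return table, truth


def simulate_dataset(cfg: SimConfig, trait: str = "trait1"):
    """Genotypes + phenotypes + truth in one call."""
    g, truth = simulate_genotypes(cfg)
    p, truth = simulate_phenotypes(g, truth, cfg, trait=trait)
    return g, p, truth


def hudson_fst(dosages: np.ndarray, deme: np.ndarray) -> float:
    """Hudson's Fst estimator averaged over loci (ratio of averages)."""
    d0 = dosages[deme == 0]
    d1 = dosages[deme == 1]
    p0 = np.nanmean(d0, axis=0) / 2.0
    p1 = np.nanmean(d1, axis=0) / 2.0
    n0 = 2 * d0.shape[0]
    n1 = 2 * d1.shape[0]
    num = (p0 - p1) ** 2 - p0 * (1 - p0) / (n0 - 1) - p1 * (1 - p1) / (n1 - 1)
    den = p0 * (1 - p1) + p1 * (1 - p0)
    keep = den > 0
    return float(np.sum(num[keep]) / np.sum(den[keep]))


def export_fixture(g: GenotypeMatrix, p: PhenotypeTable, truth: SimTruth,
                   out_dir: str | os.PathLike) -> dict[str, str]:
    """Write VCF + phenotype TSV + truth JSON; round-trips losslessly."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "dosages": os.path.join(out_dir, "dosages.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(g, paths["vcf"])
    write_dosage_tsv(g, paths["dosages"])
    p.to_tsv(paths["phenotypes"])
    payload = {
        "deme": truth.deme.tolist(),
        "qtn_indices": truth.qtn_indices.tolist(),
        "qtn_effects": truth.qtn_effects.tolist(),
        "polygenic_indices": truth.polygenic_indices.tolist(),
        "confounded_indices": truth.confounded_indices.tolist(),
        "vg": None if np.isnan(truth.vg) else truth.vg,
        "ve": None if np.isnan(truth.ve) else truth.ve,
        "h2_indiv": None if np.isnan(truth.h2_indiv) else truth.h2_indiv,
        "h2_geno": None if np.isnan(truth.h2_geno) else truth.h2_geno,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths
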