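"""Phenotype normalization and broad-sense heritability.

Trait vectors are Box-Cox transformed with the exponent chosen on a fixed grid
(lambda in [-5, 5] by 0.1) to maximize the Shapiro-Wilk W of the transformed
values. Heritability uses the repeatability method on a balanced one-way
ANOVA with genotype as the factor:

    Vg = (MS(G) - MS(E)) / r,  Ve = MS(E)
    H2indiv = Vg / (Vg + Ve)          (single observations)
    H2geno  = Vg / (Vg + Ve / r)      (genotype means across r blocks)
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "BoxCoxResult",
    "HeritabilityEstimate",
    "boxcox_transform",
    "boxcox_search",
    "heritability_repeatability",
    "heritability_from_components",
    "write_heritability_report",
]


@dataclass
class PhenotypeTable:
    """Long-format replicated trait measurements (genotype x block x trait)."""

    data: pd.DataFrame  # columns: genotype_id, block_id, trait, value

    COLUMNS = ("genotype_id", "block_id", "trait", "value")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["value"].to_numpy(float)).all():
            raise ValueError("phenotype values must be finite")
        dup = self.data.duplicated(subset=["genotype_id", "block_id", "trait"])
        if dup.any():
            raise ValueError("duplicate (genotype, block, trait) records")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def balanced_subset(self, trait: str) -> tuple[pd.DataFrame, int, int]:
        """Rows for one trait restricted to genotypes observed in all blocks.

        Returns (rows, r, n_dropped_genotypes). Genotypes lacking the full
        complement of blocks are dropped, since the repeatability formulas
        assume a balanced design.
        """
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        counts = sub.groupby("genotype_id")["block_id"].nunique()
        r = int(counts.max())
        keep = counts[counts == r].index
        dropped = len(counts) - len(keep)
        return sub[sub["genotype_id"].isin(keep)], r, dropped

    def genotype_means(self, trait: str) -> pd.Series:
        sub, _, _ = self.balanced_subset(trait)
        return sub.groupby("genotype_id")["value"].mean()


@dataclass
class BoxCoxResult:
    lam: float
    w_statistic: float
    transformed: np.ndarray
    shift: float


@dataclass
class HeritabilityEstimate:
    ms_g: float
    ms_e: float
    vg: float
    ve: float
    r: int
    h2_indiv: float
    h2_geno: float
    truncated: bool = False  # MS(G) < MS(E) forced Vg to 0


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """(y^lam - 1)/lam for lam != 0, log(y) for lam == 0; y must be > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if lam == 0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_search(y: np.ndarray, grid_lo: float = -5.0, grid_hi: float = 5.0,
                  step: float = 0.1, shift: bool = True) -> BoxCoxResult:
    """Pick the grid lambda maximizing Shapiro-Wilk W of the transformed trait.

    Non-positive traits are shifted by 1 - min(y) first (order-preserving).
    Ties in W are broken toward the lambda closest to 1, i.e. the gentlest
    transform.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant trait: Shapiro-Wilk W undefined")
    offset = 0.0
    if y.min() <= 0:
        if not shift:
            raise ValueError("non-positive values with shift disabled")
        offset = 1.0 - y.min()
    ys = y + offset
    n_steps = int(round((grid_hi - grid_lo) / step))
    grid = np.round(grid_lo + step * np.arange(n_steps + 1), 10)
    best = None
    for lam in grid:
        z = boxcox_transform(ys, float(lam))
        if not np.isfinite(z).all() or np.ptp(z) == 0:
            continue
        w = float(stats.shapiro(z).statistic)
        key = (w, -abs(lam - 1.0))
        if best is None or key > best[0]:
            best = (key, float(lam), w, z)
    if best is None:
        raise ValueError("no lambda on the grid produced a finite transform")
    _, lam, w, z = best
    return BoxCoxResult(lam=lam, w_statistic=w, transformed=z, shift=offset)


def _anova_ms(values: np.ndarray) -> tuple[float, float]:
    """Balanced one-way ANOVA mean squares from a genotypes x blocks array."""
    n_g, r = values.shape
    grand = values.mean()
    gmeans = values.mean(axis=1)
    ss_g = r * np.sum((gmeans - grand) ** 2)
    ss_e = np.sum((values - gmeans[:, None]) ** 2)
    ms_g = ss_g / (n_g - 1)
    ms_e = ss_e / (n_g * (r - 1))
    return float(ms_g), float(ms_e)


def heritability_from_components(vg: float, ve: float, r: int) -> HeritabilityEstimate:
    """Heritabilities implied by variance components under the repeatability model."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    vp_indiv = vg + ve
    vp_geno = vg + ve / r
    h2i = vg / vp_indiv if vp_indiv > 0 else 0.0
    h2g = vg / vp_geno if vp_geno > 0 else 0.0
    return HeritabilityEstimate(
        ms_g=r * vg + ve, ms_e=ve, vg=vg, ve=ve, r=r,
        h2_indiv=h2i, h2_geno=h2g,
    )


def heritability_repeatability(p: PhenotypeTable, trait: str) -> HeritabilityEstimate:
    """Repeatability-method broad-sense heritability for one trait.

    Requires >= 2 genotypes observed in r >= 2 blocks (genotypes with
    incomplete block coverage are dropped). A negative Vg (MS(G) < MS(E)) is
    truncated to zero and flagged.
    """
    sub, r, _ = p.balanced_subset(trait)
    if r < 2:
        raise ValueError("r = 1: genotypic variance is not estimable")
    wide = sub.pivot(index="genotype_id", columns="block_id", values="value")
    values = wide.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    ms_g, ms_e = _anova_ms(values)
    vg = (ms_g - ms_e) / r
    truncated = vg < 0
    vg = max(vg, 0.0)
    est = heritability_from_components(vg, ms_e, r)
    return HeritabilityEstimate(ms_g=ms_g, ms_e=ms_e, vg=vg, ve=ms_e, r=r,
                                h2_indiv=est.h2_indiv, h2_geno=est.h2_geno,
                                truncated=truncated)


def write_heritability_report(p: PhenotypeTable, path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    for trait in p.traits():
        est = heritability_repeatability(p, trait)
        rows.append({"trait": trait, "MS_G": est.ms_g, "MS_E": est.ms_e,
                     "Vg": est.vg, "Ve": est.ve, "r": est.r,
                     "H2indiv": est.h2_indiv, "H2geno": est.h2_geno})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
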