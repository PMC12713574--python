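"""Accuracy metrics and method comparison.

Prediction accuracy is compared per (method, marker-set) cell on fold-level
R^2 values sharing the same seeded partitions, so the comparison is paired.
Heritable variance explained (HVE) normalizes accuracy by the line-level
heritability: HVE = 100 * R^2 / H2geno; values above 100% are possible and
flagged as likely inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import PredictionResult

__all__ = ["MethodComparison", "heritable_variance_explained",
           "compare_methods", "assign_letters"]


def heritable_variance_explained(r2: float, h2_geno: float) -> float:
    """100 * r2 / h2_geno; raises on a non-positive denominator."""
    if h2_geno <= 0:
        raise ValueError("h2_geno must be > 0")
    return 100.0 * r2 / h2_geno


@dataclass
class MethodComparison:
    table: pd.DataFrame          # method, fold, r2 (+ hve when h2 given)
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame          # pairwise adjusted p-values
    letters: dict[str, str]      # compact letter display

    def summary(self) -> str:
        means = self.table.groupby("method")["r2"].agg(["mean", "std"])
        lines = ["Method comparison (fold-level R^2)", "=" * 44]
        for meth, row in means.iterrows():
            lines.append(f"{meth:24s} {row['mean']:.3f} +/- {row['std']:.3f}  "
                         f"[{self.letters[meth]}]")
        lines.append(f"one-way ANOVA: F = {self.anova_f:.3f}, p = {self.anova_p:.3g}")
        return "\n".join(lines)


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values via the studentized-range distribution."""
    names = list(groups)
    k = len(names)
    ns = {g: groups[g].size for g in names}
    df_e = sum(ns.values()) - k
    mse = sum(float(np.sum((groups[g] - groups[g].mean()) ** 2)) for g in names) / df_e
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = groups[a].mean() - groups[b].mean()
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_e))
            rows.append({"group1": a, "group2": b, "meandiff": diff,
                         "p_adj": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)


def assign_letters(names: list[str], means: dict[str, float],
                   sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different (insert-and-absorb algorithm)."""
    order = sorted(names, key=lambda g: -means[g])
    cols: list[set[str]] = [set(order)]
    for a in order:
        for b in order:
            if a >= b or not sig.get((a, b), sig.get((b, a), False)):
                continue
            new_cols = []
            for col in cols:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            cols = [c for c in new_cols
                    if not any(c < d for d in new_cols)]
            # dedupe
            uniq = []
            for c in cols:
                if c not in uniq:
                    uniq.append(c)
            cols = uniq
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in names}
    for li, col in enumerate(cols):
        ch = chr(ord("a") + li)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in names}


def compare_methods(results: dict[str, PredictionResult],
                    h2_geno: float | None = None,
                    alpha: float = 0.05) -> MethodComparison:
    """One-way ANOVA + Tukey HSD across method cells on fold-level R^2."""
    sizes = {name: res.fold_r2.size for name, res in results.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"unequal fold counts across methods: {sizes}")
    groups = {name: np.asarray(res.fold_r2, float) for name, res in results.items()}
    rows = []
    for name, r2s in groups.items():
        for f, r2 in enumerate(r2s):
            row = {"method": name, "fold": f, "r2": r2}
            if h2_geno is not None:
                row["hve"] = heritable_variance_explained(r2, h2_geno)
            rows.append(row)
    table = pd.DataFrame(rows)
    if all(np.allclose(g, list(groups.values())[0]) for g in groups.values()):
        fstat, pval = 0.0, 1.0
    else:
        fstat, pval = stats.f_oneway(*groups.values())
    tukey = _tukey_pairwise(groups)
    sig = {(r["group1"], r["group2"]): bool(r["p_adj"] < alpha)
           for _, r in tukey.iterrows()}
    means = {g: float(groups[g].mean()) for g in groups}
    letters = assign_letters(list(groups), means, sig)
    return MethodComparison(table=table, anova_f=float(fstat),
                            anova_p=float(pval), tukey=tukey, letters=letters)
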