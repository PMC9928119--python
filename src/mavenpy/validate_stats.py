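"""Confirmatory statistics for candidate regions.

After the sparse model nominates a region, its signal is checked with
conventional tests: a two-factor ANOVA (phenotype × genotype, with
interaction) asking whether phenotype predicts the region's signal across
genotype classes, with per-genotype post-hoc phenotype contrasts under
Šidák multiplicity control; and the Mann–Whitney U test for small
two-group comparisons (e.g. unrescued vs rescued mutants).

Type III sums of squares are used because sorting larvae by behavior
yields unbalanced cells; on balanced designs Type III coincides with the
textbook decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["AnovaResult", "two_way_anova", "mann_whitney_u"]

_EPS_SS = 1e-12


@dataclass
class EffectRow:
    name: str
    ss: float
    df: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Two-factor ANOVA table plus within-genotype post-hoc contrasts.

    ``effects`` maps 'phenotype', 'genotype', 'interaction' (when estimable)
    and 'residual' to (SS, df, F, p); ``posthoc`` maps each genotype level to
    the phenotype contrast within it, with raw and multiplicity-adjusted p.
    """

    effects: dict
    posthoc: dict
    ss_total: float
    interaction_estimable: bool
    adjust: str

    def p(self, effect: str) -> float:
        return self.effects[effect].p


def _closed_cell_stats(df: pd.DataFrame):
    cells = df.groupby(["phenotype", "genotype"], observed=True)["signal"]
    return cells.mean(), cells.count()


def two_way_anova(
    signal: np.ndarray,
    phenotype: np.ndarray,
    genotype: np.ndarray,
    adjust: str = "sidak",
) -> AnovaResult:
    """Two-factor ANOVA of a region's signal on phenotype × genotype.

    Uses Type III sums of squares (sum-to-zero contrasts) so unbalanced cell
    counts do not conflate main effects; the interaction is dropped with a
    warning when an empty cell makes it inestimable.  Post-hoc: the
    phenotype contrast within each genotype, a t-test pooling the ANOVA
    residual variance, adjusted by Šidák (default) or Bonferroni.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if adjust not in ("sidak", "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    signal = np.asarray(signal, dtype=np.float64)
    phenotype = np.asarray(phenotype)
    genotype = np.asarray(genotype, dtype=object)
    if len(signal) != len(phenotype) or len(signal) != len(genotype):
        raise ValidationError("signal, phenotype, genotype lengths differ")
    if len(np.unique(phenotype)) < 2 or len(np.unique(genotype)) < 2:
        raise ValidationError("each factor needs >= 2 observed levels")
    df = pd.DataFrame(
        {
            "signal": signal,
            "phenotype": pd.Categorical([str(v) for v in phenotype]),
            "genotype": pd.Categorical([str(v) for v in genotype]),
        }
    )
    n_cells_possible = df["phenotype"].cat.categories.size * df["genotype"].cat.categories.size
    occupied = df.groupby(["phenotype", "genotype"], observed=True).size()
    interaction_estimable = occupied.size == n_cells_possible
    if interaction_estimable:
        formula = "signal ~ C(phenotype, Sum) * C(genotype, Sum)"
    else:
        warnings.warn(
            "empty phenotype x genotype cell: interaction dropped, "
            "main-effects-only model fitted",
            stacklevel=2,
        )
        formula = "signal ~ C(phenotype, Sum) + C(genotype, Sum)"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=3)

    def _row(label_contains: str, name: str) -> EffectRow:
        idx = [
            i
            for i in table.index
            if label_contains in i and (":" in i) == (name == "interaction")
        ]
        row = table.loc[idx[0]]
        ss, dfree = float(row["sum_sq"]), float(row["df"])
        F, p = float(row["F"]), float(row["PR(>F)"])
        ss_res = float(table.loc["Residual", "sum_sq"])
        if ss_res < _EPS_SS and ss < _EPS_SS:
            F, p = 0.0, 1.0  # no variation anywhere: nothing to test
        elif np.isnan(F):
            F, p = 0.0, 1.0
        return EffectRow(name, ss, dfree, F, p)

    effects = {
        "phenotype": _row("C(phenotype, Sum)", "phenotype"),
        "genotype": _row("C(genotype, Sum)", "genotype"),
    }
    if interaction_estimable:
        effects["interaction"] = _row(":", "interaction")
    res = table.loc["Residual"]
    effects["residual"] = EffectRow(
        "residual", float(res["sum_sq"]), float(res["df"]), np.nan, np.nan
    )

    # post-hoc: phenotype contrast within each genotype, pooled residual MSE
    mse = effects["residual"].ss / effects["residual"].df if effects["residual"].df > 0 else 0.0
    df_res = effects["residual"].df
    levels_p = list(df["phenotype"].cat.categories)
    posthoc = {}
    contrasts = []
    for geno in df["genotype"].cat.categories:
        sub = df[df["genotype"] == geno]
        groups = {lv: sub.loc[sub["phenotype"] == lv, "signal"] for lv in levels_p}
        if any(len(g) == 0 for g in groups.values()):
            continue
        a, b = groups[levels_p[0]], groups[levels_p[1]]
        diff = float(b.mean() - a.mean())
        if mse > _EPS_SS:
            se = float(np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b))))
            t = diff / se
            p_raw = float(2.0 * stats.t.sf(abs(t), df_res))
        else:
            t, p_raw = 0.0, 1.0
        contrasts.append((str(geno), diff, t, p_raw))
    k = len(contrasts)
    for geno, diff, t, p_raw in contrasts:
        if adjust == "sidak":
            p_adj = float(1.0 - (1.0 - p_raw) ** k)
        else:
            p_adj = float(min(1.0, p_raw * k))
        posthoc[geno] = {"diff": diff, "t": t, "p_raw": p_raw, "p_adj": p_adj}

    ss_total = float(((signal - signal.mean()) ** 2).sum())
    return AnovaResult(
        effects=effects,
        posthoc=posthoc,
        ss_total=ss_total,
        interaction_estimable=interaction_estimable,
        adjust=adjust,
    )


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Mann–Whitney U (two-sided) for two independent samples.

    ``mode='exact'`` enumerates the null permutation distribution (valid
    without ties); ``'normal_approx'`` uses the normal approximation with
    midrank tie correction and continuity correction; ``'auto'`` (default)
    picks exact for small tie-free samples (n_a + n_b <= 12), otherwise the
    approximation.  Returns ``(U_a, p)`` with U counted for the first sample.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= 12 and not has_ties) else "normal_approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
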