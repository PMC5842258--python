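"""Accession-level descriptive statistics.

One-way ANOVA of each trait across accessions (with an automatic log10
fallback when residual normality is rejected) and the pairwise Pearson
correlation panel of the trait set, with the conventional */**/***
significance tiers at P ≤ 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "genotype_anova",
    "correlation_matrix",
]


@dataclass(frozen=True)
class AnovaResult:
    fstat: float
    pvalue: float
    used_log10: bool
    log_offset: float
    shapiro_p: float
    df_between: int
    df_within: int
    significant: bool  # at the P < 0.05 convention


def _one_way(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return f, p, df_b, df_w


def genotype_anova(
    table: pd.DataFrame,
    trait: str,
    group: str = "accession",
    normality_alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA of ``trait`` by accession with a log10 fallback.

    Residual normality is screened with a Shapiro–Wilk test; when it is
    rejected at ``normality_alpha`` the ANOVA is recomputed on
    log10-transformed values (shifted by a small positive offset if zeros
    are present — the offset is recorded in the result) and flagged.
    Accessions are judged significantly different at P < 0.05.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    sub = table[[group, trait]].dropna()
    groups = [g.to_numpy(dtype=float) for _, g in sub.groupby(group)[trait] if g.size > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 accessions with data")
    if sum(g.size for g in groups) < len(groups) + 1:
        raise ValueError("ANOVA needs at least one replicated accession")

    f, p, df_b, df_w = _one_way(groups)
    resid = np.concatenate([g - g.mean() for g in groups])
    if resid.size >= 3 and np.ptp(resid) > 0:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    else:
        shapiro_p = 1.0

    used_log10, offset = False, 0.0
    if shapiro_p < normality_alpha:
        vals = np.concatenate(groups)
        mn = float(vals.min())
        if mn < 0:
            raise ValueError("log10 fallback impossible: negative trait values")
        if mn == 0.0:
            positive = vals[vals > 0]
            offset = float(positive.min() / 2.0) if positive.size else 1e-6
        lgroups = [np.log10(g + offset) for g in groups]
        f, p, df_b, df_w = _one_way(lgroups)
        used_log10 = True

    return AnovaResult(
        fstat=f,
        pvalue=p,
        used_log10=used_log10,
        log_offset=offset,
        shapiro_p=shapiro_p,
        df_between=df_b,
        df_within=df_w,
        significant=p < 0.05,
    )


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided P-values vs zero."""

    r: pd.DataFrame
    pvalue: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    @property
    def r_squared(self) -> pd.DataFrame:
        """Squared correlations (for comparison with R² reports)."""
        return self.r**2

    def lower_triangle(self) -> pd.DataFrame:
        """Table mirroring the conventional lower-triangle layout with
        star annotations."""
        cols = list(self.r.columns)
        out = pd.DataFrame("", index=cols, columns=cols, dtype=object)
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                if j < i:
                    rv = self.r.loc[a, b]
                    out.loc[a, b] = (
                        "NA" if pd.isna(rv) else f"{self.stars.loc[a, b]}{rv:.2f}"
                    )
        return out


def _star(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_matrix(accession_means: pd.DataFrame) -> CorrelationResult:
    """Symmetric Pearson correlation panel over trait columns.

    Missing values are handled pairwise-complete; a constant column has
    undefined correlations, reported as missing with a warning.
    """
    num = accession_means.select_dtypes(include=[np.number])
    cols = list(num.columns)
    if num.shape[0] < 3:
        raise ValueError("correlations need at least 3 accessions")
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    np.fill_diagonal(n.values, num.notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            a, b = num[cols[i]], num[cols[j]]
            ok = a.notna() & b.notna()
            n.iloc[i, j] = n.iloc[j, i] = int(ok.sum())
            if ok.sum() < 3 or a[ok].nunique() < 2 or b[ok].nunique() < 2:
                warnings.warn(
                    f"correlation undefined for ({cols[i]}, {cols[j]}): "
                    "constant or too few paired values",
                    stacklevel=2,
                )
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            res = stats.pearsonr(a[ok], b[ok])
            r.iloc[i, j] = r.iloc[j, i] = float(res.statistic)
            p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue)
    stars = p.map(_star)
    for c in cols:  # a variable is not "significantly correlated with itself"
        stars.loc[c, c] = ""
    return CorrelationResult(r=r, pvalue=p, n=n, stars=stars)
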