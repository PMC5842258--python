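"""Marker validation on an independent test panel.

A candidate marker identified by association mapping is scored in a new
set of accessions (genotype previously unknown) and the trait is
compared between the two homozygous allele classes with a two-sample
t-test (Welch by default).  Allele frequencies per sub-population are
tabulated with a chi-square test of independence to check that the
allele classes do not simply mirror population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleTTestResult",
    "allele_ttest",
    "allele_frequency_by_subpop",
]

PANEL_COLUMNS = ("accession", "allele_class", "replicate", "fmax")


@dataclass(frozen=True)
class AlleleTTestResult:
    t: float
    pvalue: float
    class_a: str
    class_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    n_excluded_accessions: int  # heterozygous / other calls, reported apart
    welch: bool
    significant: bool  # at the P < 0.05 convention


def _accession_means(panel: pd.DataFrame, trait: str) -> pd.DataFrame:
    g = panel.groupby("accession", sort=True)
    means = g[trait].mean()
    classes = g["allele_class"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "inconsistent"
    )
    return pd.DataFrame({"allele_class": classes, trait: means})


def allele_ttest(
    panel: pd.DataFrame,
    class_a: str | None = None,
    class_b: str | None = None,
    trait: str = "fmax",
    welch: bool = True,
    use_accession_means: bool = True,
) -> AlleleTTestResult:
    """Two-sample t-test of the trait between two allele classes.

    ``panel`` has one row per plant replicate with columns
    ``accession, allele_class, replicate, <trait>``.  Replicates are
    collapsed to accession means before testing (set
    ``use_accession_means=False`` to pool plants).  When the two classes
    are not named, the two most frequent single-allele calls are used;
    heterozygous and other calls are excluded from the comparison and
    counted in the result.  Welch's unequal-variance statistic is the
    default; ``welch=False`` gives the pooled-variance test.
    """
    required = {"accession", "allele_class", trait}
    if not required <= set(panel.columns):
        raise ValueError(f"validation panel needs columns {sorted(required)}")
    data = panel.dropna(subset=["allele_class", trait])
    work = _accession_means(data, trait) if use_accession_means else data

    calls = work["allele_class"].astype(str)
    if class_a is None or class_b is None:
        homozygous = calls[~calls.str.contains("/") & (calls.str.len() == 1)]
        top = homozygous.value_counts().index.tolist()
        if len(top) < 2:
            raise ValueError("fewer than two homozygous allele classes present")
        class_a = class_a or top[0]
        class_b = class_b or top[1]
    a_vals = work.loc[calls == class_a, trait].to_numpy(dtype=float)
    b_vals = work.loc[calls == class_b, trait].to_numpy(dtype=float)
    if a_vals.size == 0:
        raise ValueError(f"allele class {class_a!r} is empty")
    if b_vals.size == 0:
        raise ValueError(f"allele class {class_b!r} is empty")
    excluded = int((~calls.isin([class_a, class_b])).sum())

    res = stats.ttest_ind(a_vals, b_vals, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both classes constant and equal
        t, p = 0.0, 1.0
    return AlleleTTestResult(
        t=t,
        pvalue=p,
        class_a=str(class_a),
        class_b=str(class_b),
        mean_a=float(a_vals.mean()),
        mean_b=float(b_vals.mean()),
        n_a=int(a_vals.size),
        n_b=int(b_vals.size),
        n_excluded_accessions=excluded,
        welch=welch,
        significant=p < 0.05,
    )


def allele_frequency_by_subpop(
    panel: pd.DataFrame,
    q: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Allele counts and frequencies per sub-population.

    Accessions are hard-assigned to the sub-population with the largest
    ancestry fraction (argmax of their Q row); returns the count table
    (with per-subpopulation frequencies appended) plus the chi-square
    statistic and P-value of the allele-by-subpopulation independence
    test (no continuity correction).
    """
    required = {"accession", "allele_class"}
    if not required <= set(panel.columns):
        raise ValueError(f"validation panel needs columns {sorted(required)}")
    calls = (
        panel.dropna(subset=["allele_class"])
        .groupby("accession", sort=True)["allele_class"]
        .first()
    )
    common = calls.index.intersection(q.index)
    if len(common) == 0:
        raise ValueError("no accessions shared between panel and Q matrix")
    assignment = q.loc[common].idxmax(axis=1)
    counts = pd.crosstab(assignment, calls.loc[common])
    if (counts.sum(axis=1) == 0).any() or counts.shape[0] < 2:
        raise ValueError("each sub-population needs at least one accession")
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    freqs = counts.div(counts.sum(axis=1), axis=0).add_suffix("_freq")
    table = pd.concat([counts, freqs], axis=1)
    table.index.name = "subpop"
    return table, float(chi2), float(p)
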