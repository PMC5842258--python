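"""Associative Transcriptomics engine.

Association mapping on a diversity panel using two marker classes derived
from transcriptome sequencing:

* **SNP markers** — biallelic variants coded as 0/1/2 copies of the
  alternate allele, scanned with a mixed linear model (MLM) whose fixed
  effects are an intercept, the population-ancestry covariates (Q matrix,
  last column dropped for identifiability) and the marker dosage, and
  whose random effect has covariance proportional to a genome-wide
  kinship matrix K.  Variance components are estimated once per trait
  under the null by REML (spectral EMMA formulation) and reused for every
  marker (the P3D/EMMAX approximation); each marker is then tested by
  generalized least squares with a Wald F-test.
* **Gene expression markers (GEMs)** — per-unigene transcript abundance
  (RPKM, modelled on a log2(x+1) scale) used as the predictor in a
  fixed-effect model ``trait ~ intercept + Q + expression``.

Associated GEMs can be mapped back onto the SNPs by treating their
(transformed) RPKM vector as the trait in a second-pass MLM scan.

Effect sizes are additionally reported as a *trait effect percent*: the
absolute difference between the two homozygote class means expressed as a
percentage of the trait's range across accessions.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SnpMatrix",
    "ExpressionMatrix",
    "FilterReport",
    "VarianceComponents",
    "maf_filter",
    "kinship_matrix",
    "fit_null_model",
    "mlm_scan",
    "ols_scan",
    "gem_scan",
    "expression_as_trait",
    "trait_effect_percent",
    "genomic_inflation",
    "validate_q",
]

MISSING = np.nan

# ---------------------------------------------------------------------------
# containers


@dataclass
class SnpMatrix:
    """Genotype matrix plus marker map.

    ``genotypes``: accessions (rows) x markers (columns), dosage codes
    0/1/2 of the alternate allele, ``NaN`` for missing calls.
    ``marker_map``: indexed by marker id with columns ``chrom`` and
    ``pos``; its row order defines genome order and is enforced on the
    genotype columns.  ``alleles``: optional per-marker ``allele0`` /
    ``allele1`` labels.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    alleles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not {"chrom", "pos"} <= set(self.marker_map.columns):
            raise ValueError("marker_map needs 'chrom' and 'pos' columns")
        if set(self.genotypes.columns) != set(self.marker_map.index):
            raise ValueError("marker_map must cover exactly the genotyped markers")
        # enforce genome order on the genotype columns
        self.genotypes = self.genotypes.loc[:, self.marker_map.index]
        for chrom, sub in self.marker_map.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within pseudochromosome {chrom}")
        vals = self.genotypes.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def accessions(self) -> pd.Index:
        return self.genotypes.index

    @property
    def markers(self) -> pd.Index:
        return self.marker_map.index

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker over non-missing calls."""
        p = self.genotypes.mean(axis=0, skipna=True) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, markers) -> "SnpMatrix":
        markers = pd.Index(markers)
        return SnpMatrix(
            genotypes=self.genotypes.loc[:, markers].copy(),
            marker_map=self.marker_map.loc[markers].copy(),
            alleles=None if self.alleles is None else self.alleles.loc[markers].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Unigene x accession RPKM matrix with an optional unigene map."""

    rpkm: pd.DataFrame
    gene_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.rpkm.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("RPKM values must be non-negative")
        if self.gene_map is not None:
            missing = self.rpkm.index.difference(self.gene_map.index)
            if len(missing):
                raise ValueError("gene_map does not cover all unigenes")
            self.gene_map = self.gene_map.loc[self.rpkm.index]

    @property
    def unigenes(self) -> pd.Index:
        return self.rpkm.index

    @property
    def accessions(self) -> pd.Index:
        return self.rpkm.columns

    @property
    def n_unigenes(self) -> int:
        return self.rpkm.shape[0]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_all_missing: int
    threshold: float


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float          # sigma_e2 / sigma_g2
    loglik: float         # restricted log-likelihood at the optimum
    n: int
    n_fixed: int
    at_bound: bool = field(default=False)


def validate_q(q: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check that ancestry fractions are a proper Q matrix (rows sum to 1)."""
    vals = q.to_numpy(dtype=float)
    if np.any(vals < -atol) or np.any(vals > 1 + atol):
        raise ValueError("Q entries must lie in [0, 1]")
    if not np.allclose(vals.sum(axis=1), 1.0, atol=atol):
        raise ValueError("Q rows must sum to 1")
    return q


# ---------------------------------------------------------------------------
# marker bookkeeping


def maf_filter(
    snps: SnpMatrix, threshold: float = 0.05
) -> tuple[SnpMatrix, FilterReport]:
    """Remove markers whose minor-allele frequency is strictly below ``threshold``.

    The boundary is retained: with the default 5% cut-off a marker at MAF
    exactly 0.05 stays in.  Markers with every call missing are removed
    and counted separately in the report.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("MAF threshold must lie in (0, 0.5]")
    n_calls = snps.genotypes.notna().sum(axis=0)
    all_missing = n_calls == 0
    maf = snps.maf()
    keep = (~all_missing) & (maf >= threshold)
    report = FilterReport(
        n_input=snps.n_markers,
        n_retained=int(keep.sum()),
        n_removed_maf=int((~keep & ~all_missing).sum()),
        n_all_missing=int(all_missing.sum()),
        threshold=threshold,
    )
    return snps.subset(snps.markers[keep.to_numpy()]), report


def _impute_dosage(g: np.ndarray) -> tuple[np.ndarray, int]:
    """Mean-impute missing dosages of one marker; returns (imputed, n_imputed)."""
    miss = np.isnan(g)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return g, 0
    if n_miss == g.size:
        raise ValueError("marker has no non-missing calls")
    out = g.copy()
    out[miss] = np.nanmean(g)
    return out, n_miss


def kinship_matrix(snps: SnpMatrix, psd_tol: float = 1e-8) -> pd.DataFrame:
    """Genome-wide relatedness (VanRaden centered cross-product).

    Missing genotypes are mean-imputed per marker, dosages centered by
    twice the alternate-allele frequency, and the cross-product scaled by
    ``2 * sum_j p_j (1 - p_j)``.  If imputation noise leaves the matrix
    indefinite (minimum eigenvalue < -1e-8), ``(|min eig| + 1e-10) I`` is
    added so downstream solvers see a positive semi-definite matrix.
    """
    if snps.n_accessions < 2:
        raise ValueError("kinship needs at least 2 accessions")
    G = snps.genotypes.to_numpy(dtype=float)
    p = np.nanmean(G, axis=0) / 2.0
    usable = ~np.isnan(p)
    if not usable.any():
        raise ValueError("no markers with any non-missing calls")
    G = G[:, usable]
    p = p[usable]
    Z = np.where(np.isnan(G), 0.0, G - 2.0 * p)  # mean imputation == centered zero
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all usable markers are monomorphic")
    K = Z @ Z.T / denom
    K = (K + K.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(K)[0])
    if min_eig < -psd_tol:
        K = K + (abs(min_eig) + 1e-10) * np.eye(K.shape[0])
    acc = snps.accessions
    return pd.DataFrame(K, index=acc, columns=acc)


# ---------------------------------------------------------------------------
# mixed model


def _fixed_design(accessions: pd.Index, q: pd.DataFrame | None) -> np.ndarray:
    """Intercept plus Q with its last ancestry column dropped."""
    n = len(accessions)
    cols = [np.ones(n)]
    if q is not None:
        q = validate_q(q.loc[accessions])
        if q.shape[1] > 1:
            cols.extend(q.to_numpy(dtype=float)[:, :-1].T)
    return np.column_stack(cols)


def _align(y: pd.Series, q, k, snps=None):
    acc = y.index
    if snps is not None:
        if not acc.isin(snps.accessions).all():
            raise ValueError("trait accessions missing from genotype matrix")
    if k is not None and not acc.isin(k.index).all():
        raise ValueError("trait accessions missing from kinship matrix")
    if q is not None and not acc.isin(q.index).all():
        raise ValueError("trait accessions missing from Q matrix")
    return acc


def fit_null_model(
    y: pd.Series,
    q: pd.DataFrame | None,
    k: pd.DataFrame,
    bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML variance components of ``y = Xb + g + e`` with cov(g) = sigma_g2 K.

    The restricted likelihood is profiled down to the single variance
    ratio ``delta = sigma_e2/sigma_g2`` via the spectral decomposition of
    ``S K S`` (S the projection orthogonal to the fixed effects), then
    optimized in log-delta over ``bounds`` (grid + bounded refinement).
    """
    y = y.astype(float)
    if not np.all(np.isfinite(y.to_numpy())):
        raise ValueError("trait vector contains non-finite values")
    acc = _align(y, q, k)
    X = _fixed_design(acc, q)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    if n - p < 2:
        raise ValueError("too few accessions for REML")
    K = k.loc[acc, acc].to_numpy(dtype=float)
    yv = y.to_numpy()

    S = np.eye(n) - X @ np.linalg.pinv(X.T @ X) @ X.T
    M = S @ K @ S
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1][: n - p]
    lam = np.clip(evals[order], 0.0, None)
    U = evecs[:, order]
    eta2 = (U.T @ yv) ** 2
    nq = n - p

    def reml_ll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        denom = lam + delta
        return 0.5 * (
            nq * math.log(nq / (2.0 * math.pi))
            - nq
            - nq * math.log(float(np.sum(eta2 / denom)))
            - float(np.sum(np.log(denom)))
        )

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    grid = np.linspace(lo, hi, 121)
    vals = np.array([reml_ll(g) for g in grid])
    best = int(np.argmax(vals))
    if best in (0, len(grid) - 1):
        log_delta, ll = grid[best], vals[best]
        at_bound = True
    else:
        res = optimize.minimize_scalar(
            lambda t: -reml_ll(t),
            bounds=(grid[best - 1], grid[best + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        log_delta, ll = float(res.x), -float(res.fun)
        at_bound = False
    delta = math.exp(log_delta)
    sigma_g2 = float(np.sum(eta2 / (lam + delta))) / nq
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=delta,
        loglik=ll,
        n=n,
        n_fixed=p,
        at_bound=at_bound,
    )


def _wald_gls(
    A: np.ndarray, w: np.ndarray, ys: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted LS of rotated response on rotated design; Wald test on the
    last column.  Returns (beta_last, se_last, F, P).

    Solved via QR of the square-root-weighted design (not normal
    equations) so the conditioning of the design is not squared.
    """
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    yw = ys * sw
    Qm, R = np.linalg.qr(Aw)
    beta = solve_triangular(R, Qm.T @ yw)
    resid = yw - Aw @ beta
    rss = float(resid @ resid)
    dof = A.shape[0] - A.shape[1]
    sigma2 = rss / dof
    # [ (A'WA)^-1 ]_(last,last) = || last row of R^-1 ||^2 = || R^-T e_last ||^2
    r_last = solve_triangular(R, np.eye(R.shape[0])[:, -1], trans="T")
    var_b = sigma2 * float(r_last @ r_last)
    if var_b <= 0:
        return float(beta[-1]), float("nan"), float("nan"), float("nan")
    fstat = float(beta[-1] ** 2 / var_b)
    pval = float(stats.f.sf(fstat, 1, dof))
    return float(beta[-1]), float(math.sqrt(var_b)), fstat, max(pval, 5e-324)


def _finalize_scan(res: pd.DataFrame) -> pd.DataFrame:
    ok = res["status"] == "ok"
    res["p_bonferroni"] = np.nan
    res["p_bh"] = np.nan
    if ok.any():
        pv = res.loc[ok, "pvalue"].to_numpy()
        res.loc[ok, "p_bonferroni"] = np.minimum(pv * ok.sum(), 1.0)
        res.loc[ok, "p_bh"] = multipletests(pv, method="fdr_bh")[1]
    return res


def mlm_scan(
    y: pd.Series,
    snps: SnpMatrix,
    q: pd.DataFrame | None,
    k: pd.DataFrame,
    vc: VarianceComponents | None = None,
    p3d: bool = True,
) -> pd.DataFrame:
    """Mixed-linear-model SNP association scan (P3D/EMMAX by default).

    Per marker the additive dosage (missing calls mean-imputed) is
    appended to the fixed effects and tested by GLS under the null-model
    variance ratio ``delta``; with ``p3d=False`` delta is re-estimated by
    REML for every marker (slow, exact).  Monomorphic and all-missing
    markers are flagged and skipped.  Results keep genome order; raw
    P-values are reported alongside Bonferroni and Benjamini–Hochberg
    columns, and the scan metadata (delta, variance components, fixed
    effects) travels in ``DataFrame.attrs``.
    """
    acc = _align(y, q, k, snps)
    yv = y.to_numpy(dtype=float)
    X0 = _fixed_design(acc, q)
    n, p0 = X0.shape
    if vc is None:
        vc = fit_null_model(y, q, k)
    K = k.loc[acc, acc].to_numpy(dtype=float)
    evals, U = np.linalg.eigh((K + K.T) / 2.0)
    G = snps.genotypes.loc[acc].to_numpy(dtype=float)
    ys = U.T @ yv
    X0s = U.T @ X0
    w = 1.0 / (np.clip(evals, 0.0, None) + vc.delta)

    rows = []
    for j, marker in enumerate(snps.markers):
        g = G[:, j]
        rec = {
            "marker": marker,
            "chrom": snps.marker_map.iloc[j]["chrom"],
            "pos": snps.marker_map.iloc[j]["pos"],
            "maf": np.nan,
            "n_imputed": 0,
            "beta": np.nan,
            "se": np.nan,
            "fstat": np.nan,
            "pvalue": np.nan,
            "trait_effect_pct": np.nan,
            "status": "ok",
        }
        if np.all(np.isnan(g)):
            rec["status"] = "all_missing"
            rows.append(rec)
            continue
        gi, n_imp = _impute_dosage(g)
        rec["n_imputed"] = n_imp
        pfreq = float(np.nanmean(g)) / 2.0
        rec["maf"] = min(pfreq, 1.0 - pfreq)
        if np.ptp(gi) == 0.0:
            rec["status"] = "monomorphic"
            rows.append(rec)
            continue
        if not p3d:
            vc_j = _exact_marker_vc(yv, X0, gi, K, acc)
            w_j = 1.0 / (np.clip(evals, 0.0, None) + vc_j.delta)
        else:
            w_j = w
        A = np.column_stack([X0s, U.T @ gi])
        beta, se, fstat, pval = _wald_gls(A, w_j, ys)
        rec.update(beta=beta, se=se, fstat=fstat, pvalue=pval)
        try:
            rec["trait_effect_pct"] = trait_effect_percent(yv, g)
        except ValueError:
            pass
        rows.append(rec)

    res = _finalize_scan(pd.DataFrame(rows))
    res.attrs.update(
        scan="mlm",
        delta=vc.delta,
        sigma_g2=vc.sigma_g2,
        sigma_e2=vc.sigma_e2,
        p3d=p3d,
        covariates="intercept" + ("" if q is None else "+Q"),
        n_accessions=n,
    )
    return res


def _exact_marker_vc(yv, X0, g, K, acc) -> VarianceComponents:
    # re-profile REML with the marker in the fixed effects
    Xfull = np.column_stack([X0, g])
    n, p = Xfull.shape
    S = np.eye(n) - Xfull @ np.linalg.pinv(Xfull.T @ Xfull) @ Xfull.T
    M = (S @ K @ S + (S @ K @ S).T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1][: n - p]
    lam = np.clip(evals[order], 0.0, None)
    eta2 = (evecs[:, order].T @ yv) ** 2
    nq = n - p

    def reml_ll(log_delta):
        delta = math.exp(log_delta)
        denom = lam + delta
        return 0.5 * (
            nq * math.log(nq / (2 * math.pi))
            - nq
            - nq * math.log(float(np.sum(eta2 / denom)))
            - float(np.sum(np.log(denom)))
        )

    grid = np.linspace(math.log(1e-5), math.log(1e5), 81)
    vals = [reml_ll(t) for t in grid]
    best = int(np.argmax(vals))
    delta = math.exp(grid[best])
    sigma_g2 = float(np.sum(eta2 / (lam + delta))) / nq
    return VarianceComponents(sigma_g2, delta * sigma_g2, delta, vals[best], n, p)


def ols_scan(
    y: pd.Series, snps: SnpMatrix, q: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Naive fixed-effects scan (no kinship): OLS F-test per marker.

    Used as the uncorrected comparator when demonstrating genomic
    inflation under population structure.
    """
    acc = _align(y, q, None, snps)
    identity = pd.DataFrame(np.eye(len(acc)), index=acc, columns=acc)
    vc = VarianceComponents(1.0, 1e5, 1e5, 0.0, len(acc), 1)
    res = mlm_scan(y, snps, q, identity, vc=vc)
    res.attrs["scan"] = "ols"
    return res


def gem_scan(
    y: pd.Series,
    expr: ExpressionMatrix,
    q: pd.DataFrame | None,
    kinship: pd.DataFrame | None = None,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Gene-expression-marker scan: ``trait ~ intercept + Q + expression``.

    Expression enters on a log2(RPKM+1) scale by default (``transform``
    may be ``"log2p1"`` or ``"none"``).  The default model is fixed-effects
    only (Q correction); pass ``kinship`` to add the random polygenic
    effect exactly as in :func:`mlm_scan`.  Unigenes with zero expression
    variance are flagged and skipped.  The sign of the reported
    coefficient distinguishes positive from negative expression–trait
    correlation; a partial R² for the expression term is included.
    """
    acc = _align(y, q, kinship)
    missing = acc.difference(expr.accessions)
    if len(missing):
        raise ValueError("trait accessions missing from expression matrix")
    X = expr.rpkm.loc[:, acc].to_numpy(dtype=float)
    if transform == "log2p1":
        Xt = np.log2(X + 1.0)
    elif transform == "none":
        Xt = X
    else:
        raise ValueError(f"unknown transform {transform!r}")
    yv = y.to_numpy(dtype=float)
    X0 = _fixed_design(acc, q)
    n, p0 = X0.shape

    if kinship is not None:
        vc = fit_null_model(y, q, kinship)
        K = kinship.loc[acc, acc].to_numpy(dtype=float)
        evals, U = np.linalg.eigh((K + K.T) / 2.0)
        w = 1.0 / (np.clip(evals, 0.0, None) + vc.delta)
        ys, X0s = U.T @ yv, U.T @ X0
    else:
        vc = None
        U = None
        w = np.ones(n)
        ys, X0s = yv, X0

    rows = []
    gene_map = expr.gene_map
    for i, unigene in enumerate(expr.unigenes):
        x = Xt[i]
        rec = {
            "unigene": unigene,
            "chrom": gene_map.loc[unigene, "chrom"] if gene_map is not None else "",
            "pos": gene_map.loc[unigene, "pos"] if gene_map is not None else np.nan,
            "mean_rpkm": float(np.mean(X[i])),
            "beta": np.nan,
            "se": np.nan,
            "fstat": np.nan,
            "pvalue": np.nan,
            "r2": np.nan,
            "status": "ok",
        }
        if np.ptp(x) == 0.0:
            rec["status"] = "zero_variance"
            rows.append(rec)
            continue
        xs = x if U is None else U.T @ x
        A = np.column_stack([X0s, xs])
        beta, se, fstat, pval = _wald_gls(A, w, ys)
        # partial R2 of the expression term
        b0 = np.linalg.lstsq(np.sqrt(w)[:, None] * X0s, np.sqrt(w) * ys, rcond=None)[0]
        rss0 = float(np.sum(w * (ys - X0s @ b0) ** 2))
        bw = np.linalg.lstsq(np.sqrt(w)[:, None] * A, np.sqrt(w) * ys, rcond=None)[0]
        rss1 = float(np.sum(w * (ys - A @ bw) ** 2))
        rec.update(
            beta=beta,
            se=se,
            fstat=fstat,
            pvalue=pval,
            r2=(rss0 - rss1) / rss0 if rss0 > 0 else np.nan,
        )
        rows.append(rec)

    res = _finalize_scan(pd.DataFrame(rows))
    res.attrs.update(
        scan="gem",
        transform=transform,
        covariates="intercept" + ("" if q is None else "+Q") + ("" if kinship is None else "+K"),
        delta=None if vc is None else vc.delta,
        n_accessions=n,
    )
    return res


def expression_as_trait(
    unigene: str,
    expr: ExpressionMatrix,
    snps: SnpMatrix,
    q: pd.DataFrame | None,
    k: pd.DataFrame,
    transform: str = "log2p1",
    **scan_kwargs,
) -> pd.DataFrame:
    """Second-pass scan: map a unigene's expression as the trait onto SNPs."""
    if unigene not in expr.unigenes:
        raise KeyError(f"unigene {unigene!r} not in expression matrix")
    x = expr.rpkm.loc[unigene]
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    y = pd.Series(x, index=expr.accessions, name=unigene).loc[snps.accessions.intersection(expr.accessions)]
    res = mlm_scan(y.astype(float), snps, q, k, **scan_kwargs)
    res.attrs.update(scan="expression_as_trait", unigene=unigene, transform=transform)
    return res


def trait_effect_percent(y: np.ndarray, dosage: np.ndarray) -> float:
    """Homozygote-class mean difference as % of the trait range.

    ``|mean(class 2) - mean(class 0)| / (max(y) - min(y)) * 100`` over
    accessions with non-missing calls; both homozygote classes must be
    represented.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    m0 = dosage == 0.0
    m2 = dosage == 2.0
    if not (m0.any() and m2.any()):
        raise ValueError("both homozygote classes must be non-empty")
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng == 0.0:
        raise ValueError("trait range is zero")
    return float(abs(np.nanmean(y[m2]) - np.nanmean(y[m0])) / rng * 100.0)


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median association chi² over its null median."""
    pv = np.asarray(pvalues, dtype=float)
    pv = pv[np.isfinite(pv)]
    if pv.size == 0:
        raise ValueError("no finite P-values")
    chi2 = stats.chi2.isf(pv, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
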