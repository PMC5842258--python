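"""Synthetic diversity panels with known ground truth.

Every downstream stage of the pipeline — bend-curve trait extraction,
trait statistics, kinship-corrected SNP scans, GEM scans, marker
validation, FTIR differencing — can be exercised on panels generated
here, with the planted effects recorded in a :class:`GroundTruth` ledger
so recovery can be verified.

The generator emulates a small association panel of near-inbred
allopolyploid accessions:

* two (or more) admixed sub-populations, per-marker subpopulation allele
  frequencies drawn from a Balding–Nichols distribution at a configured
  Fst, accession genotypes sampled from admixture-weighted frequencies;
* biallelic markers in pseudomolecule order over paired "A"/"C"
  pseudochromosomes, with a configurable fraction of marker pairs
  duplicated as correlated homoeologues;
* log-scale transcript abundance (RPKM) with planted cis-eQTL;
* quantitative traits built from planted SNP effects, planted
  expression-mediated effects, a kinship-structured polygenic term and
  i.i.d. environmental noise scaled to a target heritability, plus a
  panel of secondary traits (stem geometry, plant height, stem weight,
  field lodging score) with configured correlations to Fmax;
* piecewise-elastic three-point-bend traces and two-band
  (1740/1624 cm⁻¹) esterification spectra.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from atscan.assoc import ExpressionMatrix, SnpMatrix, kinship_matrix
from atscan.ftir import Spectrum
from atscan.mechanics import BendCurve

__all__ = [
    "PanelConfig",
    "GroundTruth",
    "Panel",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_traits",
    "simulate_panel",
    "simulate_bend_curve",
    "simulate_spectra",
    "write_panel",
]

# secondary traits generated alongside Fmax: (mean, sd, correlation with
# accession-level Fmax).  Magnitudes are field-plausible for mature
# oilseed-rape stems (mm, mm^2, mm^4, g, cm, force units).
SECONDARY_TRAITS: dict[str, tuple[float, float, float]] = {
    "f_over_v": (15.0, 4.5, 0.88),
    "stem_diameter": (9.5, 1.4, 0.69),
    "second_moment": (360.0, 110.0, 0.61),
    "parenchyma_area": (45.0, 12.0, 0.54),
    "cortex_thickness": (1.6, 0.35, 0.43),
    "hollow_area": (10.0, 6.0, 0.13),
    "plant_height": (140.0, 18.0, 0.39),
    "stem_weight": (35.0, 10.0, 0.61),
    "slr": (12.0, 3.5, None),  # correlation taken from PanelConfig
}


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions of a synthetic panel.

    Defaults mirror the real study's scale: 79 accessions apportioned
    between K=2 admixed sub-populations, markers in pseudomolecule order
    over paired A/C pseudochromosomes, three plant replicates per
    accession.  ``causal_snps`` plants direct marker→trait effects
    (trait units per alternate-allele copy); ``mediator_genes`` plants
    chains marker →(cis effect, log2 units per copy)→ expression
    →(trait units per log2 unit)→ trait.
    """

    n_accessions: int = 79
    n_subpops: int = 2
    fst: float = 0.2
    n_markers: int = 10_000
    n_genes: int = 2_000
    causal_snps: tuple[tuple[int, float], ...] = ()
    mediator_genes: tuple[tuple[int, int, float, float], ...] = ()
    heritability: float = 0.6
    polygenic_var: float = 0.3
    subpop_effect: float = 0.0
    slr_correlation: float = 0.42
    n_replicates: int = 3
    n_chrom_pairs: int = 2
    het_rate: float = 0.03
    missing_rate: float = 0.02
    dup_fraction: float = 0.10
    dup_concordance: float = 0.9
    expr_baseline_mean: float = 3.5
    expr_baseline_sd: float = 1.2
    expr_noise_sd: float = 0.5
    trait_intercept: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_subpops", "n_markers", "n_genes",
                     "n_replicates", "n_chrom_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.polygenic_var < 0:
            raise ValueError("polygenic_var must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0 or not 0.0 <= self.het_rate < 1.0:
            raise ValueError("rates must lie in [0, 1)")
        if not 0.0 <= self.dup_fraction <= 1.0 or not 0.0 <= self.dup_concordance <= 1.0:
            raise ValueError("duplication parameters must lie in [0, 1]")
        for idx, _ in self.causal_snps:
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"causal marker index {idx} out of range")
        for g_idx, m_idx, _, _ in self.mediator_genes:
            if not 0 <= g_idx < self.n_genes:
                raise ValueError(f"mediator gene index {g_idx} out of range")
            if not 0 <= m_idx < self.n_markers:
                raise ValueError(f"cis marker index {m_idx} out of range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["causal_snps"] = [list(t) for t in self.causal_snps]
        d["mediator_genes"] = [list(t) for t in self.mediator_genes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        d = dict(d)
        d["causal_snps"] = tuple(tuple(t) for t in d.get("causal_snps", ()))
        d["mediator_genes"] = tuple(tuple(t) for t in d.get("mediator_genes", ()))
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests."""

    q_matrix: pd.DataFrame
    causal_snps: tuple[tuple[int, float], ...] = ()
    mediator_genes: tuple[tuple[int, int, float, float], ...] = ()
    genetic_values: pd.Series | None = None
    subpop_freqs: np.ndarray | None = None   # n_subpops x n_markers
    ancestral_freqs: np.ndarray | None = None
    causal_markers: tuple[str, ...] = ()
    mediator_unigenes: tuple[str, ...] = ()
    cis_markers: tuple[str, ...] = ()
    ester_levels: dict | None = None
    heritability: float | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.q_matrix.sum(axis=1).to_numpy(), 1.0, atol=1e-12):
            raise ValueError("Q rows must sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "q_matrix": {
                "index": list(map(str, self.q_matrix.index)),
                "columns": list(map(str, self.q_matrix.columns)),
                "values": self.q_matrix.to_numpy().tolist(),
            },
            "causal_snps": [list(t) for t in self.causal_snps],
            "mediator_genes": [list(t) for t in self.mediator_genes],
            "causal_markers": list(self.causal_markers),
            "mediator_unigenes": list(self.mediator_unigenes),
            "cis_markers": list(self.cis_markers),
            "heritability": self.heritability,
            "genetic_values": None
            if self.genetic_values is None
            else {str(k): float(v) for k, v in self.genetic_values.items()},
            "ester_levels": self.ester_levels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Panel:
    """A complete synthetic panel."""

    config: PanelConfig
    snps: SnpMatrix
    q: pd.DataFrame
    expr: ExpressionMatrix
    traits: pd.DataFrame
    truth: GroundTruth


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    config: PanelConfig, rng: np.random.Generator | None = None
) -> tuple[SnpMatrix, pd.DataFrame, dict]:
    """Draw genotypes and ancestry for one panel.

    Returns ``(snps, q_matrix, truth_parts)`` where ``truth_parts``
    carries the ancestral and per-subpopulation allele frequencies used,
    for estimator-oracle tests.
    """
    rng = _rng(config.seed if rng is None else rng)
    n, m, K, F = config.n_accessions, config.n_markers, config.n_subpops, config.fst

    p_anc = rng.uniform(0.1, 0.9, size=m)
    if F > 0:
        shape = (1.0 - F) / F
        freqs = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(K, m))
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    else:
        freqs = np.tile(p_anc, (K, 1))

    # admixed ancestry: each accession leans towards its assigned subpop
    alpha = np.full((n, K), 1.0)
    alpha[np.arange(n), np.arange(n) % K] = 8.0
    qvals = rng.gamma(alpha)
    qvals /= qvals.sum(axis=1, keepdims=True)
    accessions = pd.Index([f"Acc{i + 1:03d}" for i in range(n)], name="accession")
    q = pd.DataFrame(qvals, index=accessions, columns=[f"Q{k + 1}" for k in range(K)])

    pi = qvals @ freqs  # accession-specific allele frequencies
    alt = rng.random((n, m)) < pi
    geno = np.where(alt, 2.0, 0.0)
    het = rng.random((n, m)) < config.het_rate
    geno[het] = 1.0

    # homoeologous duplication: pair markers in A blocks with the marker at
    # the same offset in the corresponding C block, copying subpop
    # frequencies and (mostly) genotypes
    chroms, positions = _pseudomolecule_layout(m, config.n_chrom_pairs)
    n_half = m // 2
    n_dup = int(round(config.dup_fraction * min(n_half, m - n_half)))
    dup_pairs: list[tuple[int, int]] = []
    if n_dup > 0:
        offsets = rng.choice(min(n_half, m - n_half), size=n_dup, replace=False)
        for off in offsets:
            a_idx, c_idx = int(off), int(n_half + off)
            freqs[:, c_idx] = freqs[:, a_idx]
            keep = rng.random(n) < config.dup_concordance
            pi_c = qvals @ freqs[:, c_idx]
            resampled = np.where(rng.random(n) < pi_c, 2.0, 0.0)
            geno[:, c_idx] = np.where(keep, geno[:, a_idx], resampled)
            dup_pairs.append((a_idx, c_idx))

    if config.missing_rate > 0:
        geno[rng.random((n, m)) < config.missing_rate] = np.nan

    markers = pd.Index([f"JCVI_{j + 1}:{positions[j]}" for j in range(m)], name="marker")
    marker_map = pd.DataFrame({"chrom": chroms, "pos": positions}, index=markers)
    genotypes = pd.DataFrame(geno, index=accessions, columns=markers)
    alleles = pd.DataFrame(
        {"allele0": np.repeat("A", m), "allele1": np.repeat("G", m)}, index=markers
    )
    snps = SnpMatrix(genotypes=genotypes, marker_map=marker_map, alleles=alleles)
    truth_parts = {
        "ancestral_freqs": p_anc,
        "subpop_freqs": freqs,
        "dup_pairs": dup_pairs,
    }
    return snps, q, truth_parts


def _pseudomolecule_layout(m: int, n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign markers to ordered positions on paired A/C pseudochromosomes."""
    labels = [f"A{i + 1}" for i in range(n_pairs)] + [f"C{i + 1}" for i in range(n_pairs)]
    n_half = m // 2
    sizes_a = np.diff(np.linspace(0, n_half, n_pairs + 1).astype(int))
    sizes_c = np.diff(np.linspace(0, m - n_half, n_pairs + 1).astype(int))
    chroms = np.concatenate(
        [np.repeat(lbl, s) for lbl, s in zip(labels, np.concatenate([sizes_a, sizes_c]))]
    )
    positions = np.concatenate(
        [np.arange(1, s + 1) for s in np.concatenate([sizes_a, sizes_c])]
    )
    return chroms, positions


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: PanelConfig,
    snps: SnpMatrix,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-scale expression with planted cis-eQTL, exponentiated to RPKM.

    Per gene: ``log2 RPKM = baseline + cis_effect * dosage + noise``;
    missing cis dosages are mean-imputed when generating.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    n, g = config.n_accessions, config.n_genes
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=g)
    log2r = np.tile(baseline[:, None], (1, n))
    if config.expr_noise_sd > 0:
        log2r = log2r + rng.normal(0.0, config.expr_noise_sd, size=(g, n))
    G = snps.genotypes.to_numpy(dtype=float)
    for g_idx, m_idx, cis_effect, _ in config.mediator_genes:
        dosage = G[:, m_idx]
        mean = np.nanmean(dosage)
        dosage = np.where(np.isnan(dosage), mean, dosage)
        log2r[g_idx] = log2r[g_idx] + cis_effect * dosage
    rpkm = np.exp2(log2r)
    unigenes = pd.Index([f"UG_{i + 1}" for i in range(g)], name="unigene")
    chroms, positions = _pseudomolecule_layout(g, config.n_chrom_pairs)
    gene_map = pd.DataFrame({"chrom": chroms, "pos": positions}, index=unigenes)
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm, index=unigenes, columns=snps.accessions),
        gene_map=gene_map,
    )


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    config: PanelConfig,
    snps: SnpMatrix,
    expr: ExpressionMatrix,
    q: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant-level trait table plus ground truth.

    Fmax is the primary trait: intercept + planted SNP effects + planted
    expression-mediated effects (on log2(RPKM+1)) + an optional
    ancestry-correlated component (``subpop_effect`` trait units per unit
    of first-subpopulation ancestry fraction, centered — the classic
    confounded-trait scenario) + a polygenic term drawn from
    N(0, polygenic_var * K) with K the realized kinship, plus i.i.d.
    plant-level environmental noise scaled so genetic/total variance ≈
    the configured heritability.  Secondary traits are drawn with
    configured correlations to the accession-level Fmax and small
    replicate noise.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    n = config.n_accessions
    acc = snps.accessions
    G = snps.genotypes.to_numpy(dtype=float)

    gv = np.zeros(n)
    for m_idx, effect in config.causal_snps:
        dosage = G[:, m_idx]
        dosage = np.where(np.isnan(dosage), np.nanmean(dosage), dosage)
        gv = gv + effect * dosage
    log2e = np.log2(expr.rpkm.to_numpy(dtype=float) + 1.0)
    for g_idx, _, _, trait_effect in config.mediator_genes:
        gv = gv + trait_effect * log2e[g_idx]

    if config.subpop_effect != 0.0:
        anc = q.to_numpy(dtype=float)[:, 0]
        gv = gv + config.subpop_effect * (anc - anc.mean())

    if config.polygenic_var > 0:
        K = kinship_matrix(snps).to_numpy()
        K = K / max(np.mean(np.diag(K)), 1e-12)
        evals, evecs = np.linalg.eigh((K + K.T) / 2.0)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
        gv = gv + np.sqrt(config.polygenic_var) * (L @ rng.standard_normal(n))

    var_g = float(np.var(gv))
    h2 = config.heritability
    if h2 >= 1.0:
        env_var = 0.0
    elif var_g > 0:
        env_var = var_g * (1.0 - h2) / max(h2, 1e-12)
    else:
        env_var = 1.0 - h2

    reps = config.n_replicates
    env = (
        rng.normal(0.0, np.sqrt(env_var), size=(n, reps)) if env_var > 0 else np.zeros((n, reps))
    )
    fmax_plants = config.trait_intercept + gv[:, None] + env
    fmax_acc = fmax_plants.mean(axis=1)

    # secondary traits: configured correlation with accession-level Fmax
    sd_fmax = float(np.std(fmax_acc))
    z = (fmax_acc - fmax_acc.mean()) / sd_fmax if sd_fmax > 0 else np.zeros(n)
    columns = {"fmax": fmax_plants}
    for name, (mean, sd, rho) in SECONDARY_TRAITS.items():
        if rho is None:
            rho = config.slr_correlation
        eps = rng.standard_normal(n)
        acc_vals = mean + sd * (rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * eps)
        rep_noise = rng.normal(0.0, 0.15 * sd, size=(n, reps))
        vals = acc_vals[:, None] + rep_noise
        if name in ("hollow_area", "parenchyma_area", "cortex_thickness"):
            vals = np.clip(vals, 0.0, None)
        columns[name] = vals

    records = []
    for i, a in enumerate(acc):
        for r in range(reps):
            rec = {"accession": a, "replicate": r + 1}
            rec.update({name: columns[name][i, r] for name in columns})
            records.append(rec)
    traits = pd.DataFrame(records)

    truth = GroundTruth(
        q_matrix=q,
        causal_snps=config.causal_snps,
        mediator_genes=config.mediator_genes,
        genetic_values=pd.Series(gv, index=acc, name="genetic_value"),
        causal_markers=tuple(snps.markers[m] for m, _ in config.causal_snps),
        mediator_unigenes=tuple(expr.unigenes[g] for g, _, _, _ in config.mediator_genes),
        cis_markers=tuple(snps.markers[m] for _, m, _, _ in config.mediator_genes),
        heritability=h2,
    )
    return traits, truth


def simulate_panel(config: PanelConfig) -> Panel:
    """Generate a complete panel (genotypes, Q, expression, traits, truth)."""
    rng = np.random.default_rng(config.seed)
    snps, q, parts = simulate_genotypes(config, rng)
    expr = simulate_expression(config, snps, rng)
    traits, truth = simulate_traits(config, snps, expr, q, rng)
    truth.subpop_freqs = parts["subpop_freqs"]
    truth.ancestral_freqs = parts["ancestral_freqs"]
    return Panel(config=config, snps=snps, q=q, expr=expr, traits=traits, truth=truth)


# ---------------------------------------------------------------------------
# bend curves and spectra


def simulate_bend_curve(
    fmax: float,
    slope: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    step: float = 0.004,
    tail_mult: float = 1.6,
    decay: float = 2.5,
) -> BendCurve:
    """Piecewise-elastic three-point-bend trace.

    Force rises linearly at ``slope`` to exactly ``fmax`` (failure), then
    decays exponentially (post-failure tail); white noise of SD
    ``noise_sd`` is added throughout.  ``step`` is the displacement
    sampling interval (mm) — the default corresponds to a 2 mm/s probe
    sampled at 500 points/s.
    """
    if fmax <= 0 or slope <= 0:
        raise ValueError("fmax and slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    d_peak = fmax / slope
    n_pre = max(int(round(d_peak / step)), 20)
    pre = np.linspace(0.0, d_peak, n_pre + 1)
    n_tail = max(int(round(n_pre * (tail_mult - 1.0))), 5)
    tail = d_peak + np.linspace(0.0, (tail_mult - 1.0) * d_peak, n_tail + 1)[1:]
    # force at the peak sample is exactly fmax (pre/d_peak ends at 1.0)
    f_pre = fmax * (pre / d_peak)
    f_tail = fmax * np.exp(-decay * (tail - d_peak) / d_peak)
    d = np.concatenate([pre, tail])
    f = np.concatenate([f_pre, f_tail])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    return BendCurve(displacement=d, force=f)


def simulate_spectra(
    ester_level: float,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.003,
    band_amplitude: float = 0.35,
) -> list[Spectrum]:
    """Two-band esterification spectra on the 800–4000 cm⁻¹ grid.

    The 1740 cm⁻¹ ester band scales with ``ester_level`` and the
    1624 cm⁻¹ carboxylate band with ``1 - ester_level``; fixed background
    features (carbohydrate fingerprint bands, the OH stretch) and white
    noise complete the spectrum.
    """
    if not 0.0 <= ester_level <= 1.0:
        raise ValueError("ester_level must lie in [0, 1]")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    rng = _rng(seed)
    w = np.arange(800.0, 4000.0 + 2.0, 2.0)

    def gauss(center, width):
        return np.exp(-0.5 * ((w - center) / width) ** 2)

    background = (
        0.02
        + 0.60 * gauss(1040.0, 55.0)
        + 0.25 * gauss(1370.0, 45.0)
        + 0.30 * gauss(3350.0, 180.0)
    )
    signal = (
        background
        + band_amplitude * ester_level * gauss(1740.0, 16.0)
        + band_amplitude * (1.0 - ester_level) * gauss(1624.0, 16.0)
    )
    spectra = []
    for r in range(n_replicates):
        a = signal + (rng.normal(0.0, noise_sd, size=w.size) if noise_sd > 0 else 0.0)
        spectra.append(
            Spectrum(wavenumber=w.copy(), absorbance=a, meta={"replicate": r + 1, "ester_level": ester_level})
        )
    return spectra


# ---------------------------------------------------------------------------
# serialization


def write_panel(panel: Panel, outdir) -> dict[str, Path]:
    """Write a panel in the tab-delimited formats the pipeline reads.

    Emits ``genotypes.tsv`` (markers as rows), ``expression.tsv``
    (unigene x accession RPKM), ``q.csv``, ``traits.tsv``,
    ``config.json`` and ``truth.json``; returns the path map.
    """
    from atscan import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "expression": outdir / "expression.tsv",
        "q": outdir / "q.csv",
        "traits": outdir / "traits.tsv",
        "config": outdir / "config.json",
        "truth": outdir / "truth.json",
    }
    io.write_genotypes(panel.snps, paths["genotypes"])
    io.write_expression(panel.expr, paths["expression"])
    io.write_q(panel.q, paths["q"])
    io.write_table(panel.traits, paths["traits"], provenance={"stage": "synth"})
    paths["config"].write_text(json.dumps(panel.config.to_dict(), indent=1, sort_keys=True))
    panel.truth.to_json(paths["truth"])
    return paths
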