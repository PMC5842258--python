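"""End-to-end pipeline orchestration.

``run_full`` chains mechanics → trait statistics → MAF filtering →
kinship → MLM SNP scans → GEM scans → expression-as-trait second-pass
scans, writing every stage's output with provenance headers and a JSON
report with content digests so a rerun under the same configuration can
be verified byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from atscan import assoc, io, mechanics, plots, traitstats

__all__ = ["RunConfig", "ConfigError", "StageError", "run_full"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """File paths and parameters of a full run."""

    outdir: str
    genotypes: str
    q: str
    traits: str | None = None
    expression: str | None = None
    curves_dir: str | None = None
    geometry: str | None = None
    span: float = mechanics.DEFAULT_SPAN_MM
    maf_threshold: float = 0.05
    scan_traits: tuple[str, ...] = ("fmax",)
    top_gems: int = 1
    gem_transform: str = "log2p1"
    make_plots: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("scan_traits"), list):
            data["scan_traits"] = tuple(data["scan_traits"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        problems = []
        for name in ("genotypes", "q", "traits", "expression", "geometry", "curves_dir"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                problems.append(f"{name}: {path} does not exist")
        if self.traits is None and (self.curves_dir is None or self.geometry is None):
            problems.append("either 'traits' or both 'curves_dir' and 'geometry' are required")
        if not 0 < self.maf_threshold <= 0.5:
            problems.append("maf_threshold must lie in (0, 0.5]")
        if self.span <= 0:
            problems.append("span must be positive")
        if problems:
            raise ConfigError("; ".join(problems))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written
    to ``<outdir>/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(config).items()}, "stages": {}, "outputs": {}}
    report["config"]["scan_traits"] = list(config.scan_traits)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, stage: str, extra: dict | None = None):
        prov = {"stage": stage, "seed": config.seed}
        if extra:
            prov.update(extra)
        path = outdir / name
        io.write_table(df, path, provenance=prov)
        written[name] = path

    # -- inputs ------------------------------------------------------------
    try:
        snps = io.read_genotypes(config.genotypes)
        q = io.read_q(config.q)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    # -- mechanics ---------------------------------------------------------
    if config.traits is not None:
        traits = io.read_table(config.traits)
    else:
        try:
            geometry = io.read_geometry_csv(config.geometry)
            curves = {
                rec: io.read_curve_csv(Path(config.curves_dir) / f"{rec}.csv")
                for rec in geometry["sample"]
            }
            traits = mechanics.derive_trait_table(curves, geometry, span=config.span)
        except Exception as exc:
            raise StageError("mechanics", str(exc)) from exc
        emit("trait_table.tsv", traits, "mechanics", {"span_mm": config.span})
    if "accession" not in traits.columns:
        raise StageError("traitstats", "trait table lacks an 'accession' column")
    means = (
        traits.drop(columns=["sample", "replicate"], errors="ignore")
        .groupby("accession")
        .mean(numeric_only=True)
    )
    emit("accession_means.tsv", means.reset_index(), "traitstats")

    # -- trait statistics --------------------------------------------------
    try:
        anova_rows = []
        for trait in means.columns:
            try:
                res = traitstats.genotype_anova(traits, trait)
            except ValueError:
                continue
            anova_rows.append(
                {
                    "trait": trait,
                    "fstat": res.fstat,
                    "pvalue": res.pvalue,
                    "used_log10": res.used_log10,
                    "log_offset": res.log_offset,
                    "significant": res.significant,
                }
            )
        emit("anova.tsv", pd.DataFrame(anova_rows), "traitstats")
        try:
            corr = traitstats.correlation_matrix(means)
        except ValueError as exc:  # e.g. fewer than 3 accessions
            report["stages"]["traitstats"] = {
                "n_traits": len(means.columns),
                "correlations_skipped": str(exc),
            }
        else:
            emit("correlations_r.tsv", corr.r.reset_index(names="trait"), "traitstats")
            emit(
                "correlations_lower.tsv",
                corr.lower_triangle().reset_index(names="trait"),
                "traitstats",
            )
            report["stages"]["traitstats"] = {"n_traits": len(means.columns)}
    except Exception as exc:
        raise StageError("traitstats", str(exc)) from exc

    # -- association -------------------------------------------------------
    try:
        filtered, filt_report = assoc.maf_filter(snps, config.maf_threshold)
        report["stages"]["maf_filter"] = {
            "n_input": filt_report.n_input,
            "n_retained": filt_report.n_retained,
            "n_removed_maf": filt_report.n_removed_maf,
            "n_all_missing": filt_report.n_all_missing,
            "threshold": filt_report.threshold,
        }
        k = assoc.kinship_matrix(filtered)
    except Exception as exc:
        raise StageError("kinship", str(exc)) from exc

    gem_results: dict[str, pd.DataFrame] = {}
    for trait in config.scan_traits:
        if trait not in means.columns:
            raise StageError("mlm_scan", f"trait {trait!r} not in trait table")
        y = means[trait].dropna()
        try:
            vc = assoc.fit_null_model(y, q, k)
            res = assoc.mlm_scan(y, filtered, q, k, vc=vc)
        except Exception as exc:
            raise StageError("mlm_scan", f"trait {trait!r}: {exc}") from exc
        emit(
            f"snp_scan_{trait}.tsv",
            res,
            "mlm_scan",
            {"trait": trait, "delta": f"{vc.delta:.6g}", "maf_threshold": config.maf_threshold},
        )
        report["stages"].setdefault("mlm_scan", {})[trait] = {
            "delta": vc.delta,
            "lambda": assoc.genomic_inflation(res["pvalue"].dropna()),
            "top_marker": res.loc[res["pvalue"].idxmin(), "marker"]
            if res["pvalue"].notna().any()
            else None,
        }
        if config.make_plots:
            plots.make_manhattan(res, outdir / f"manhattan_{trait}.png", title=trait)
            written[f"manhattan_{trait}.png"] = outdir / f"manhattan_{trait}.png"

        if config.expression is not None:
            try:
                expr = io.read_expression(config.expression)
                gres = assoc.gem_scan(y, expr, q, transform=config.gem_transform)
            except Exception as exc:
                raise StageError("gem_scan", f"trait {trait!r}: {exc}") from exc
            emit(f"gem_scan_{trait}.tsv", gres, "gem_scan", {"trait": trait})
            gem_results[trait] = gres
            report["stages"].setdefault("gem_scan", {})[trait] = {
                "top_unigene": gres.loc[gres["pvalue"].idxmin(), "unigene"]
                if gres["pvalue"].notna().any()
                else None
            }

    # -- expression-as-trait second pass ------------------------------------
    if gem_results and config.top_gems > 0:
        expr = io.read_expression(config.expression)
        second_pass = {}
        for trait, gres in gem_results.items():
            top = (
                gres.dropna(subset=["pvalue"])
                .nsmallest(config.top_gems, "pvalue")["unigene"]
                .tolist()
            )
            for unigene in top:
                try:
                    res2 = assoc.expression_as_trait(unigene, expr, filtered, q, k)
                except Exception as exc:
                    raise StageError("expression_as_trait", f"{unigene}: {exc}") from exc
                name = f"expr_as_trait_{unigene}.tsv"
                emit(name, res2, "expression_as_trait", {"unigene": unigene, "for_trait": trait})
                second_pass[unigene] = {
                    "for_trait": trait,
                    "top_marker": res2.loc[res2["pvalue"].idxmin(), "marker"]
                    if res2["pvalue"].notna().any()
                    else None,
                }
        report["stages"]["expression_as_trait"] = second_pass

    report["outputs"] = {name: _digest(path) for name, path in sorted(written.items())}
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
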