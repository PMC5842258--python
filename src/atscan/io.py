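"""Readers and writers for the pipeline's tab-delimited formats.

All tabular outputs are UTF-8, tab-delimited, with ``#``-prefixed
provenance header lines.  Genotype input accepts two dialects,
auto-detected from the header:

* the package's own layout — markers as rows:
  ``marker  chrom  pos  allele0  allele1  acc1..accN`` with dosage calls
  in {0, 1, 2, NA};
* a HapMap-dialect table (header starting ``rs#``) with single-letter
  IUPAC diploid codes per accession, as distributed for transcriptome
  SNP collections.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from atscan.assoc import ExpressionMatrix, SnpMatrix, validate_q
from atscan.ftir import Spectrum
from atscan.mechanics import BendCurve

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_q",
    "write_q",
    "read_table",
    "write_table",
    "read_curve_csv",
    "read_geometry_csv",
    "read_spectrum_csv",
    "read_spectra_long",
]

# IUPAC single-letter diploid codes -> unordered allele pair
IUPAC_DIPLOID = {
    "A": ("A", "A"), "C": ("C", "C"), "G": ("G", "G"), "T": ("T", "T"),
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"), "W": ("A", "T"),
    "K": ("G", "T"), "M": ("A", "C"),
}
HAPMAP_META_COLS = 11  # rs#, alleles, chrom, pos, strand, assembly#, center,
                       # protLSID, assayLSID, panelLSID, QCcode


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in sorted(provenance.items()))


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Write a tidy table as tab-delimited UTF-8 with provenance headers."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(_provenance_lines(provenance))
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes(snps: SnpMatrix, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    alleles = snps.alleles
    if alleles is None:
        alleles = pd.DataFrame(
            {"allele0": "A", "allele1": "G"}, index=snps.markers
        )
    geno = snps.genotypes.T  # markers as rows
    out = pd.DataFrame(
        {
            "marker": snps.markers,
            "chrom": snps.marker_map["chrom"].to_numpy(),
            "pos": snps.marker_map["pos"].to_numpy(),
            "allele0": alleles["allele0"].to_numpy(),
            "allele1": alleles["allele1"].to_numpy(),
        }
    )
    calls = geno.to_numpy(dtype=float)
    call_df = pd.DataFrame(
        np.where(np.isnan(calls), "NA", calls.astype(object)),
        columns=snps.accessions,
    )
    # dosages as compact integers
    for c in call_df.columns:
        call_df[c] = [v if v == "NA" else str(int(v)) for v in call_df[c]]
    out = pd.concat([out, call_df], axis=1)
    buf = _io.StringIO()
    buf.write(_provenance_lines(provenance))
    out.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_genotypes(path) -> SnpMatrix:
    """Read a genotype table, auto-detecting the dialect from its header."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
    first_field = header.split("\t", 1)[0].strip().lower()
    if first_field in ("rs#", "rs"):
        return _read_hapmap(path)
    return _read_simple_genotypes(path)


def _read_simple_genotypes(path) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], dtype={"chrom": str})
    required = {"marker", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype table must have columns {sorted(required)}")
    df = df.set_index("marker")
    meta_cols = [c for c in ("chrom", "pos", "allele0", "allele1") if c in df.columns]
    acc_cols = [c for c in df.columns if c not in meta_cols]
    genotypes = df[acc_cols].astype(float).T
    genotypes.index.name = "accession"
    marker_map = df[["chrom", "pos"]]
    alleles = df[["allele0", "allele1"]] if {"allele0", "allele1"} <= set(df.columns) else None
    return SnpMatrix(genotypes=genotypes, marker_map=marker_map, alleles=alleles)


def _read_hapmap(path) -> SnpMatrix:
    # the header itself contains '#' ("rs#"), so strip provenance lines by
    # hand instead of using the pandas comment feature
    with open(path, encoding="utf-8") as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str)
    meta = df.columns[:HAPMAP_META_COLS]
    acc_cols = list(df.columns[HAPMAP_META_COLS:])
    if not acc_cols:
        raise ValueError("HapMap table has no accession columns")
    markers = df[meta[0]]
    allele_pairs = df[meta[1]].str.split("/", expand=True)
    if allele_pairs.shape[1] < 2:
        raise ValueError("HapMap 'alleles' column must be like 'A/G'")
    a0 = allele_pairs[0].to_numpy()
    a1 = allele_pairs[1].to_numpy()
    calls = df[acc_cols].to_numpy(dtype=object)
    dosage = np.full(calls.shape, np.nan)
    for i in range(calls.shape[0]):
        for j in range(calls.shape[1]):
            code = str(calls[i, j]).strip().upper()
            pair = IUPAC_DIPLOID.get(code)
            if pair is None:
                continue  # N, -, NN ... -> missing
            if set(pair) <= {a0[i], a1[i]}:
                dosage[i, j] = pair.count(a1[i])
    genotypes = pd.DataFrame(dosage.T, index=pd.Index(acc_cols, name="accession"),
                             columns=pd.Index(markers, name="marker"))
    marker_map = pd.DataFrame(
        {"chrom": df[meta[2]].to_numpy(), "pos": df[meta[3]].astype(float).to_numpy()},
        index=pd.Index(markers, name="marker"),
    )
    alleles = pd.DataFrame({"allele0": a0, "allele1": a1},
                           index=pd.Index(markers, name="marker"))
    # HapMap files are position-sorted per chromosome but chromosome blocks
    # may interleave; sort to genome order without disturbing chrom order
    chrom_rank = {c: i for i, c in enumerate(marker_map["chrom"].unique())}
    order = marker_map.assign(_rank=marker_map["chrom"].map(chrom_rank)).sort_values(
        ["_rank", "pos"], kind="stable"
    ).index
    marker_map = marker_map.loc[order]
    return SnpMatrix(genotypes=genotypes.loc[:, order], marker_map=marker_map, alleles=alleles.loc[order])


# ---------------------------------------------------------------------------
# expression / Q


def write_expression(expr: ExpressionMatrix, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    out = pd.DataFrame(index=expr.unigenes)
    if expr.gene_map is not None:
        out["chrom"] = expr.gene_map["chrom"]
        out["pos"] = expr.gene_map["pos"]
    out = pd.concat([out, expr.rpkm], axis=1)
    buf = _io.StringIO()
    buf.write(_provenance_lines(provenance))
    out.to_csv(buf, sep="\t", index_label="unigene", float_format="%.6g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="unigene", dtype={"chrom": str})
    gene_map = None
    if {"chrom", "pos"} <= set(df.columns):
        gene_map = df[["chrom", "pos"]]
        df = df.drop(columns=["chrom", "pos"])
    return ExpressionMatrix(rpkm=df.astype(float), gene_map=gene_map)


def write_q(q: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    buf = _io.StringIO()
    if provenance:
        buf.write(_provenance_lines(provenance))
    q.to_csv(buf, index_label="accession")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_q(path) -> pd.DataFrame:
    q = pd.read_csv(path, comment="#", index_col="accession")
    return validate_q(q)


# ---------------------------------------------------------------------------
# curves, geometry, spectra


def read_curve_csv(path) -> BendCurve:
    """Per-sample bend trace: CSV with ``displacement_mm,force`` columns."""
    df = pd.read_csv(path, comment="#")
    if not {"displacement_mm", "force"} <= set(df.columns):
        raise ValueError("curve CSV needs 'displacement_mm' and 'force' columns")
    return BendCurve(
        displacement=df["displacement_mm"].to_numpy(dtype=float),
        force=df["force"].to_numpy(dtype=float),
    )


def read_geometry_csv(path) -> pd.DataFrame:
    """Per-sample cross-section measurements."""
    df = pd.read_csv(path, comment="#")
    required = {"sample", "accession", "whole_area_mm2", "hollow_area_mm2"}
    if not required <= set(df.columns):
        raise ValueError(f"geometry CSV needs columns {sorted(required)}")
    return df


def read_spectrum_csv(path) -> Spectrum:
    """Single spectrum: CSV with ``wavenumber_cm1,absorbance`` columns."""
    df = pd.read_csv(path, comment="#")
    if not {"wavenumber_cm1", "absorbance"} <= set(df.columns):
        raise ValueError("spectrum CSV needs 'wavenumber_cm1' and 'absorbance' columns")
    return Spectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def read_spectra_long(path) -> dict[str, list[Spectrum]]:
    """Long-format multi-spectrum table grouped by genotype.

    Columns: ``genotype, sample, wavenumber_cm1, absorbance``; returns a
    mapping genotype -> list of per-sample spectra.
    """
    df = pd.read_csv(path, comment="#")
    required = {"genotype", "sample", "wavenumber_cm1", "absorbance"}
    if not required <= set(df.columns):
        raise ValueError(f"long spectra table needs columns {sorted(required)}")
    out: dict[str, list[Spectrum]] = {}
    for (genotype, sample), sub in df.groupby(["genotype", "sample"], sort=True):
        out.setdefault(str(genotype), []).append(
            Spectrum(
                wavenumber=sub["wavenumber_cm1"].to_numpy(dtype=float),
                absorbance=sub["absorbance"].to_numpy(dtype=float),
                meta={"sample": sample, "genotype": genotype},
            )
        )
    return out
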