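"""Reading and writing cohort files.

Phenotypes travel as a delimited text table (comma or tab, auto-detected on
read) with a fixed header contract; genotypes as either a delimited dosage
table (0/1/2 copies of the minor allele) or a minimal VCF v4.2 with GT-only
FORMAT.  Round-tripping through :func:`write_dataset` / :func:`read_dataset`
is an identity on every field including missingness.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import N_WAVES, LongitudinalDataset
from .errors import DataFormatError

__all__ = ["write_dataset", "read_dataset", "write_vcf", "read_vcf"]

_FLOAT_FMT = "%.17g"  # round-trips doubles exactly

PHENOTYPE_REQUIRED = ["subject_id", "pts_w1", "pts_w2", "pts_w3", "cts_total",
                      "age", "gender", "pc1", "pc2"]


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def write_dataset(
    dataset: LongitudinalDataset,
    phenotype_path,
    genotype_path=None,
    genotype_format: str = "table",
    sep: str = ",",
) -> None:
    """Write the cohort; ``genotype_format`` is ``"table"`` or ``"vcf"``."""
    dataset.to_frame().to_csv(phenotype_path, sep=sep, index=False,
                              float_format=_FLOAT_FMT)
    if genotype_path is not None:
        if genotype_format == "table":
            dataset.genotype_frame().to_csv(genotype_path, sep=sep, index=False,
                                            float_format=_FLOAT_FMT)
        elif genotype_format == "vcf":
            write_vcf(dataset, genotype_path)
        else:
            raise ValueError(f"unknown genotype_format {genotype_format!r}")


def read_dataset(phenotype_path, genotype_path=None) -> LongitudinalDataset:
    """Read a cohort written by :func:`write_dataset` (or hand-built files
    following the same header contract).  Malformed rows are reported with
    1-based line numbers (header = line 1)."""
    sep = _detect_sep(phenotype_path)
    try:
        df = pd.read_csv(phenotype_path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # delegate parse position when pandas offers one
        raise DataFormatError(f"cannot parse {phenotype_path}: {exc}") from exc
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{phenotype_path}: missing required column(s) {', '.join(missing)}"
        )

    bad_lines = []
    numeric = {}
    num_cols = [c for c in df.columns if c != "subject_id"]
    for col in num_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        newly_bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        bad_lines.extend((df.index[newly_bad] + 2).tolist())
        numeric[col] = vals.to_numpy(dtype=float)
    if bad_lines:
        raise DataFormatError(
            f"{phenotype_path}: non-numeric values", lines=sorted(set(bad_lines))
        )

    n = len(df)
    pts = np.column_stack([numeric[f"pts_w{w + 1}"] for w in range(N_WAVES)])
    item_cols = [f"cts_{j + 1}" for j in range(6)]
    cts_items = (
        np.column_stack([numeric[c] for c in item_cols])
        if all(c in df.columns for c in item_cols)
        else None
    )
    true_class = (
        numeric["true_class"].astype(int) if "true_class" in df.columns else None
    )

    if genotype_path is None:
        dosages = np.zeros((n, 0))
        snp_names: tuple = ()
        geno_ids = None
    elif str(genotype_path).endswith(".vcf"):
        geno_ids, snp_names, dosages = read_vcf(genotype_path)
    else:
        gsep = _detect_sep(genotype_path)
        gdf = pd.read_csv(genotype_path, sep=gsep, float_precision="round_trip")
        if "subject_id" not in gdf.columns:
            raise DataFormatError(f"{genotype_path}: missing subject_id column")
        geno_ids = gdf["subject_id"].astype(str).to_numpy()
        snp_names = tuple(c for c in gdf.columns if c != "subject_id")
        dosages = gdf[list(snp_names)].to_numpy(dtype=float)

    if geno_ids is not None:
        order = {sid: i for i, sid in enumerate(geno_ids)}
        try:
            idx = np.array([order[str(s)] for s in df["subject_id"]])
        except KeyError as exc:
            raise DataFormatError(
                f"{genotype_path}: no genotype row for subject {exc.args[0]}"
            ) from exc
        dosages = dosages[idx]

    try:
        return LongitudinalDataset(
            subject_id=df["subject_id"].to_numpy(),
            pts=pts,
            cts_items=cts_items,
            cts_total=numeric["cts_total"],
            dosages=dosages,
            snp_names=snp_names,
            age=numeric["age"],
            gender=numeric["gender"],
            ancestry_pcs=np.column_stack([numeric["pc1"], numeric["pc2"]]),
            true_class=true_class,
        )
    except Exception as exc:
        raise DataFormatError(f"{phenotype_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# minimal VCF (GT only)

#: synthetic placeholder alleles; REF is the major allele, ALT the minor, so
#: the ALT-allele count in GT equals the minor-allele dosage
_REF, _ALT = "A", "C"


def write_vcf(dataset: LongitudinalDataset, path) -> None:
    """Minimal VCF v4.2: one record per SNP, GT-only, ALT = minor allele."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=15>\n")
        samples = "\t".join(str(s) for s in dataset.subject_id)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, name in enumerate(dataset.snp_names):
            calls = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in dataset.dosages[:, j]
            )
            fh.write(
                f"15\t{1000 * (j + 1)}\t{name}\t{_REF}\t{_ALT}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path):
    """Read a GT-only VCF; returns (sample_ids, snp_names, dosage matrix).

    Dosage counts ALT alleles; the writer orients ALT as the minor allele,
    so dosage = copies of the minor allele.  Uses pysam's VCF parser.
    """
    import pysam

    try:
        vf = pysam.VariantFile(os.fspath(path))
    except Exception as exc:
        raise DataFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = np.array(list(vf.header.samples))
    names, rows = [], []
    for rec in vf:
        names.append(rec.id if rec.id is not None else f"{rec.chrom}:{rec.pos}")
        row = np.full(len(samples), np.nan)
        for i, sid in enumerate(samples):
            alleles = rec.samples[sid]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            row[i] = float(sum(1 for a in alleles if a == 1))
        rows.append(row)
    vf.close()
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    return samples, tuple(names), dosages
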