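"""Readers and writers for the pipeline's on-disk formats.

Genotypes are accepted either as VCF 4.x (GT fields; dosages counted on the
ALT allele) or as a plain dosage TSV (``SNP CHR POS A1 A2 <sample...>``,
missing = ``NA``). Summary statistics, phenotypes and result tables are
tab-separated with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FormatError,
    GenotypeDataset,
    SummaryStatTable,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("SNP", "A1", "A2", "BETA", "P")
DOSAGE_META_COLUMNS = ("SNP", "CHR", "POS", "A1", "A2")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeDataset:
    """Read genotypes from a VCF or a dosage TSV.

    For VCF the ALT allele is the counted allele (``a1``); non-biallelic
    records are skipped with a warning. Variants are returned sorted by
    (chrom, pos).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage_tsv"
    if format == "vcf":
        ds = _read_vcf(path)
    elif format == "dosage_tsv":
        ds = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return ds.sort_variants()


def _read_vcf(path: Path) -> GenotypeDataset:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, chroms, poss, a1s, a2s, cols = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping non-biallelic record %s at %s:%s", v.ID, v.CHROM, v.POS)
            continue
        dos = np.empty(len(samples), dtype=np.float64)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for a in alleles if a == 1))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        a1s.append(v.ALT[0])
        a2s.append(v.REF)
        cols.append(dos)
    if n_skipped:
        logger.warning("%d non-biallelic records skipped in %s", n_skipped, path)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.float64)
    )
    return GenotypeDataset(variants=variants, samples=samples, dosages=dosages)


def _read_dosage_tsv(path: Path) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    except Exception as exc:
        raise FormatError(f"cannot parse dosage TSV {path}: {exc}") from exc
    missing = [c for c in DOSAGE_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV {path} lacks required column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in DOSAGE_META_COLUMNS]
    variants = pd.DataFrame(
        {
            "id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(int),
            "a1": df["A1"].astype(str),
            "a2": df["A2"].astype(str),
        }
    )
    dosages = df[sample_cols].to_numpy(dtype=np.float64).T
    return GenotypeDataset(variants=variants, samples=sample_cols, dosages=dosages)


def write_genotypes(ds: GenotypeDataset, path: str | Path, format: str = "auto") -> None:
    """Write genotypes as VCF (integer dosages become GT fields) or dosage TSV."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" else "dosage_tsv"
    if format == "vcf":
        _write_vcf(ds, path)
    elif format == "dosage_tsv":
        _write_dosage_tsv(ds, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(ds: GenotypeDataset, path: Path) -> None:
    chroms = []
    for c in ds.variants["chrom"]:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for j, row in enumerate(ds.variants.itertuples(index=False)):
            gts = "\t".join(
                _GT_CODES.get(d, "./.") if not np.isnan(d) else "./."
                for d in ds.dosages[:, j]
            )
            # a2 is REF, a1 (counted allele) is ALT
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_dosage_tsv(ds: GenotypeDataset, path: Path) -> None:
    meta = pd.DataFrame(
        {
            "SNP": ds.variants["id"],
            "CHR": ds.variants["chrom"],
            "POS": ds.variants["pos"],
            "A1": ds.variants["a1"],
            "A2": ds.variants["a2"],
        }
    )
    dos = pd.DataFrame(ds.dosages.T, columns=ds.samples)
    dos = dos.astype(object).where(~dos.isna(), "NA")
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path, phenotype_label: str = "") -> SummaryStatTable:
    """Read a ``SNP A1 A2 BETA P`` summary-statistics TSV.

    Rows with P outside (0, 1] are rejected (counted in a log message);
    a missing required column raises :class:`FormatError` naming it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    except Exception as exc:
        raise FormatError(f"cannot parse summary TSV {path}: {exc}") from exc
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"summary TSV {path} lacks required column {col!r}")
    p = pd.to_numeric(df["P"], errors="coerce")
    beta = pd.to_numeric(df["BETA"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1) | beta.isna()
    if bad.any():
        logger.warning("%s: rejected %d rows with invalid P or BETA", path, int(bad.sum()))
    df = df.loc[~bad]
    records = pd.DataFrame(
        {
            "id": df["SNP"].astype(str).to_numpy(),
            "a1": df["A1"].astype(str).to_numpy(),
            "a2": df["A2"].astype(str).to_numpy(),
            "beta": beta[~bad].to_numpy(dtype=float),
            "p": p[~bad].to_numpy(dtype=float),
        }
    )
    label = phenotype_label or path.stem
    return SummaryStatTable(phenotype_label=label, records=records)


def write_summary_stats(table: SummaryStatTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "SNP": table.records["id"],
            "A1": table.records["a1"],
            "A2": table.records["a2"],
            "BETA": table.records["beta"],
            "P": table.records["p"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# phenotypes / results / config
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (``IID age sex stroke <subtests...>``)."""
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise FormatError(f"phenotype TSV {path} lacks required column 'IID'")
    if df["IID"].duplicated().any():
        raise FormatError(f"phenotype TSV {path} has duplicate IIDs")
    return df.set_index("IID")


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="IID", float_format="%.10g")


def write_results(table: pd.DataFrame | Sequence, path: str | Path) -> None:
    """Write result rows as TSV with >= 6 significant digits on floats."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r._asdict() if hasattr(r, "_asdict") else dict(r) for r in table])
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg


def sorted_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a variant table sorted by (chrom, pos)."""
    keys = [
        (chrom_sort_key(c), p) for c, p in zip(variants["chrom"], variants["pos"])
    ]
    order = sorted(range(len(keys)), key=keys.__getitem__)
    return variants.iloc[order].reset_index(drop=True)
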