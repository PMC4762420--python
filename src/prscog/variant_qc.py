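"""Variant-level quality control and summary-statistic harmonization.

QC keeps a variant only if its call rate, minor-allele frequency and
Hardy–Weinberg test all pass (one conjunction over the input dataset, not a
sequential re-estimation). Harmonization then intersects the cohort with the
base GWAS, removes strand-ambiguous (A/T, G/C) variants and low-frequency
variants, and aligns effect signs to the cohort's counted allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeDataset,
    HarmonizedEffects,
    PrscogError,
    SummaryStatTable,
    VALID_ALLELES,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Variant-filter thresholds.

    ``call_rate_min``, ``maf_min`` and ``hwe_p_min`` gate the per-cohort QC;
    ``score_maf_min`` is the stricter frequency floor applied at
    harmonization time (variants rarer than this in the cohort never enter a
    score).
    """

    call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    score_maf_min: float = 0.02

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "hwe_p_min", "score_maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PrscogError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy–Weinberg.

    Expected genotype counts come from the estimated allele frequency.
    Returns 1.0 when any expected count is zero (monomorphic site: the model
    fits trivially). All-zero counts are a domain error.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise PrscogError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise PrscogError("all genotype counts are zero")
    return float(hwe_test_vectorized(np.array([n_AA]), np.array([n_Aa]), np.array([n_aa]))[0])


def hwe_test_vectorized(
    n_AA: np.ndarray, n_Aa: np.ndarray, n_aa: np.ndarray
) -> np.ndarray:
    """Vectorized form of :func:`hwe_test` over parallel count arrays."""
    n_AA = np.asarray(n_AA, dtype=float)
    n_Aa = np.asarray(n_Aa, dtype=float)
    n_aa = np.asarray(n_aa, dtype=float)
    n = n_AA + n_Aa + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2.0 * n_AA + n_Aa) / (2.0 * n)
        q = 1.0 - p
        e_AA = n * p * p
        e_Aa = 2.0 * n * p * q
        e_aa = n * q * q
        chi2 = (
            (n_AA - e_AA) ** 2 / e_AA
            + (n_Aa - e_Aa) ** 2 / e_Aa
            + (n_aa - e_aa) ** 2 / e_aa
        )
    pval = stats.chi2.sf(chi2, df=1)
    degenerate = (e_AA == 0) | (e_Aa == 0) | (e_aa == 0)
    pval = np.where(degenerate, 1.0, pval)
    return np.where(n == 0, np.nan, pval)


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def apply_variant_qc(
    ds: GenotypeDataset, thr: QCThresholds | None = None
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Filter variants on call rate, MAF and HWE; return (dataset, report).

    The three predicates are evaluated on the input dataset and combined
    with AND. The report has one row per *removed* variant with columns
    ``variant, filter, value`` (a variant failing several filters is listed
    once per failed filter).
    """
    if ds.n_variants == 0:
        raise PrscogError("cannot QC an empty dataset")
    thr = thr or QCThresholds()
    call = ds.call_rate()
    maf = ds.maf()
    n0, n1, n2 = ds.genotype_counts()
    hwe_p = hwe_test_vectorized(n2, n1, n0)  # orientation is irrelevant to the test
    hwe_p = np.where(np.isnan(hwe_p), 0.0, hwe_p)  # no calls at all -> fail

    pass_call = call >= thr.call_rate_min
    pass_maf = maf >= thr.maf_min
    pass_hwe = hwe_p >= thr.hwe_p_min
    keep = pass_call & pass_maf & pass_hwe

    rows = []
    ids = ds.variants["id"].to_numpy()
    for mask, name, values in (
        (~pass_call, "call_rate", call),
        (~pass_maf, "maf", maf),
        (~pass_hwe, "hwe", hwe_p),
    ):
        for j in np.flatnonzero(mask):
            rows.append({"variant": ids[j], "filter": name, "value": float(values[j])})
    report = pd.DataFrame(rows, columns=["variant", "filter", "value"])
    logger.info(
        "variant QC: %d/%d retained (call_rate fails=%d, maf fails=%d, hwe fails=%d)",
        int(keep.sum()), ds.n_variants,
        int((~pass_call).sum()), int((~pass_maf).sum()), int((~pass_hwe).sum()),
    )
    return ds.take_variants(keep), report


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or G/C (unresolvable across strands)."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise PrscogError(f"non-ACGT allele in pair {a1}/{a2}")
    pair = {a1, a2}
    return pair == {"A", "T"} or pair == {"G", "C"}


def harmonize(
    ds: GenotypeDataset,
    stats_table: SummaryStatTable,
    thr: QCThresholds | None = None,
) -> HarmonizedEffects:
    """Align summary effects to the dataset's counted alleles.

    Drops variants that are absent from the summary table, strand-ambiguous,
    rarer in the cohort than ``score_maf_min``, or whose allele pair cannot
    be matched. Where the summary effect allele is the dataset's *other*
    allele, beta is negated so every retained beta refers to the counted
    allele.
    """
    thr = thr or QCThresholds()
    maf = ds.maf()
    summary = stats_table.records.set_index("id")

    ids, betas, ps = [], [], []
    report = {
        "not_in_stats": 0,
        "ambiguous": 0,
        "low_maf": 0,
        "allele_mismatch": 0,
        "retained": 0,
    }
    for j, row in enumerate(ds.variants.itertuples(index=False)):
        vid = str(row.id)
        if vid not in summary.index:
            report["not_in_stats"] += 1
            continue
        if is_strand_ambiguous(row.a1, row.a2):
            report["ambiguous"] += 1
            continue
        if maf[j] < thr.score_maf_min:
            report["low_maf"] += 1
            continue
        srow = summary.loc[vid]
        s1, s2, beta = str(srow["a1"]), str(srow["a2"]), float(srow["beta"])
        if (s1, s2) == (row.a1, row.a2):
            aligned = beta
        elif (s1, s2) == (row.a2, row.a1):
            aligned = -beta
        else:
            report["allele_mismatch"] += 1
            continue
        ids.append(vid)
        betas.append(aligned)
        ps.append(float(srow["p"]))
    report["retained"] = len(ids)
    logger.info("harmonize %s: %s", stats_table.phenotype_label, report)
    table = pd.DataFrame({"id": ids, "beta": betas, "p": ps})
    return HarmonizedEffects(
        phenotype_label=stats_table.phenotype_label, table=table, report=report
    )


def harmonization_prefilter(
    ds: GenotypeDataset,
    stats_tables: dict[str, SummaryStatTable],
    thr: QCThresholds | None = None,
) -> GenotypeDataset:
    """Restrict a dataset to variants that could enter *any* score.

    Keeps variants that are non-ambiguous, at or above ``score_maf_min`` and
    present in at least one summary table. Running LD pruning on this set
    (rather than once per phenotype) is equivalent whenever the summary
    tables cover the same variants, and avoids redundant work.
    """
    thr = thr or QCThresholds()
    maf = ds.maf()
    in_any = set()
    for t in stats_tables.values():
        in_any.update(t.records["id"].astype(str))
    keep = np.zeros(ds.n_variants, dtype=bool)
    for j, row in enumerate(ds.variants.itertuples(index=False)):
        keep[j] = (
            str(row.id) in in_any
            and not is_strand_ambiguous(row.a1, row.a2)
            and maf[j] >= thr.score_maf_min
        )
    return ds.take_variants(keep)
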