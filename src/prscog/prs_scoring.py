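"""Pruning-and-thresholding polygenic risk scores.

Each score is the plain sum over its SNP set of (aligned beta x effect-allele
dosage). Missing genotypes contribute nothing — no mean imputation — and the
per-sample count of nonmissing SNPs is carried alongside as the downstream
covariate that absorbs the resulting scale differences. Thresholding is
strict (``p < t``), so SNP sets are nested across the canonical thresholds.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_P_THRESHOLDS,
    GenotypeDataset,
    HarmonizedEffects,
    PRSProfile,
    PrscogError,
    SummaryStatTable,
)
from .variant_qc import QCThresholds, harmonize

logger = logging.getLogger(__name__)


def threshold_label(phenotype: str, threshold: float) -> str:
    return f"{phenotype}_p{threshold:g}"


def subset_by_pvalue(effects: HarmonizedEffects, threshold: float) -> HarmonizedEffects:
    """Retain records with GWAS p strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise PrscogError(f"threshold must lie in (0, 1], got {threshold}")
    mask = effects.table["p"].to_numpy() < threshold
    return HarmonizedEffects(
        phenotype_label=effects.phenotype_label,
        table=effects.table.loc[mask].reset_index(drop=True),
        report=dict(effects.report),
    )


def compute_prs(
    ds: GenotypeDataset, effects: HarmonizedEffects
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (score, nonmissing-SNP count) for one SNP set.

    ``score_i = sum_j beta_j * dosage_ij`` over variants with an observed
    genotype; a sample with no observed variant in the set scores 0 with
    count 0.
    """
    vidx = ds.variant_index()
    missing_ids = [v for v in effects.table["id"] if v not in vidx]
    if missing_ids:
        raise PrscogError(
            f"effects reference variants absent from dataset: {missing_ids[:5]}"
        )
    if effects.n_variants == 0:
        logger.warning(
            "empty SNP set for %s: all scores 0", effects.phenotype_label
        )
        n = ds.n_samples
        return np.zeros(n), np.zeros(n, dtype=np.int64)
    cols = np.array([vidx[v] for v in effects.table["id"]], dtype=np.intp)
    beta = effects.table["beta"].to_numpy(dtype=float)
    X = ds.dosages[:, cols]
    observed = ~np.isnan(X)
    scores = np.where(observed, X, 0.0) @ beta
    n_nonmissing = observed.sum(axis=1).astype(np.int64)
    return scores, n_nonmissing


def compute_all_scores(
    ds: GenotypeDataset,
    stats: Mapping[str, SummaryStatTable | HarmonizedEffects],
    thresholds: Iterable[float] = DEFAULT_P_THRESHOLDS,
    qc: QCThresholds | None = None,
) -> PRSProfile:
    """One score column per (stroke phenotype x p-value threshold).

    ``stats`` may hold raw summary tables (harmonized here against ``ds``)
    or pre-harmonized effects. The dataset is expected to be QC-filtered and
    LD-pruned already. Columns are named ``<phenotype>_p<threshold>``.
    """
    thresholds = list(thresholds)
    score_data: dict[str, np.ndarray] = {}
    count_data: dict[str, np.ndarray] = {}
    for label, table in stats.items():
        if isinstance(table, SummaryStatTable):
            effects = harmonize(ds, table, qc)
        else:
            effects = table
        for t in thresholds:
            sub = subset_by_pvalue(effects, t)
            s, n = compute_prs(ds, sub)
            name = threshold_label(label, t)
            score_data[name] = s
            count_data[name] = n
    index = pd.Index(ds.samples, name="IID")
    return PRSProfile(
        scores=pd.DataFrame(score_data, index=index),
        counts=pd.DataFrame(count_data, index=index),
    )
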