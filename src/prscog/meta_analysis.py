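"""Random-effects meta-analysis of per-cohort partial correlations.

Correlations are pooled on the Fisher z scale with sampling variance
``1 / (n - 3 - k)`` for a partial correlation adjusted for ``k`` covariates.
Heterogeneity is the classical Cochran Q under fixed-effect weights;
between-study variance uses the DerSimonian–Laird moment estimator, and the
pooled estimate is back-transformed to the correlation scale.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetaResult, MetaStudy, PrscogError

logger = logging.getLogger(__name__)


def fisher_z(r: float, n: int, k_cov: int = 0) -> tuple[float, float]:
    """Fisher transform of a (partial) correlation with its variance.

    ``z = atanh(r)``, ``var = 1 / (n - 3 - k_cov)``; the ``k_cov`` term is
    the standard degrees-of-freedom correction for partial correlations.
    """
    if not abs(r) < 1:
        raise PrscogError(f"|r| must be < 1 for the Fisher transform, got {r}")
    denom = n - 3 - k_cov
    if denom < 1:
        raise PrscogError(f"n - 3 - k_cov must be >= 1 (n={n}, k_cov={k_cov})")
    return float(np.arctanh(r)), 1.0 / denom


def random_effects_meta(
    studies: Sequence[MetaStudy], scale: str = "z"
) -> MetaResult:
    """DerSimonian–Laird random-effects pooling with Cochran Q.

    On the default z scale: fixed-effect weights ``w = 1/v`` give the Q
    statistic; ``tau2 = max(0, (Q - (m-1)) / (sum w - sum w^2 / sum w))``;
    random-effect weights ``1/(v + tau2)`` give the pooled z, back-
    transformed to ``omnibus_r``. ``scale="r"`` pools raw correlations with
    variance ``(1 - r^2)^2 / (n - 1 - k_cov)`` instead (no back-transform).
    """
    if len(studies) < 2:
        raise PrscogError("meta-analysis needs at least 2 studies")
    for s in studies:
        if not isinstance(s, MetaStudy):
            raise PrscogError(f"invalid study entry: {s!r}")
    if scale == "z":
        pairs = [fisher_z(s.r, s.n, s.k_cov) for s in studies]
        eff = np.array([z for z, _ in pairs])
        var = np.array([v for _, v in pairs])
    elif scale == "r":
        eff = np.array([s.r for s in studies])
        var = np.array(
            [(1 - s.r**2) ** 2 / (s.n - 1 - s.k_cov) for s in studies]
        )
    else:
        raise PrscogError(f"unknown meta-analysis scale {scale!r}")

    m = len(studies)
    w = 1.0 / var
    mean_fe = float((w * eff).sum() / w.sum())
    Q = float((w * (eff - mean_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (m - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (var + tau2)
    pooled = float((w_star * eff).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    p_Q = float(stats.chi2.sf(Q, df=m - 1))
    omnibus = float(np.tanh(pooled)) if scale == "z" else pooled
    return MetaResult(
        omnibus_r=omnibus,
        se_z=se,
        tau2=tau2,
        Q=Q,
        p_Q=p_Q,
        n_studies=m,
    )


def run_meta_grid(
    cohort_tables: Mapping[str, pd.DataFrame],
    phenotypes: Mapping[str, Mapping[str, str]] | Sequence[str] = ("gf", "general", "crystallized"),
    scale: str = "z",
) -> pd.DataFrame:
    """Pool each (score x meta phenotype) across cohort association tables.

    ``cohort_tables`` maps cohort label to the DataFrame produced by
    :func:`prscog.association.run_association_grid`. ``phenotypes`` is
    either a list of phenotype column names common to all cohorts, or a
    mapping of meta-phenotype role -> {cohort: column name} when cohorts
    name their crystallized test differently. Scores present in fewer than
    2 cohorts are skipped with a warning.
    """
    if isinstance(phenotypes, Mapping):
        roles = {role: dict(m) for role, m in phenotypes.items()}
    else:
        roles = {ph: {c: ph for c in cohort_tables} for ph in phenotypes}

    all_scores: list[str] = []
    for table in cohort_tables.values():
        for s in table["score"].unique():
            if s not in all_scores:
                all_scores.append(s)

    rows = []
    for score in all_scores:
        for role, colmap in roles.items():
            studies = []
            for cohort, table in cohort_tables.items():
                pheno_col = colmap.get(cohort)
                if pheno_col is None:
                    continue
                hit = table[(table["score"] == score) & (table["phenotype"] == pheno_col)]
                if hit.empty:
                    continue
                row = hit.iloc[0]
                if not np.isfinite(row["r"]):
                    continue
                k_cov = len(str(row["covariates"]).split(",")) if row["covariates"] else 0
                studies.append(
                    MetaStudy(cohort=cohort, r=float(row["r"]), n=int(row["n"]), k_cov=k_cov)
                )
            if len(studies) < 2:
                logger.warning(
                    "score %s / phenotype %s present in %d cohort(s); skipped",
                    score, role, len(studies),
                )
                continue
            res = random_effects_meta(studies, scale=scale)
            rows.append(
                {
                    "score": score,
                    "phenotype": role,
                    "n_studies": res.n_studies,
                    "omnibus_r": res.omnibus_r,
                    "se_z": res.se_z,
                    "tau2": res.tau2,
                    "Q": res.Q,
                    "p_Q": res.p_Q,
                    "estimator": res.tau2_estimator,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "score", "phenotype", "n_studies", "omnibus_r",
            "se_z", "tau2", "Q", "p_Q", "estimator",
        ],
    )
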