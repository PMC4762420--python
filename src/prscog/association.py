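"""Partial correlations between risk scores and cognitive phenotypes.

Each test partials the score-specific nonmissing-SNP count and the 4 MDS
components out of both the score and the phenotype, correlates the
residuals, and tests the correlation with the usual t statistic on
``n - 2 - k`` degrees of freedom. Samples with a history of stroke are
excluded before any test; p-values are reported uncorrected by default
(the full grid is emitted so multiplicity handling stays with the reader).
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationResult, PRSProfile, PrscogError
from .phenotype_model import CognitivePhenotypes
from .population_structure import StructureComponents

logger = logging.getLogger(__name__)


class PartialCorrelation(NamedTuple):
    r: float
    p: float
    df: int
    n: int
    defined: bool = True


def partial_correlation(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None
) -> PartialCorrelation:
    """Partial correlation of x and y given covariates Z.

    r is the Pearson correlation of the residuals of x and y on
    [intercept | Z] over complete cases; the two-sided p comes from
    ``t = r sqrt(df / (1 - r^2))`` with ``df = n - 2 - ncol(Z)``. A zero
    residual variance yields an undefined result (``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None or (hasattr(Z, "size") and np.size(Z) == 0):
        Z = np.empty((len(x), 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    n = int(ok.sum())
    if n < k + 4:
        raise PrscogError(f"too few complete cases (n={n}) for {k} covariates")
    X = np.column_stack([np.ones(n), Z[ok]])
    coef_x, *_ = np.linalg.lstsq(X, x[ok], rcond=None)
    coef_y, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    rx = x[ok] - X @ coef_x
    ry = y[ok] - X @ coef_y
    vx, vy = rx @ rx, ry @ ry
    df = n - 2 - k
    # residual variance at numerical zero (e.g. x exactly linear in Z)
    tol_x = 1e-12 * max(1.0, float(x[ok] @ x[ok]))
    tol_y = 1e-12 * max(1.0, float(y[ok] @ y[ok]))
    if vx <= tol_x or vy <= tol_y:
        return PartialCorrelation(np.nan, np.nan, df, n, defined=False)
    r = float((rx @ ry) / np.sqrt(vx * vy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r, max(p, np.finfo(float).tiny), df, n)


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise PrscogError(f"unknown adjustment method {method!r}")


def run_association_grid(
    profile: PRSProfile,
    cog: CognitivePhenotypes,
    mds: StructureComponents,
    stroke: pd.Series | np.ndarray,
    phenotypes: Sequence[str] | None = None,
    exclude_stroke: bool = True,
    adjust: str = "none",
) -> pd.DataFrame:
    """One partial correlation per (score column x cognitive phenotype).

    Inputs must share sample ids; stroke-history cases are removed before
    any test. Covariates for each test are that score's nonmissing-SNP
    count plus the MDS components. Listwise deletion is per test. Returns
    a DataFrame with columns ``score phenotype n r p df covariates``.
    """
    phenotypes = list(phenotypes) if phenotypes is not None else list(cog.phenotypes)
    ids = profile.scores.index
    for name, other in (("phenotypes", cog.data.index), ("mds", mds.components.index)):
        missing = ids.difference(other)
        if len(missing):
            raise PrscogError(
                f"sample ids absent from {name} table: {list(missing[:5])}"
            )
    stroke = pd.Series(np.asarray(stroke, dtype=bool), index=ids) if not isinstance(stroke, pd.Series) else stroke.astype(bool)
    keep = ids if not exclude_stroke else ids[~stroke.reindex(ids).to_numpy()]
    if len(keep) == 0:
        raise PrscogError("no samples remain after stroke exclusion")
    if exclude_stroke:
        logger.info("excluded %d stroke cases; %d samples analyzed", len(ids) - len(keep), len(keep))

    cogd = cog.data.reindex(keep)
    mdsd = mds.components.reindex(keep)
    scores = profile.scores.reindex(keep)
    counts = profile.counts.reindex(keep)
    mds_names = list(mdsd.columns)

    results: list[AssociationResult] = []
    for score_name in profile.score_names:
        Z = np.column_stack(
            [counts[score_name].to_numpy(dtype=float), mdsd.to_numpy(dtype=float)]
        )
        # a constant nonmissing count (no missing genotypes) carries no
        # information and would make the design collinear with the intercept
        cz = Z[:, 0]
        if np.nanstd(cz) == 0:
            Z = Z[:, 1:]
            covariates = tuple(mds_names)
        else:
            covariates = (f"{score_name}_n", *mds_names)
        x = scores[score_name].to_numpy(dtype=float)
        for pheno_name in phenotypes:
            y = cogd[pheno_name].to_numpy(dtype=float)
            pc = partial_correlation(x, y, Z)
            results.append(
                AssociationResult(
                    score_name=score_name,
                    phenotype_name=pheno_name,
                    r=pc.r,
                    p=pc.p,
                    df=pc.df,
                    n=pc.n,
                    covariates=covariates,
                    defined=pc.defined,
                )
            )
    out = pd.DataFrame(
        {
            "score": [r.score_name for r in results],
            "phenotype": [r.phenotype_name for r in results],
            "n": [r.n for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "df": [r.df for r in results],
            "covariates": [",".join(r.covariates) for r in results],
        }
    )
    out["p_adjusted"] = _adjust_pvalues(out["p"].to_numpy(), adjust)
    return out
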