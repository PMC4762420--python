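"""Construction of the cohort cognitive phenotypes.

Each subtest is first adjusted for age and sex by least-squares
residualization. General fluid ability (gf) is the first principal component
of the adjusted fluid subtests (correlation-matrix PCA); general cognitive
ability re-runs the same PCA with the crystallized test added as a column.
The cognitive-aging phenotype residualizes later-life gf on the age-adjusted
childhood ability score together with age and sex, isolating change since
childhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PrscogError

logger = logging.getLogger(__name__)

#: names given to the derived composites in the output table
GF, GENERAL, AGING = "gf", "general", "aging"


@dataclass
class CognitivePhenotypes:
    """Adjusted subtests plus derived composites for one cohort.

    ``data`` is indexed by sample id; ``phenotypes`` lists the columns used
    in the per-cohort association grid; ``meta_phenotypes`` maps the three
    meta-analysis phenotype roles to column names.
    """

    data: pd.DataFrame
    phenotypes: list[str]
    meta_phenotypes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def residualize(y: np.ndarray | pd.Series, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [intercept | covariates].

    Rows with any missing value get NaN residuals; the fit uses complete
    cases only. With no covariates this is mean-centering. Rank-deficient
    covariates are an error.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        X = np.ones((n, 1))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        X = np.column_stack([np.ones(n), Z])
    ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    if ok.sum() < X.shape[1] + 2:
        raise PrscogError(
            f"too few complete cases ({int(ok.sum())}) for {X.shape[1]} design columns"
        )
    Xc, yc = X[ok], y[ok]
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        raise PrscogError(
            f"collinear covariates: design rank {rank} < {X.shape[1]} columns"
        )
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    out = np.full(n, np.nan)
    out[ok] = yc - Xc @ coef
    return out


def first_pc_composite(tests: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Scores on the first principal component of column-standardized tests.

    Complete cases only (listwise deletion; incomplete rows get NaN). The
    sign is oriented so the composite correlates positively with the row
    mean of the standardized inputs. A constant column is an error.
    """
    X = np.asarray(tests, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise PrscogError("need a matrix with at least 2 test columns")
    n = X.shape[0]
    ok = ~np.isnan(X).any(axis=1)
    Xc = X[ok]
    if Xc.shape[0] < X.shape[1] + 2:
        raise PrscogError("too few complete cases for PCA")
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise PrscogError(f"test column {j} is constant across complete cases")
    Z = (Xc - Xc.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    v = vecs[:, -1]
    scores = Z @ v
    rowmean = Z.mean(axis=1)
    if np.corrcoef(scores, rowmean)[0, 1] < 0:
        scores = -scores
    out = np.full(n, np.nan)
    out[ok] = scores
    return out


def cognitive_aging(
    gf: np.ndarray,
    childhood: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    childhood_age: np.ndarray | None = None,
) -> np.ndarray:
    """Later-life gf residualized on age-adjusted childhood score, age, sex.

    The childhood score is first residualized on its own age at testing when
    that age is available (the "age-adjusted" childhood score); cohorts
    without a childhood measure cannot form this phenotype.
    """
    childhood = np.asarray(childhood, dtype=float)
    if np.isnan(childhood).all():
        raise PrscogError(
            "no childhood scores available; skip the cognitive-aging phenotype"
        )
    if childhood_age is not None:
        childhood = residualize(childhood, np.asarray(childhood_age, dtype=float))
    Z = np.column_stack([childhood, np.asarray(age, float), np.asarray(sex, float)])
    return residualize(np.asarray(gf, dtype=float), Z)


# ---------------------------------------------------------------------------
# cohort-level assembly
# ---------------------------------------------------------------------------

def build_cognitive_phenotypes(
    pheno: pd.DataFrame,
    fluid: list[str] = ("fluid1", "fluid2", "fluid3"),
    crystallized: str = "crystallized",
    childhood: str | None = "childhood_score",
    age_col: str = "age",
    sex_col: str = "sex",
) -> CognitivePhenotypes:
    """Adjust subtests for age and sex, then derive gf / general / aging.

    The association phenotypes are the adjusted subtests (fluid battery plus
    the crystallized test) and the two composites — six columns for the
    canonical three-fluid-one-crystallized battery. The aging residual is
    added when a childhood score is present but is not part of the default
    association set (it is cohort-specific).
    """
    fluid = list(fluid)
    for col in (*fluid, crystallized, age_col, sex_col):
        if col not in pheno.columns:
            raise PrscogError(f"phenotype table lacks column {col!r}")
    covs = pheno[[age_col, sex_col]].to_numpy(dtype=float)
    out = pd.DataFrame(index=pheno.index)
    for col in (*fluid, crystallized):
        out[col] = residualize(pheno[col].to_numpy(dtype=float), covs)
    out[GF] = first_pc_composite(out[fluid])
    out[GENERAL] = first_pc_composite(out[[*fluid, crystallized]])

    has_childhood = childhood is not None and childhood in pheno.columns
    if has_childhood and not pheno[childhood].isna().all():
        out[AGING] = cognitive_aging(
            out[GF].to_numpy(),
            pheno[childhood].to_numpy(dtype=float),
            pheno[age_col].to_numpy(dtype=float),
            pheno[sex_col].to_numpy(dtype=float),
        )
    else:
        logger.info("no childhood score column; aging phenotype not constructed")

    phenotypes = [*fluid, crystallized, GF, GENERAL]
    meta = {"gf": GF, "general": GENERAL, "crystallized": crystallized}
    return CognitivePhenotypes(data=out, phenotypes=phenotypes, meta_phenotypes=meta)
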