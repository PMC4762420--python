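"""Multidimensional scaling of genetic distances for stratification control.

The distance is allele-sharing dissimilarity, ``1 - IBS``: for samples i, j
the mean over variants non-missing in both of ``1 - |g_i - g_j| / 2``.
Classical (Torgerson) MDS of that matrix yields the component scores used as
ancestry covariates; the first 4 components reproduce the conventional
stratification adjustment for SNP-array cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .datatypes import GenotypeDataset, PrscogError

logger = logging.getLogger(__name__)


@dataclass
class StructureComponents:
    """Per-sample MDS component scores with their eigenvalues."""

    components: pd.DataFrame  # index: sample ids; columns C1..Ck
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise PrscogError("eigenvalues must be non-increasing")
        self.eigenvalues = ev


def ibs_distance(ds: GenotypeDataset, chunk: int = 2000) -> np.ndarray:
    """Pairwise allele-sharing distance ``1 - IBS`` over complete variants.

    ``D[i, j] = 1 - mean_v(1 - |g_iv - g_jv| / 2)`` over variants observed
    in both samples. Raises if some pair shares no observed variant.
    Computed blockwise with matrix products: with one-hot indicators H0/H2
    of dosage 0 and 2, ``|a - b| = (a - b)^2 - 2 * (1[a=0]1[b=2] +
    1[a=2]1[b=0])``.
    """
    n, m = ds.dosages.shape
    if n < 2:
        raise PrscogError("IBS distance needs at least 2 samples")
    C = np.zeros((n, n))
    T = np.zeros((n, n))
    for s in range(0, m, chunk):
        X = ds.dosages[:, s : s + chunk]
        M = (~np.isnan(X)).astype(np.float64)
        Xf = np.where(np.isnan(X), 0.0, X)
        X2 = Xf * Xf
        H0 = ((X == 0.0).astype(np.float64))
        H2 = ((X == 2.0).astype(np.float64))
        C += M @ M.T
        sq = X2 @ M.T
        T += sq + sq.T - 2.0 * (Xf @ Xf.T)
        c02 = H0 @ H2.T
        T -= 2.0 * (c02 + c02.T)
    if (C == 0).any():
        i, j = np.argwhere((C == 0) & ~np.eye(n, dtype=bool))[0]
        raise PrscogError(
            f"samples {ds.samples[i]!r} and {ds.samples[j]!r} share no "
            "non-missing variant"
        )
    D = (T / 2.0) / C
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def classical_mds(
    D: np.ndarray, k: int = 4, sample_ids: list[str] | None = None
) -> StructureComponents:
    """Torgerson MDS: top-k eigenpairs of the double-centered squared matrix.

    ``B = -1/2 J D^2 J`` with J the centering projector; component m is
    ``eigenvector_m * sqrt(max(eigenvalue_m, 0))``. Sign convention: each
    component's largest-magnitude loading is positive. If fewer than ``k``
    positive eigenvalues are available the extra components are returned as
    zeros with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise PrscogError("distance matrix must be square and symmetric")
    if np.abs(np.diag(D)).max() > 1e-8:
        raise PrscogError("distance matrix must have a zero diagonal")
    k = int(k)
    if k < 1 or k > n - 1:
        raise PrscogError(f"k must lie in [1, n-1], got {k}")

    A = -0.5 * D * D
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    B = (B + B.T) / 2.0

    if n <= 600:
        vals, vecs = scipy.linalg.eigh(B)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        # deterministic Lanczos start vector for reproducibility
        v0 = np.cos(np.arange(n, dtype=float))
        vals, vecs = scipy.sparse.linalg.eigsh(B, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    n_pos = int((vals > 1e-12).sum())
    if n_pos < k:
        logger.warning("only %d positive eigenvalues available for k=%d", n_pos, k)
    comps = vecs * np.sqrt(np.maximum(vals, 0.0))
    for c in range(k):
        j = np.argmax(np.abs(comps[:, c]))
        if comps[j, c] < 0:
            comps[:, c] = -comps[:, c]
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    frame = pd.DataFrame(
        comps, index=pd.Index(ids, name="IID"), columns=[f"C{c + 1}" for c in range(k)]
    )
    return StructureComponents(components=frame, eigenvalues=vals)


def mds_components(
    ds: GenotypeDataset,
    k: int = 4,
    max_variants: int | None = None,
    seed: int = 0,
) -> StructureComponents:
    """IBS distance then classical MDS, optionally on a variant subsample.

    ``max_variants`` caps the number of variants entering the distance (a
    seeded uniform subsample); structure estimates stabilize well below the
    full array size, and the cap bounds the quadratic distance computation.
    """
    use = ds
    if max_variants is not None and ds.n_variants > max_variants:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(ds.n_variants, size=max_variants, replace=False))
        use = ds.take_variants(idx)
    D = ibs_distance(use)
    return classical_mds(D, k=k, sample_ids=list(ds.samples))
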