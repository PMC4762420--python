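"""Sliding-window LD pruning on squared genotype correlation.

The pruning rule mirrors the conventional ``--indep-pairwise 200 5 0.25``
recipe: scan 200-SNP windows sliding by 5 along each chromosome; whenever a
pair of still-retained variants has r-squared above the threshold, drop the
member with the lower minor-allele frequency (ties drop the later-positioned
one); repeat until a full pass removes nothing. r-squared is the squared
Pearson correlation of dosages over samples non-missing in both variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeDataset, PrscogError, chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneParams:
    window_size: int = 200
    window_step: int = 5
    r2_max: float = 0.25

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise PrscogError("window_size must be >= 2")
        if not 1 <= self.window_step <= self.window_size:
            raise PrscogError("window_step must lie in [1, window_size]")
        if not 0 < self.r2_max < 1:
            raise PrscogError("r2_max must lie in (0, 1)")


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    Returns 0 when either vector is constant over the complete pairs, or
    when fewer than 3 complete pairs exist (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PrscogError("dosage vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        logger.warning("fewer than 3 complete pairs; treating r2 as 0")
        return 0.0
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    vx = xs @ xs
    vy = ys @ ys
    if vx <= 0 or vy <= 0:
        return 0.0
    cov = xs @ ys
    return float(cov * cov / (vx * vy))


def _banded_r2(dosages: np.ndarray, window: int) -> np.ndarray:
    """Pairwise-complete r2 for all column pairs with index distance < window.

    Returns ``band`` with ``band[i, d-1] = r2(column i, column i+d)`` for
    ``1 <= d < window`` (NaN where ``i+d`` is out of range). Computed in
    overlapping 2*window column chunks so each chunk reduces to a handful of
    matrix products.
    """
    n, m = dosages.shape
    w = min(window, m)
    band = np.full((m, max(w - 1, 1)), np.nan)
    if m < 2:
        return band
    step = w
    for s in range(0, m, step):
        e = min(s + 2 * w, m)
        X = dosages[:, s:e]
        M = (~np.isnan(X)).astype(np.float64)
        Xf = np.where(np.isnan(X), 0.0, X)
        X2 = Xf * Xf
        C = M.T @ M                      # complete-pair counts
        Sx = Xf.T @ M                    # sum of x_i over joint support with j
        Sxx = X2.T @ M
        Sxy = Xf.T @ Xf
        with np.errstate(divide="ignore", invalid="ignore"):
            num = C * Sxy - Sx * Sx.T
            varx = C * Sxx - Sx * Sx
            denom = varx * varx.T
            r2 = np.where(denom > 0, (num * num) / denom, 0.0)
        r2[C < 3] = 0.0
        width = e - s
        for local_i in range(width):
            gi = s + local_i
            if gi + 1 >= m:
                break
            if gi >= s + step and e < m:
                continue  # this row is fully covered by the next chunk
            hi = min(w - 1, width - local_i - 1, m - gi - 1)
            if hi > 0:
                band[gi, :hi] = r2[local_i, local_i + 1 : local_i + 1 + hi]
        if e >= m:
            break
    return band


def _chromosome_segments(ds: GenotypeDataset) -> list[tuple[int, int]]:
    chroms = [chrom_sort_key(c) for c in ds.variants["chrom"]]
    segments = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            segments.append((start, i))
            start = i
    return segments


def prune(ds: GenotypeDataset, params: PruneParams | None = None) -> list[str]:
    """Greedy sliding-window pruning; returns retained variant ids in order.

    Requires variants sorted by (chrom, pos); windows never span
    chromosomes. Within each window, pairs are scanned in (i, j) order; when
    both members of a high-LD pair are still retained, the lower-MAF member
    is removed (tie: the later-positioned one). Windows slide by
    ``window_step``; passes repeat until none removes a variant.
    """
    params = params or PruneParams()
    m = ds.n_variants
    if m == 0:
        return []
    maf = ds.maf()
    retained = np.ones(m, dtype=bool)
    ids = ds.variants["id"].to_numpy()

    for seg_start, seg_end in _chromosome_segments(ds):
        seg_len = seg_end - seg_start
        if seg_len < 2:
            continue
        band = _banded_r2(ds.dosages[:, seg_start:seg_end], params.window_size)
        # pairs exceeding the threshold, as local (i, j) index pairs
        exceed_i, exceed_d = np.nonzero(band > params.r2_max)
        exceed_j = exceed_i + exceed_d + 1
        order = np.lexsort((exceed_j, exceed_i))
        exceed_i, exceed_j = exceed_i[order], exceed_j[order]

        changed = True
        while changed:
            changed = False
            for w_start in range(0, seg_len, params.window_step):
                w_end = min(w_start + params.window_size, seg_len)
                lo = np.searchsorted(exceed_i, w_start, side="left")
                hi = np.searchsorted(exceed_i, w_end, side="left")
                for k in range(lo, hi):
                    i, j = exceed_i[k], exceed_j[k]
                    if j >= w_end:
                        continue
                    gi, gj = seg_start + i, seg_start + j
                    if not (retained[gi] and retained[gj]):
                        continue
                    # drop the lower-MAF member; tie -> later position
                    drop = gi if maf[gi] < maf[gj] else gj
                    retained[drop] = False
                    changed = True
                if w_end >= seg_len:
                    break

    kept = [str(v) for v in ids[retained]]
    logger.info("LD pruning retained %d/%d variants", len(kept), m)
    return kept


def prune_dataset(ds: GenotypeDataset, params: PruneParams | None = None) -> GenotypeDataset:
    """Convenience: apply :func:`prune` and subset the dataset."""
    kept = set(prune(ds, params))
    mask = ds.variants["id"].astype(str).isin(kept).to_numpy()
    return ds.take_variants(mask)
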