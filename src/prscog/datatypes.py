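"""Core in-memory containers shared by every stage of the pipeline.

Genotypes are held as an effect-allele dosage matrix (samples x variants,
float64 with NaN marking missing calls); variant metadata travels alongside
as a DataFrame so that harmonization and pruning can reason about alleles
and genomic order without touching the matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical stroke phenotype labels for the base GWAS summary tables
STROKE_PHENOTYPES = ("ALL_ISCHEMIC", "SVD", "LVD", "CE")

#: canonical GWAS p-value thresholds used to bin SNPs into scores
DEFAULT_P_THRESHOLDS = (0.8, 0.5, 0.1, 0.05, 0.01)

VARIANT_COLUMNS = ("id", "chrom", "pos", "a1", "a2")


class PrscogError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PrscogError):
    """A file does not conform to its declared format."""


class ValidationError(PrscogError):
    """An in-memory object violates a structural invariant."""


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Order chromosomes numerically when possible, lexicographically otherwise."""
    s = str(chrom)
    if re.fullmatch(r"\d+", s):
        return (0, int(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant; ``a1`` is the counted (effect) allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValidationError(f"{self.id}: alleles must differ ({self.a1}/{self.a2})")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position must be >= 1, got {self.pos}")


@dataclass
class GenotypeDataset:
    """Samples x variants matrix of effect-allele dosages.

    Parameters
    ----------
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2``; ``a1`` is the
        allele whose copies the dosage counts.
    samples
        Ordered sample identifiers.
    dosages
        ``(n_samples, n_variants)`` float array with entries in ``{0, 1, 2}``
        or NaN for missing genotype calls.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValidationError(f"variant table lacks columns: {missing_cols}")
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate variant ids: {dups[:5]}")

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Full (O(n*m)) check of dosage values and variant ordering."""
        d = self.dosages
        obs = d[~np.isnan(d)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or NaN")
        keys = [
            (chrom_sort_key(c), p)
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]
        if keys != sorted(keys):
            raise ValidationError("variants are not sorted by (chrom, pos)")
        for rec in self.variant_records():  # allele validity via VariantRecord
            if rec.a1 not in VALID_ALLELES or rec.a2 not in VALID_ALLELES:
                raise ValidationError(f"{rec.id}: non-ACGT allele {rec.a1}/{rec.a2}")

    def variant_records(self) -> Iterator[VariantRecord]:
        for row in self.variants.itertuples(index=False):
            yield VariantRecord(str(row.id), str(row.chrom), int(row.pos), row.a1, row.a2)

    # -- per-variant statistics -------------------------------------------
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted allele ``a1`` among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-variant counts of dosage (0, 1, 2) among non-missing calls."""
        d = self.dosages
        n0 = np.nansum(d == 0.0, axis=0).astype(np.int64)
        n1 = np.nansum(d == 1.0, axis=0).astype(np.int64)
        n2 = np.nansum(d == 2.0, axis=0).astype(np.int64)
        return n0, n1, n2

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            dosages=self.dosages[:, idx].copy(),
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in idx],
            dosages=self.dosages[idx, :].copy(),
        )

    def sort_variants(self) -> "GenotypeDataset":
        order = sorted(
            range(self.n_variants),
            key=lambda i: (
                chrom_sort_key(self.variants["chrom"].iat[i]),
                int(self.variants["pos"].iat[i]),
            ),
        )
        return self.take_variants(order)

    def variant_index(self) -> Mapping[str, int]:
        return {v: i for i, v in enumerate(self.variants["id"])}

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants[list(VARIANT_COLUMNS)].equals(
                other.variants[list(VARIANT_COLUMNS)]
            )
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class SummaryStatTable:
    """Base-GWAS summary statistics for one stroke phenotype.

    ``records`` columns: ``id, a1, a2, beta, p`` where ``a1`` is the effect
    allele and ``beta`` its log-odds effect size.
    """

    phenotype_label: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        for col in ("id", "a1", "a2", "beta", "p"):
            if col not in self.records.columns:
                raise ValidationError(f"summary table lacks column {col!r}")
        p = self.records["p"].to_numpy(dtype=float)
        if len(p) and ((p <= 0) | (p > 1)).any():
            raise ValidationError("summary p-values must lie in (0, 1]")
        if self.records["id"].duplicated().any():
            raise ValidationError("duplicate variant ids in summary table")
        same = self.records["a1"] == self.records["a2"]
        if same.any():
            raise ValidationError("effect allele equals other allele for some records")

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedEffects:
    """Summary effects aligned to a genotype dataset's counted alleles.

    ``table`` columns: ``id, beta, p`` — one row per retained variant, in
    the dataset's variant order; ``beta`` is sign-corrected so it refers to
    the dataset's counted allele. ``report`` gives per-reason drop counts.
    """

    phenotype_label: str
    table: pd.DataFrame
    report: dict[str, int] = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)


@dataclass
class PRSProfile:
    """Per-sample polygenic scores and their nonmissing-SNP counts.

    ``scores`` and ``counts`` share an index of sample ids and columns named
    ``<phenotype>_p<threshold>``.
    """

    scores: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.counts.columns):
            raise ValidationError("score and count columns differ")
        if not self.scores.index.equals(self.counts.index):
            raise ValidationError("score and count sample indices differ")

    @property
    def score_names(self) -> list[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        """Wide table with ``<name>`` score and ``<name>_n`` count columns."""
        out = pd.DataFrame(index=self.scores.index)
        for name in self.scores.columns:
            out[name] = self.scores[name]
            out[f"{name}_n"] = self.counts[name]
        out.index.name = "IID"
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PRSProfile":
        score_cols = [c for c in frame.columns if not c.endswith("_n")]
        scores = frame[score_cols].copy()
        counts = frame[[f"{c}_n" for c in score_cols]].copy()
        counts.columns = score_cols
        return cls(scores=scores, counts=counts)


@dataclass(frozen=True)
class AssociationResult:
    """One partial correlation between a score and a cognitive phenotype."""

    score_name: str
    phenotype_name: str
    r: float
    p: float
    df: int
    n: int
    covariates: tuple[str, ...]
    defined: bool = True


@dataclass(frozen=True)
class MetaStudy:
    """One cohort's contribution to a random-effects meta-analysis."""

    cohort: str
    r: float
    n: int
    k_cov: int = 0

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValidationError(f"{self.cohort}: |r| must be < 1, got {self.r}")
        if self.n - 3 - self.k_cov < 1:
            raise ValidationError(
                f"{self.cohort}: n - 3 - k_cov must be >= 1 "
                f"(n={self.n}, k_cov={self.k_cov})"
            )


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate with heterogeneity diagnostics."""

    omnibus_r: float
    se_z: float
    tau2: float
    Q: float
    p_Q: float
    n_studies: int
    tau2_estimator: str = "DL"
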