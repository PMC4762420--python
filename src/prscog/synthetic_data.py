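"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates three ingredients of the real study design:

* **Target-cohort genotypes** — LD-blocked diploid SNP arrays. Each
  haplotype's alleles within a block come from thresholding an
  exchangeable-correlation multivariate-normal latent at the standard-normal
  quantile of the variant's minor-allele frequency; the two haplotypes are
  independent, so Hardy–Weinberg equilibrium holds marginally at every site.
* **Base-GWAS summary statistics** — a spike-slab architecture of true
  log-odds effects per stroke phenotype, observed with sampling noise whose
  standard error follows the usual ``1/sqrt(2 N p (1-p))`` scaling, then
  emitted with a fraction of records allele-flipped (beta negated) and a
  fraction of variants given strand-ambiguous A/T or G/C allele pairs, so the
  harmonization stage has real work to do.
* **Cohort phenotypes** — a latent cognitive factor with a tunable genetic
  correlation to each stroke liability (positive genetic overlap produces a
  *negative* risk-score/cognition correlation), loading on three fluid
  subtests and one crystallized test, plus age/sex effects, a childhood
  ability score, and a logistic stroke-history indicator.

Every stage draws from its own deterministically derived substream of the
configured seed, so e.g. changing ``flip_fraction`` perturbs only the flip
pattern, never the underlying effect sizes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeDataset,
    STROKE_PHENOTYPES,
    SummaryStatTable,
    ValidationError,
)

_NONAMBIGUOUS_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_AMBIGUOUS_PAIRS = (("A", "T"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort and its base GWAS.

    Defaults describe a large population-based target cohort (n = 5,000)
    scored against a stroke GWAS with the effective sample size of a
    ~12,000-case / ~62,000-control consortium meta-analysis, under a highly
    polygenic (60% causal) architecture whose per-SNP power is deliberately
    weak (non-centrality ~0.8) — the regime in which scores built from more
    SNPs correlate more strongly with the outcome.
    """

    n_samples: int = 5000
    n_snps: int = 10_000
    n_blocks: int = 1000
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 0.6
    h2: float = 0.38
    n_gwas: int = 10_000
    rho_g: Mapping[str, float] = field(
        default_factory=lambda: {"ALL_ISCHEMIC": 0.3, "SVD": 0.2, "LVD": 0.2, "CE": 0.0}
    )
    missing_rate: float = 0.02
    ambiguous_fraction: float = 0.05
    flip_fraction: float = 0.1
    seed: int = 0
    # phenotype-model parameters
    fluid_loadings: tuple[float, ...] = (0.7, 0.65, 0.6)
    crystallized_loading: float = 0.6
    childhood_stability: float = 0.7
    stroke_prevalence: float = 0.03
    stroke_beta: float = 0.3
    age_mean: float = 55.0
    age_sd: float = 11.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples: must be >= 2")
        if self.n_snps < 1 or self.n_blocks < 1 or self.n_snps % self.n_blocks:
            raise ValidationError(
                "n_blocks: n_snps must divide into n_blocks contiguous blocks"
            )
        if not 0 <= self.block_rho < 1:
            raise ValidationError("block_rho: must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range: must satisfy 0 < low <= high <= 0.5")
        for name in ("causal_fraction", "missing_rate", "ambiguous_fraction", "flip_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}: must lie in [0, 1]")
        if not 0 < self.h2 <= 1:
            raise ValidationError("h2: must lie in (0, 1]")
        if self.n_gwas < 1:
            raise ValidationError("n_gwas: must be positive")
        for label, r in self.rho_g.items():
            if not -1 <= r <= 1:
                raise ValidationError(f"rho_g[{label}]: must lie in [-1, 1]")
        if sum(r * r for r in self.rho_g.values()) > 1:
            raise ValidationError("rho_g: sum of squared genetic correlations exceeds 1")
        if not 0 < self.stroke_prevalence < 1:
            raise ValidationError("stroke_prevalence: must lie in (0, 1)")
        for lam in (*self.fluid_loadings, self.crystallized_loading):
            if not 0 < lam < 1:
                raise ValidationError("loadings: must lie in (0, 1)")

    @property
    def block_size(self) -> int:
        return self.n_snps // self.n_blocks

    def phenotype_labels(self) -> tuple[str, ...]:
        return tuple(self.rho_g.keys()) or STROKE_PHENOTYPES


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by (seed, stage label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# shared variant scaffold
# ---------------------------------------------------------------------------

def simulate_variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Variant metadata shared by genotype and summary-stat simulation.

    Columns: ``id chrom pos a1 a2 maf block ambiguous``. ``maf`` is the
    target frequency of the counted allele ``a1`` (kept <= 0.5 so a1 is the
    minor allele by construction).
    """
    rng = _stream(config.seed, "variants")
    m = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    ambiguous = rng.random(m) < config.ambiguous_fraction
    pair_idx = rng.integers(0, 4, size=m)
    amb_idx = rng.integers(0, 2, size=m)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    for j in range(m):
        pair = _AMBIGUOUS_PAIRS[amb_idx[j]] if ambiguous[j] else _NONAMBIGUOUS_PAIRS[pair_idx[j]]
        a1[j], a2[j] = pair
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "a1": a1,
            "a2": a2,
            "maf": mafs,
            "block": np.repeat(np.arange(config.n_blocks), config.block_size),
            "ambiguous": ambiguous,
        }
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """LD-blocked diploid dosages under a latent-Gaussian liability model.

    Within a block each haplotype's latents share exchangeable correlation
    ``block_rho`` (one common factor per haplotype per block); a latent below
    the ``Phi^{-1}(maf)`` quantile codes one copy of the counted allele.
    Missing calls are inserted independently at ``missing_rate``.
    """
    config.validate()
    variants = simulate_variant_table(config)
    rng = _stream(config.seed, "genotypes")
    n, m, bs = config.n_samples, config.n_snps, config.block_size
    rho = config.block_rho
    thresholds = stats.norm.ppf(variants["maf"].to_numpy())

    dosages = np.empty((n, m), dtype=np.float64)
    sq_rho, sq_1mrho = np.sqrt(rho), np.sqrt(1.0 - rho)
    for b in range(config.n_blocks):
        sl = slice(b * bs, (b + 1) * bs)
        block_dos = np.zeros((n, bs), dtype=np.float64)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sq_rho * shared + sq_1mrho * rng.standard_normal((n, bs))
            block_dos += latent < thresholds[sl]
        dosages[:, sl] = block_dos

    if config.missing_rate > 0:
        miss = _stream(config.seed, "missingness").random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    samples = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeDataset(
        variants=variants.drop(columns=["maf", "block", "ambiguous"]),
        samples=samples,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    config: SimulationConfig, truth_out: bool = False
) -> dict[str, SummaryStatTable] | tuple[dict[str, SummaryStatTable], dict[str, np.ndarray]]:
    """Spike-slab true effects observed with GWAS sampling noise.

    For each stroke phenotype, a causal indicator is drawn at
    ``causal_fraction``; causal true betas are normal with variance
    ``h2 / (m_causal * 2 p (1-p))`` so the total liability-scale variance
    explained is ``h2``. Observed betas add noise with standard error
    ``1 / sqrt(2 n_gwas p (1-p))`` and carry the two-sided normal p-value.
    A ``flip_fraction`` subset is emitted with swapped alleles and negated
    beta (the harmonization stage must undo this). With ``truth_out`` the
    unflipped true-effect vectors (aligned to the counted allele ``a1``) are
    returned as well.
    """
    config.validate()
    variants = simulate_variant_table(config)
    mafs = variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * config.n_gwas * mafs * (1.0 - mafs))

    tables: dict[str, SummaryStatTable] = {}
    truths: dict[str, np.ndarray] = {}
    for label in config.phenotype_labels():
        rng_b = _stream(config.seed, f"betas:{label}")
        causal = rng_b.random(config.n_snps) < config.causal_fraction
        m_causal = max(int(causal.sum()), 1)
        sd = np.sqrt(config.h2 / (m_causal * 2.0 * mafs * (1.0 - mafs)))
        true_beta = np.where(causal, rng_b.standard_normal(config.n_snps) * sd, 0.0)

        rng_n = _stream(config.seed, f"gwas-noise:{label}")
        obs_beta = true_beta + rng_n.standard_normal(config.n_snps) * se
        z = obs_beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.finfo(float).tiny, 1.0)

        a1 = variants["a1"].to_numpy().copy()
        a2 = variants["a2"].to_numpy().copy()
        emit_beta = obs_beta.copy()
        if config.flip_fraction > 0:
            flip = _stream(config.seed, f"flips:{label}").random(config.n_snps) < config.flip_fraction
            a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
            emit_beta[flip] = -emit_beta[flip]

        tables[label] = SummaryStatTable(
            phenotype_label=label,
            records=pd.DataFrame(
                {
                    "id": variants["id"],
                    "a1": a1,
                    "a2": a2,
                    "beta": emit_beta,
                    "p": p,
                }
            ),
        )
        truths[label] = true_beta
    if truth_out:
        return tables, truths
    return tables


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    ds: GenotypeDataset,
    truth: Mapping[str, np.ndarray],
    config: SimulationConfig,
    return_latent: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Cognitive battery, demographics and stroke history for one cohort.

    The latent cognitive factor is
    ``g = -sum_k rho_g[k] * std(X beta_k) + sqrt(1 - sum rho^2) * eps``:
    positive genetic correlation with a stroke liability therefore lowers g,
    so a well-recovered risk score correlates *negatively* with cognition.
    Subtests load on g with unique noise; age and sex effects are added so
    the phenotype-construction stage has something to adjust away. Stroke
    history follows a logistic model on the standardized all-phenotype
    genetic risk with intercept set to the target prevalence.

    Returns a table indexed by IID with columns ``age, sex, stroke,
    fluid1..3, crystallized, childhood_score``.
    """
    labels = list(config.rho_g.keys())
    for label in labels:
        if label not in truth:
            raise ValidationError(f"truth lacks effect vector for {label!r}")
        if len(truth[label]) != ds.n_variants:
            raise ValidationError(
                f"truth[{label!r}] has {len(truth[label])} effects for "
                f"{ds.n_variants} variants"
            )
    rng = _stream(config.seed, "phenotypes")
    n = ds.n_samples

    # latent genetic values from mean-imputed dosages (the generator's own
    # latent; downstream scoring never imputes)
    X = ds.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    genetic_scores = {k: _standardize(X @ np.asarray(truth[k], dtype=float)) for k in labels}
    rho2 = sum(config.rho_g[k] ** 2 for k in labels)
    g = -sum(config.rho_g[k] * genetic_scores[k] for k in labels)
    g = g + np.sqrt(max(0.0, 1.0 - rho2)) * rng.standard_normal(n)

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 18.0, 100.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    z_age = _standardize(age)

    def subtest(loading: float, age_eff: float, sex_eff: float) -> np.ndarray:
        unique = np.sqrt(1.0 - loading**2) * rng.standard_normal(n)
        return loading * g + unique + age_eff * z_age + sex_eff * sex

    fluid = {
        f"fluid{i + 1}": subtest(lam, age_eff=-0.3, sex_eff=0.1)
        for i, lam in enumerate(config.fluid_loadings)
    }
    crystallized = subtest(config.crystallized_loading, age_eff=0.1, sex_eff=0.1)

    stab = config.childhood_stability
    childhood = stab * g + np.sqrt(1.0 - stab**2) * rng.standard_normal(n)

    # stroke risk from the combined genetic liability (equal weights over
    # phenotypes with nonzero overlap), prevalence pinned via the intercept
    risk = sum(genetic_scores[k] for k in labels)
    risk = _standardize(np.asarray(risk, dtype=float))
    intercept = np.log(config.stroke_prevalence / (1.0 - config.stroke_prevalence))
    p_stroke = 1.0 / (1.0 + np.exp(-(intercept + config.stroke_beta * risk)))
    stroke = rng.random(n) < p_stroke

    out = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "stroke": stroke,
            **fluid,
            "crystallized": crystallized,
            "childhood_score": childhood,
        },
        index=pd.Index(ds.samples, name="IID"),
    )
    if return_latent:
        return out, g
    return out


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig):
    """Generate genotypes, summary tables, true effects and phenotypes.

    Returns ``(GenotypeDataset, {label: SummaryStatTable}, {label: true
    betas}, phenotype DataFrame)``, all mutually consistent.
    """
    ds = simulate_genotypes(config)
    tables, truth = simulate_summary_stats(config, truth_out=True)
    pheno = simulate_phenotypes(ds, truth, config)
    return ds, tables, truth, pheno


def unflipped_config(config: SimulationConfig) -> SimulationConfig:
    """The same study with ``flip_fraction = 0`` (identical effect draws)."""
    return replace(config, flip_fraction=0.0)
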