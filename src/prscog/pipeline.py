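"""End-to-end orchestration: simulate/ingest -> QC -> prune -> score ->
structure -> phenotypes -> association -> meta-analysis.

The per-cohort stage order follows the scoring recipe: variant QC on the
cohort, then restriction to variants that can enter a score (present in the
base GWAS, non-ambiguous, common enough), LD pruning once on that set, and
per-phenotype harmonization and threshold-binned scoring on the pruned
variants. MDS components are computed from the pruned set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .association import run_association_grid
from .datatypes import DEFAULT_P_THRESHOLDS, GenotypeDataset, PRSProfile
from .ld_pruning import PruneParams, prune_dataset
from .meta_analysis import run_meta_grid
from .phenotype_model import CognitivePhenotypes, build_cognitive_phenotypes
from .population_structure import StructureComponents, mds_components
from .prs_scoring import compute_all_scores
from .synthetic_data import SimulationConfig, simulate_cohort
from .variant_qc import QCThresholds, apply_variant_qc, harmonization_prefilter, harmonize

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """Everything the pipeline derives for one cohort."""

    label: str
    profile: PRSProfile
    mds: StructureComponents
    cognitive: CognitivePhenotypes
    associations: pd.DataFrame
    n_variants_qc: int
    n_variants_pruned: int


@dataclass
class PipelineOptions:
    qc: QCThresholds = field(default_factory=QCThresholds)
    prune: PruneParams = field(default_factory=PruneParams)
    thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS
    mds_k: int = 4
    mds_max_variants: int | None = 2000
    exclude_stroke: bool = True
    adjust: str = "none"


def analyze_cohort(
    label: str,
    ds: GenotypeDataset,
    stats_tables: dict,
    pheno: pd.DataFrame,
    options: PipelineOptions | None = None,
    mds_seed: int = 0,
) -> CohortResult:
    """Run the per-cohort analysis on already-loaded inputs."""
    options = options or PipelineOptions()
    ds_qc, _report = apply_variant_qc(ds, options.qc)
    scoreable = harmonization_prefilter(ds_qc, stats_tables, options.qc)
    pruned = prune_dataset(scoreable, options.prune)
    logger.info(
        "%s: %d variants post-QC, %d scoreable, %d after pruning",
        label, ds_qc.n_variants, scoreable.n_variants, pruned.n_variants,
    )
    effects = {lab: harmonize(pruned, t, options.qc) for lab, t in stats_tables.items()}
    profile = compute_all_scores(pruned, effects, options.thresholds, options.qc)
    mds = mds_components(
        pruned, k=options.mds_k, max_variants=options.mds_max_variants, seed=mds_seed
    )
    cognitive = build_cognitive_phenotypes(pheno)
    assoc = run_association_grid(
        profile,
        cognitive,
        mds,
        stroke=pheno["stroke"],
        exclude_stroke=options.exclude_stroke,
        adjust=options.adjust,
    )
    return CohortResult(
        label=label,
        profile=profile,
        mds=mds,
        cognitive=cognitive,
        associations=assoc,
        n_variants_qc=ds_qc.n_variants,
        n_variants_pruned=pruned.n_variants,
    )


def run_synthetic_cohort(
    config: SimulationConfig,
    label: str = "cohort",
    options: PipelineOptions | None = None,
) -> CohortResult:
    """Simulate one cohort and run the full per-cohort analysis."""
    ds, tables, _truth, pheno = simulate_cohort(config)
    return analyze_cohort(
        label, ds, tables, pheno, options=options, mds_seed=config.seed
    )


def run_study(
    cohort_configs: dict[str, SimulationConfig],
    options: PipelineOptions | None = None,
) -> tuple[dict[str, CohortResult], pd.DataFrame]:
    """Per-cohort analyses plus the cross-cohort random-effects meta-analysis.

    Returns the cohort results and the 20-score x 3-phenotype meta table
    (gf, general, crystallized).
    """
    results = {
        label: run_synthetic_cohort(cfg, label=label, options=options)
        for label, cfg in cohort_configs.items()
    }
    tables = {label: res.associations for label, res in results.items()}
    # meta phenotypes resolved per cohort through the cognitive construction
    roles: dict[str, dict[str, str]] = {}
    for role in ("gf", "general", "crystallized"):
        roles[role] = {
            label: res.cognitive.meta_phenotypes[role] for label, res in results.items()
        }
    meta = run_meta_grid(tables, phenotypes=roles)
    return results, meta
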