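"""End-to-end orchestration: simulate -> count -> profile -> markers -> stats.

`run_pipeline` exercises the whole chain on a synthetic world and returns
every intermediate plus the cohort association block: the ImP-richness
partial correlation, the ImP x glycemic-status comparison, functional-urdA
enrichment in the low-richness Bacteroides-like enterotype, and the
(planted-null) ImP-histidine association, BH-FDR adjusted as one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import foods
from .community_profile import (
    DMMModel,
    EnterotypeAssignment,
    assign_enterotypes,
    collapse_to_genus,
    compute_mgs_abundance,
    fit_dmm,
    select_n_components,
)
from .gene_quant import (
    GeneCountTable,
    GeneQuantConfig,
    classify_gene_count,
    compute_gene_richness,
    downsize_counts,
    fpkm_normalize,
    map_reads,
    richness_bimodal_threshold,
    smart_shared_count,
)
from .marker_quant import (
    MarkerQuantConfig,
    build_active_site_window,
    build_marker_table,
    quantify_hutH,
    quantify_window_reads,
)
from .synthetic_data import SyntheticWorld, SyntheticWorldConfig, simulate_cohort_truth, simulate_reads

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Problem sizes and knobs of one full synthetic-cohort run."""

    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    gene_quant: GeneQuantConfig = field(default_factory=GeneQuantConfig)
    markers: MarkerQuantConfig = field(default_factory=MarkerQuantConfig)
    k_enterotypes: int | None = 3  # None = BIC selection over k_range
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    dmm_restarts: int = 3
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        # rarefaction depth defaults to 90% of the simulated read depth
        if self.gene_quant.downsize_depth == GeneQuantConfig().downsize_depth:
            self.gene_quant.downsize_depth = max(1, int(0.9 * self.world.read_depth))


@dataclass
class PipelineResult:
    world: SyntheticWorld
    raw_counts: GeneCountTable
    richness: pd.Series
    richness_threshold: float
    gene_count_class: pd.Series
    fpkm: GeneCountTable
    mgs_abundance: pd.DataFrame
    genus_counts: pd.DataFrame
    dmm_model: DMMModel
    enterotypes: EnterotypeAssignment
    marker_table: pd.DataFrame
    cohort: pd.DataFrame
    associations: pd.DataFrame
    odds_ratios: dict
    exclusions: cs.ExclusionAccounting | None


def _default_exclusion_rules(alpha: float = 0.05):
    """The three-stage cohort exclusion: non-metabolic CVD etiology, Grubbs
    ImP outliers (on the log scale), incomplete biochemistry."""

    def rule_cvd(df):
        return df["cvd_nonmetabolic"].fillna(False).astype(bool)

    def rule_grubbs(df):
        flagged = cs.grubbs_outliers(np.log(df["imp"].to_numpy()), alpha=alpha)
        mask = pd.Series(False, index=df.index)
        mask.iloc[flagged] = True
        return mask

    def rule_incomplete(df):
        return df[["glucose", "insulin", "hba1c"]].isna().any(axis=1)

    return [
        ("non_metabolic_cvd", rule_cvd),
        ("imp_grubbs_outlier", rule_grubbs),
        ("incomplete_biochemistry", rule_incomplete),
    ]


def run_pipeline(config: PipelineConfig | None = None, progress: bool = False) -> PipelineResult:
    cfg = config or PipelineConfig()
    wcfg = cfg.world

    def log(msg):
        if progress:
            print(f"[imppipe] {msg}", flush=True)

    log(f"simulating world: {wcfg.n_subjects} subjects, {wcfg.n_genes} genes")
    world = simulate_cohort_truth(wcfg)

    log(f"simulating + mapping reads at depth {wcfg.read_depth}")
    mappings = {}
    window_counts = {}
    depths = {}
    windows = [build_active_site_window(r, cfg.markers.window_nt) for r in world.urda_refs]
    for i, subject in enumerate(world.subjects):
        reads = simulate_reads(world, subject, wcfg.read_depth, seed=wcfg.seed + 100_000 + i)
        mappings[subject] = map_reads(reads, world.catalog, cfg.gene_quant)
        window_counts[subject] = quantify_window_reads(reads, windows, cfg.markers)
        depths[subject] = len(reads)
        if progress and (i + 1) % 100 == 0:
            log(f"  {i + 1}/{len(world.subjects)} subjects")

    log("counting (smart shared), rarefying, normalizing")
    raw = smart_shared_count(mappings, world.catalog.ids)
    depth = cfg.gene_quant.downsize_depth
    n_reps = cfg.gene_quant.n_rarefactions
    rich = compute_gene_richness(raw, depth, n_reps, seed=cfg.seed + 1)
    down = downsize_counts(raw, depth, n_reps, seed=cfg.seed + 2)
    fpkm = fpkm_normalize(down, world.catalog)

    healthy = world.truth["diabetes_status"] == "healthy"
    healthy_rich = rich.richness.loc[rich.richness.index.intersection(world.truth.index[healthy])]
    if cfg.gene_quant.richness_threshold is not None:
        threshold = cfg.gene_quant.richness_threshold
    else:
        threshold = richness_bimodal_threshold(healthy_rich, seed=cfg.seed)
    gc_class = classify_gene_count(rich.richness, threshold)

    log("profiling community (MGS, genus, DMM enterotypes)")
    mgs_ab = compute_mgs_abundance(fpkm.data, world.mgs_defs)
    genus_counts = collapse_to_genus(mgs_ab, world.mgs_defs)
    if cfg.k_enterotypes is not None:
        K = cfg.k_enterotypes
    else:
        K = select_n_components(genus_counts, cfg.k_range, seed=cfg.seed,
                                n_init=cfg.dmm_restarts)
    model = fit_dmm(genus_counts, K, seed=cfg.seed, n_init=cfg.dmm_restarts)
    enterotypes = assign_enterotypes(model, genus_counts, richness=rich.richness)

    log("quantifying histidine-utilization markers")
    hutH = quantify_hutH(fpkm, world.ko_annotation, cfg.markers)
    marker_table = build_marker_table(window_counts, depths, hutH)

    log("assembling cohort table and statistics")
    cohort = world.cohort_table()
    cohort = cohort.join(rich.richness.rename("gene_richness"))
    cohort = cohort.join(gc_class.rename("gene_count_class"))
    cohort = cohort.join(enterotypes.labels)
    b2 = enterotypes.bacteroides2_analog
    cohort["bacteroides2"] = (
        (enterotypes.labels == b2) if b2 is not None else False
    )
    cohort = cohort.join(marker_table[["true_urda_rpm", "false_urda_rpm", "hutH_fpkm"]])
    cohort = cohort.join(world.nutrition[["energy_kcal", "histidine_g", "bmr_kcal"]])
    idx = cs.derive_indices(cohort)
    cohort = cohort.join(idx)

    exclusions = None
    kept = cohort
    kept, exclusions = cs.apply_cohort_exclusions(cohort, _default_exclusion_rules())

    # log-transform ImP per the skewness policy
    imp_tr = cs.log_transform_policy(kept["imp"].to_numpy())
    kept = kept.assign(imp_model=imp_tr.values)

    covs1 = cs.design_matrix(kept, cs.MODEL_COVARIATES[1])
    rows = []
    r_rich = cs.partial_correlation(kept["imp_model"], kept["gene_richness"], covs1)
    rows.append(("imp_vs_richness", "partial_r", r_rich))
    g_cmp = cs.linear_group_comparison(kept["imp_model"], kept["diabetes_status"], covs1)
    rows.append(("imp_vs_status", "beta_t2d", g_cmp))
    urda_ok = kept["true_urda_rpm"].notna()
    u_cmp = cs.partial_correlation(
        kept.loc[urda_ok, "true_urda_rpm"],
        kept.loc[urda_ok, "bacteroides2"].astype(float),
        covs1.loc[urda_ok],
        method="spearman",
    )
    rows.append(("true_urda_vs_bacteroides2", "partial_rho", u_cmp))
    covs_nut = pd.concat([covs1, kept["energy_kcal"]], axis=1)
    h_cmp = cs.partial_correlation(kept["imp_model"], kept["histidine_g"], covs_nut)
    rows.append(("imp_vs_histidine", "partial_r", h_cmp))

    qvals = cs.bh_fdr([r.p for _, _, r in rows])
    table = pd.DataFrame(
        {
            "block": "primary_associations",
            "contrast": [name for name, _, _ in rows],
            "kind": [kind for _, kind, _ in rows],
            "estimate": [r.estimate for _, _, r in rows],
            "ci_low": [r.ci_low for _, _, r in rows],
            "ci_high": [r.ci_high for _, _, r in rows],
            "p": [r.p for _, _, r in rows],
            "q": qvals,
            "n": [r.n for _, _, r in rows],
        }
    ).set_index("contrast")

    quart = cs.quartile_stratify(kept["imp"])
    odds = cs.fit_multinomial_or(kept["diabetes_status"], quart, covs1)

    return PipelineResult(
        world=world,
        raw_counts=raw,
        richness=rich.richness,
        richness_threshold=threshold,
        gene_count_class=gc_class,
        fpkm=fpkm,
        mgs_abundance=mgs_ab,
        genus_counts=genus_counts,
        dmm_model=model,
        enterotypes=enterotypes,
        marker_table=marker_table,
        cohort=kept,
        associations=table,
        odds_ratios=odds,
        exclusions=exclusions,
    )
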