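"""Synthetic cohort generator: every input the pipeline consumes.

Builds a desk-scale analog of a shotgun-metagenome cohort study of the
microbial histidine -> urocanate -> imidazole propionate (ImP) route: a
nucleotide gene catalog with metagenomic-species (MGS) marker panels,
urocanate-reductase (urdA) reference homologs with annotated FAD active
sites, single-end read sets drawn from planted per-subject gene-abundance
profiles, and a clinical + nutrition table with planted effect structure —
higher ImP with worsening glycemic status, a negative ImP-richness slope, a
low-richness Bacteroides-dominated community type enriched for functional
urdA, and (by default) histidine intake independent of ImP.

Every generator is a pure function of (config, seed). All clinical and
dietary distributions are scenario choices declared in the config, not
inferences about any real cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq, foods
from .community_profile import MGSDefinition, mgs_definitions_to_tsv
from .gene_quant import GeneCatalog, ReadSet
from .marker_quant import UrdaReference, write_urda_references

__all__ = [
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "GENUS_NAMES",
    "generate_gene_catalog",
    "generate_mgs_definitions",
    "generate_urda_reference_set",
    "simulate_cohort_truth",
    "simulate_reads",
    "write_world",
]

GENUS_NAMES = [
    "Bacteroides",
    "Prevotella",
    "Faecalibacterium",
    "Ruminococcus",
    "Bifidobacterium",
    "Roseburia",
    "Alistipes",
    "Akkermansia",
    "Eubacterium",
    "Blautia",
    "Dorea",
    "Coprococcus",
]

GROUPS = ("healthy", "prediabetes", "type2diabetes")

# one unambiguous codon per amino acid for back-translation (no stops)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_AMINO = "".join(sorted(_CODON))
_CLASSIFY_POS = 373  # 1-based protein residue that decides urdA activity


def _default_alphas(n_genera: int) -> np.ndarray:
    """Three community types: Prevotella-led, Firmicutes-led, and a
    concentrated Bacteroides-dominated type (the low-richness analog)."""
    if n_genera < 7:
        raise ValueError("default enterotype alphas need at least 7 genera")
    a = np.full((3, n_genera), 0.8)
    a[0, 1] = 10.0  # Prevotella
    a[0, 3] = 2.0
    a[1] = 1.0
    a[1, 2] = 6.0  # Faecalibacterium
    a[1, 5] = 3.0
    a[1, 3] = 3.0
    a[2] = 0.3
    a[2, 0] = 12.0  # Bacteroides, concentrated -> low diversity
    a[2, 6] = 1.0
    return a


@dataclass
class SyntheticWorldConfig:
    """Scenario configuration for the synthetic cohort.

    ImP is generated on the natural-log nM scale:
    log ImP = baseline + group shift + beta_richness * z(richness)
            + beta_urdA * urdA burden + noise, noise ~ N(0, noise_sd)
    truncated at 4 SD. The three enterotypes get their own genus Dirichlet
    parameters, gene-retention level (the richness plant) and functional-urdA
    carriage probability.
    """

    n_subjects: int = 500
    group_props: tuple[float, ...] = (0.4, 0.3, 0.3)
    n_genes: int = 4000
    gene_length_range: tuple[int, int] = (300, 1200)
    n_mgs: int = 40
    mgs_size: int = 50
    markers_per_mgs: int = 50
    n_genera: int = 12
    dmm_alphas: np.ndarray | None = None
    enterotype_weights: tuple[float, ...] = (0.35, 0.35, 0.30)
    gene_retention_by_enterotype: tuple[float, ...] = (0.88, 0.82, 0.55)
    retention_concentration: float = 60.0
    background_mass: float = 0.15
    urda_prevalence_by_enterotype: tuple[float, ...] = (0.25, 0.25, 0.80)
    n_urda_true: int = 3
    n_urda_false: int = 3
    urda_protein_length: int = 450
    urda_read_frac: float = 0.004
    false_urda_read_frac: float = 0.004
    imp_baseline_log: float = 3.4  # log nM, about 30 nM
    imp_group_shift_log: tuple[float, ...] = (0.0, 0.3, 0.5)
    imp_richness_beta: float = -0.3
    imp_urda_beta: float = 0.25
    noise_sd: float = 0.3
    histidine_imp_beta: float = 0.0
    huth_gene_frac: float = 0.02
    read_depth: int = 50_000
    read_length: int = 150
    error_rate: float = 0.002
    n_nonmetabolic_cvd: int = 0
    n_imp_outliers: int = 0
    n_incomplete_biochem: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.dmm_alphas is None:
            self.dmm_alphas = _default_alphas(self.n_genera)
        self.dmm_alphas = np.asarray(self.dmm_alphas, dtype=float)
        if abs(sum(self.group_props) - 1) > 1e-9:
            raise ValueError("group_props must sum to 1")
        if abs(sum(self.enterotype_weights) - 1) > 1e-9:
            raise ValueError("enterotype_weights must sum to 1")
        if np.any(self.dmm_alphas <= 0):
            raise ValueError("Dirichlet parameters must be positive")
        if self.dmm_alphas.shape != (len(self.enterotype_weights), self.n_genera):
            raise ValueError("dmm_alphas must be (n_enterotypes, n_genera)")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["dmm_alphas"] = self.dmm_alphas.tolist()
        return json.dumps(d, indent=2)


def generate_gene_catalog(
    n_genes: int, length_range: tuple[int, int], seed: int
) -> GeneCatalog:
    """Random A/C/G/T gene catalog with lengths uniform in length_range."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 150:
        raise ValueError("gene lengths must be >= 150 nt")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = [
        bases[rng.integers(0, 4, size=int(L))].tobytes().decode("ascii") for L in lengths
    ]
    ids = [f"gene_{i:06d}" for i in range(n_genes)]
    return GeneCatalog(ids, seqs)


def generate_mgs_definitions(
    catalog: GeneCatalog,
    n_mgs: int,
    genes_per_mgs: int,
    n_markers: int,
    seed: int,
    n_genera: int = 12,
    genus_labels: list[str] | None = None,
) -> list[MGSDefinition]:
    """Disjoint MGS memberships over the catalog, each with an n_markers
    marker panel and a genus label (round-robin over the label set)."""
    if n_mgs * genes_per_mgs > len(catalog):
        raise ValueError(
            f"catalog of {len(catalog)} genes cannot host {n_mgs} x {genes_per_mgs} members"
        )
    if n_markers > genes_per_mgs:
        raise ValueError("n_markers cannot exceed genes_per_mgs")
    if genus_labels is None:
        genus_labels = (
            GENUS_NAMES[:n_genera]
            if n_genera <= len(GENUS_NAMES)
            else GENUS_NAMES + [f"genus_{i:02d}" for i in range(len(GENUS_NAMES), n_genera)]
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(catalog))
    defs = []
    for i in range(n_mgs):
        block = perm[i * genes_per_mgs : (i + 1) * genes_per_mgs]
        members = [catalog.ids[j] for j in block]
        defs.append(
            MGSDefinition(
                mgs_id=f"mgs_{i:03d}",
                member_genes=members,
                marker_genes=members[:n_markers],
                genus=genus_labels[i % len(genus_labels)],
            )
        )
    return defs


def generate_urda_reference_set(
    n_true: int, n_false: int, protein_length: int, seed: int
) -> list[UrdaReference]:
    """urdA homolog references with a controlled residue at position 373.

    False urocanate reductases carry histidine (H) at 1-based protein
    position 373; true ones carry a non-H residue. The nucleotide gene is a
    gap-free back-translation (3 x protein_length nt) and the annotated FAD
    active-site span covers codons 371-375 (clipped), hence codon 373.
    """
    if protein_length < _CLASSIFY_POS:
        raise ValueError(f"protein_length must be >= {_CLASSIFY_POS}")
    rng = np.random.default_rng(seed)
    non_h = _AMINO.replace("H", "")
    refs = []
    for i in range(n_true + n_false):
        is_true = i < n_true
        aa = [_AMINO[j] for j in rng.integers(0, len(_AMINO), size=protein_length)]
        aa[_CLASSIFY_POS - 1] = (
            non_h[int(rng.integers(0, len(non_h)))] if is_true else "H"
        )
        protein = "".join(aa)
        nt = "".join(_CODON[a] for a in protein)
        span = (3 * (_CLASSIFY_POS - 3) + 1, 3 * min(_CLASSIFY_POS + 2, protein_length))
        label = "true" if is_true else "false"
        idx = i if is_true else i - n_true
        refs.append(
            UrdaReference(
                id=f"urda_{label}_{idx:02d}",
                sequence=nt,
                protein=protein,
                active_site_span=span,
            )
        )
    return refs


@dataclass
class SyntheticWorld:
    """All generated inputs plus the per-subject ground truth."""

    config: SyntheticWorldConfig
    catalog: GeneCatalog
    mgs_defs: list[MGSDefinition]
    urda_refs: list[UrdaReference]
    ko_annotation: dict[str, str]
    truth: pd.DataFrame
    gene_abundance: pd.DataFrame
    nutrition: pd.DataFrame

    def __post_init__(self):
        catalog_ids = set(self.catalog.ids)
        for d in self.mgs_defs:
            if not set(d.marker_genes) <= catalog_ids:
                raise ValueError(f"{d.mgs_id}: marker genes missing from catalog")
        sums = self.gene_abundance.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-subject gene abundances must sum to 1")

    @property
    def subjects(self) -> list[str]:
        return list(self.truth.index)

    def cohort_table(self) -> pd.DataFrame:
        """The observable clinical table (planted truth columns removed)."""
        hidden = [
            c
            for c in (
                "enterotype_true",
                "richness_true",
                "retention",
                "urda_carrier",
                "urda_frac",
                "false_urda_frac",
                "urda_burden",
                "log_imp",
            )
            if c in self.truth.columns
        ]
        return self.truth.drop(columns=hidden)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_cohort_truth(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world (no reads; see simulate_reads)."""
    cfg = config
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=8)

    catalog = generate_gene_catalog(cfg.n_genes, cfg.gene_length_range, int(seeds[0]))
    mgs_defs = generate_mgs_definitions(
        catalog,
        cfg.n_mgs,
        cfg.mgs_size,
        cfg.markers_per_mgs,
        int(seeds[1]),
        n_genera=cfg.n_genera,
    )
    urda_refs = generate_urda_reference_set(
        cfg.n_urda_true, cfg.n_urda_false, cfg.urda_protein_length, int(seeds[2])
    )

    rng = np.random.default_rng(int(seeds[3]))

    # KO annotation: a fraction of MGS member genes carry hutH (K01745)
    member_genes = [g for d in mgs_defs for g in d.member_genes]
    n_huth = max(1, int(round(cfg.huth_gene_frac * len(member_genes))))
    huth_genes = rng.choice(member_genes, size=n_huth, replace=False)
    ko_annotation = {g: "K01745" for g in huth_genes}

    n = cfg.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    K = len(cfg.enterotype_weights)
    # genus index used by the Dirichlet draws must match the label order
    # used when spreading mass to MGS
    label_list = (
        GENUS_NAMES[: cfg.n_genera]
        if cfg.n_genera <= len(GENUS_NAMES)
        else GENUS_NAMES + [f"genus_{i:02d}" for i in range(len(GENUS_NAMES), cfg.n_genera)]
    )
    mgs_by_genus = {g: [d for d in mgs_defs if d.genus == g] for g in label_list}
    gene_idx = {g: i for i, g in enumerate(catalog.ids)}
    mgs_member_idx = {
        d.mgs_id: np.array([gene_idx[g] for g in d.member_genes]) for d in mgs_defs
    }
    background_idx = np.array(
        sorted(set(range(len(catalog))) - {i for d in mgs_defs for i in mgs_member_idx[d.mgs_id]})
    )

    group = rng.choice(len(GROUPS), size=n, p=cfg.group_props)
    enterotype = rng.choice(K, size=n, p=cfg.enterotype_weights)

    abundance = np.zeros((n, len(catalog)))
    retention = np.empty(n)
    conc = cfg.retention_concentration
    for s in range(n):
        et = enterotype[s]
        m = cfg.gene_retention_by_enterotype[et]
        f = rng.beta(m * conc, (1 - m) * conc)
        retention[s] = f
        genus_prop = rng.dirichlet(cfg.dmm_alphas[et])
        v = np.zeros(len(catalog))
        for j, g in enumerate(label_list):
            mgs_list = mgs_by_genus[g]
            if not mgs_list:
                continue
            w_mgs = rng.gamma(1.0, size=len(mgs_list))
            w_mgs /= w_mgs.sum()
            for d, wm in zip(mgs_list, w_mgs):
                idx = mgs_member_idx[d.mgs_id]
                w = rng.gamma(1.0, size=idx.size) * (rng.random(idx.size) < f)
                tot = w.sum()
                if tot > 0:
                    v[idx] += genus_prop[j] * wm * (w / tot)
        v *= 1.0 - cfg.background_mass
        wb = rng.gamma(1.0, size=background_idx.size) * (
            rng.random(background_idx.size) < f
        )
        if wb.sum() > 0:
            v[background_idx] += cfg.background_mass * wb / wb.sum()
        v /= v.sum()
        abundance[s] = v

    richness_true = (abundance > 0).sum(axis=1).astype(float)
    z_rich = (richness_true - richness_true.mean()) / richness_true.std()

    prev = np.asarray(cfg.urda_prevalence_by_enterotype)
    carrier = rng.random(n) < prev[enterotype]
    burden = np.where(carrier, rng.lognormal(0.0, 0.3, size=n), 0.0)
    urda_frac = cfg.urda_read_frac * burden
    false_frac = cfg.false_urda_read_frac * rng.lognormal(0.0, 0.3, size=n)

    shifts = np.asarray(cfg.imp_group_shift_log)[group]
    noise = np.clip(
        rng.normal(0.0, cfg.noise_sd, size=n), -4 * cfg.noise_sd, 4 * cfg.noise_sd
    )
    log_imp = (
        cfg.imp_baseline_log
        + shifts
        + cfg.imp_richness_beta * z_rich
        + cfg.imp_urda_beta * burden
        + noise
    )

    # clinical covariates (scenario distributions, truncated to plausibility)
    age_mean = np.array([54.0, 58.0, 61.0])[group]
    age = _truncated_normal(rng, age_mean, 9.0, 18, 85, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    ethnicity = rng.choice(
        ["european", "middle_eastern", "other"], size=n, p=[0.8, 0.12, 0.08]
    )
    bmi = _truncated_normal(rng, np.array([26.0, 29.5, 31.0])[group], 4.5, 16, 60, n)
    height = np.where(
        sex == "female",
        _truncated_normal(rng, 164.0, 6.0, 140, 200, n),
        _truncated_normal(rng, 177.0, 7.0, 150, 210, n),
    )
    weight = bmi * (height / 100.0) ** 2
    glucose = _truncated_normal(
        rng, np.array([5.1, 6.0, 8.2])[group], np.array([0.4, 0.5, 1.8])[group], 3, 25, n
    )
    insulin = rng.lognormal(np.log(np.array([7.0, 10.0, 13.0]))[group], 0.4, size=n)
    hba1c = _truncated_normal(
        rng, np.array([5.3, 5.9, 7.3])[group], np.array([0.3, 0.3, 1.0])[group], 4, 14, n
    )
    triglycerides = rng.lognormal(np.log(np.array([1.1, 1.4, 1.8]))[group], 0.35, size=n)
    glucose_120 = np.clip(
        glucose * 1.2 + np.array([0.5, 1.5, 4.0])[group] + rng.normal(0, 1.0, n), 3, 30
    )
    insulin_120 = insulin * rng.lognormal(np.log(4.0), 0.3, size=n)
    cpeptide_120 = rng.lognormal(np.log(2.5) + 0.1 * group, 0.3, size=n)
    creatinine_clearance = _truncated_normal(
        rng, 105.0 - 0.5 * (age - 55.0), 18.0, 20, 200, n
    )
    serum_creatinine = rng.lognormal(np.log(0.9), 0.15, size=n)
    metformin = (group == 2) & (rng.random(n) < 0.65)
    cvd = rng.random(n) < 0.25

    truth = pd.DataFrame(
        {
            "diabetes_status": np.array(GROUPS)[group],
            "enterotype_true": enterotype + 1,
            "richness_true": richness_true,
            "retention": retention,
            "urda_carrier": carrier,
            "urda_burden": burden,
            "urda_frac": urda_frac,
            "false_urda_frac": false_frac,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "bmi": bmi,
            "height": height,
            "weight": weight,
            "creatinine_clearance": creatinine_clearance,
            "serum_creatinine": serum_creatinine,
            "glucose": glucose,
            "insulin": insulin,
            "hba1c": hba1c,
            "triglycerides": triglycerides,
            "glucose_120": glucose_120,
            "insulin_120": insulin_120,
            "cpeptide_120": cpeptide_120,
            "metformin": metformin,
            "cvd": cvd,
            "cvd_nonmetabolic": False,
            "log_imp": log_imp,
        },
        index=pd.Index(subjects, name="subject_id"),
    )

    # planted exclusions: disjoint subject sets, in rule order
    n_planted = cfg.n_nonmetabolic_cvd + cfg.n_imp_outliers + cfg.n_incomplete_biochem
    if n_planted > 0:
        if n_planted > n:
            raise ValueError("more planted exclusions than subjects")
        chosen = rng.choice(n, size=n_planted, replace=False)
        cvd_ix = chosen[: cfg.n_nonmetabolic_cvd]
        out_ix = chosen[cfg.n_nonmetabolic_cvd : cfg.n_nonmetabolic_cvd + cfg.n_imp_outliers]
        inc_ix = chosen[cfg.n_nonmetabolic_cvd + cfg.n_imp_outliers :]
        truth.iloc[cvd_ix, truth.columns.get_loc("cvd_nonmetabolic")] = True
        truth.iloc[out_ix, truth.columns.get_loc("log_imp")] = cfg.imp_baseline_log + 6.0
        for col in ("glucose", "insulin", "hba1c"):
            truth.iloc[inc_ix, truth.columns.get_loc(col)] = np.nan
    truth["imp"] = np.exp(truth["log_imp"])

    # nutrition: intakes scaled so declared energy ~ appetite x 1.6 BMR
    bmr = np.array(
        [
            harris_benedict(sex[i], weight[i], height[i], age[i])
            for i in range(n)
        ]
    )
    base = foods.TYPICAL_INTAKE_G.to_numpy() * rng.lognormal(
        0.0, 0.4, size=(n, len(foods.GROUP_NAMES))
    )
    energy_raw = base @ foods.KCAL_PER_G.to_numpy()
    appetite = rng.lognormal(0.0, 0.25, size=n)
    intakes = base * (1.6 * bmr * appetite / energy_raw)[:, None]
    if cfg.histidine_imp_beta != 0.0:
        z_imp = (log_imp - log_imp.mean()) / log_imp.std()
        protein_rich = [
            foods.GROUP_NAMES.index(g)
            for g in ("red_meat", "processed_meat", "poultry", "fish_white",
                      "fish_fatty", "cheese", "eggs")
        ]
        intakes[:, protein_rich] *= np.exp(cfg.histidine_imp_beta * z_imp)[:, None]
    nutrition = pd.DataFrame(intakes, index=truth.index, columns=foods.GROUP_NAMES)
    nutrition["energy_kcal"] = intakes @ foods.KCAL_PER_G.to_numpy()
    nutrition["histidine_g"] = (
        intakes @ foods.HISTIDINE_MG_PER_G.to_numpy()
    ) / 1000.0
    nutrition["bmr_kcal"] = bmr

    gene_abundance = pd.DataFrame(abundance, index=truth.index, columns=catalog.ids)
    return SyntheticWorld(
        config=cfg,
        catalog=catalog,
        mgs_defs=mgs_defs,
        urda_refs=urda_refs,
        ko_annotation=ko_annotation,
        truth=truth,
        gene_abundance=gene_abundance,
        nutrition=nutrition,
    )


def harris_benedict(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    # local import to keep module deps one-way (cohort_stats owns the formula)
    from .cohort_stats import harris_benedict_bmr

    return harris_benedict_bmr(sex, weight_kg, height_cm, age_years)


def simulate_reads(
    world: SyntheticWorld, subject_id: str, depth: int, seed: int
) -> ReadSet:
    """Single-end reads for one subject: gene-proportional sampling
    (abundance x length), uniform start positions, substitution errors at
    the configured rate, plus injected urdA-reference reads at the planted
    per-subject fractions. Deterministic given seed."""
    if subject_id not in world.truth.index:
        raise KeyError(f"unknown subject {subject_id!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    cfg = world.config
    L = cfg.read_length
    if depth == 0:
        return ReadSet([], [])
    rng = np.random.default_rng(seed)

    ab = world.gene_abundance.loc[subject_id].to_numpy()
    lengths = world.catalog.lengths
    usable = lengths >= L
    p_gene = ab * lengths * usable
    p_gene = p_gene / p_gene.sum()

    tf = float(world.truth.at[subject_id, "urda_frac"])
    ff = float(world.truth.at[subject_id, "false_urda_frac"])
    true_refs = [r for r in world.urda_refs if r.is_true_urda]
    false_refs = [r for r in world.urda_refs if not r.is_true_urda]
    sources: list[str] = list(world.catalog.sequences)
    probs = [p_gene * (1.0 - tf - ff)]
    for refs, frac in ((true_refs, tf), (false_refs, ff)):
        if refs and frac > 0:
            w = np.array([len(r.sequence) for r in refs], dtype=float)
            probs.append(frac * w / w.sum())
            sources.extend(r.sequence for r in refs)
        elif refs:
            probs.append(np.zeros(len(refs)))
            sources.extend(r.sequence for r in refs)
    p = np.concatenate(probs)
    p /= p.sum()
    counts = rng.multinomial(depth, p)

    flat, offsets, src_lengths = _read_source_arrays(world, sources)
    # shuffle so read order does not leak the source gene
    src_per_read = np.repeat(np.arange(p.size), counts)[rng.permutation(depth)]
    span = np.maximum(src_lengths[src_per_read] - L + 1, 1)
    starts = (rng.random(depth) * span).astype(np.int64)
    idx = offsets[src_per_read] + starts
    R = flat[idx[:, None] + np.arange(L)]
    if cfg.error_rate > 0:
        err = rng.random(R.shape) < cfg.error_rate
        n_err = int(err.sum())
        if n_err:
            R[err] = (R[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    seqs = _seq._DECODE[R].reshape(R.shape[0], L)
    flat = seqs.tobytes().decode("ascii")
    sequences = [flat[i * L : (i + 1) * L] for i in range(R.shape[0])]
    ids = [f"{subject_id}_r{i:06d}" for i in range(R.shape[0])]
    return ReadSet(ids, sequences)


def _read_source_arrays(world: SyntheticWorld, sources: list[str]):
    """Cached (flat codes, offsets, lengths) over catalog + urdA sources."""
    cache = getattr(world, "_read_source_cache", None)
    if cache is None:
        lengths = np.array([len(s) for s in sources], dtype=np.int64)
        offsets = np.zeros(len(sources) + 1, dtype=np.int64)
        np.cumsum(lengths, out=offsets[1:])
        flat = _seq.encode("".join(sources))
        cache = (flat, offsets[:-1], lengths)
        world._read_source_cache = cache
    return cache


def write_world(world: SyntheticWorld, outdir, reads: bool = False) -> None:
    """Write the world's file-format views: FASTA catalog and urdA
    references (+ sidecar), MGS definitions, cohort and nutrition TSVs,
    KO annotation, and the JSON config. Per-subject FASTQ only on request."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.catalog.to_fasta(out / "catalog.fasta")
    write_urda_references(world.urda_refs, out / "urda_refs.fasta", out / "urda_refs.tsv")
    mgs_definitions_to_tsv(world.mgs_defs, out / "mgs_defs.tsv")
    world.cohort_table().to_csv(out / "cohort.tsv", sep="\t")
    world.nutrition.to_csv(out / "nutrition.tsv", sep="\t")
    pd.Series(world.ko_annotation, name="ko").rename_axis("gene_id").to_csv(
        out / "ko_annotation.tsv", sep="\t"
    )
    (out / "world.json").write_text(world.config.to_json())
    if reads:
        rdir = out / "reads"
        rdir.mkdir(exist_ok=True)
        for i, subject in enumerate(world.subjects):
            rs = simulate_reads(world, subject, world.config.read_depth,
                                seed=world.config.seed + 100_000 + i)
            rs.to_fastq(rdir / f"{subject}.fastq")
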