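# Methods

This note documents the models, defaults and design choices behind
`imppipe`, in the spirit of a package's methods appendix. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Scope and shape

The package is a desk-scale, fully synthetic re-implementation of the
computational chain linking shotgun-metagenome quantification to
cohort-level associations between serum imidazole propionate (ImP),
glycemic status, microbiome ecology and diet. Nothing here consumes real
cohort data; the synthetic generator is first-class, tested code whose
job is to plant a known structure that the downstream stages must
recover. Passing tests therefore demonstrate *internal correctness and
recoverability under the planted model*, not properties of any real
population.

## Synthetic world (`synthetic_data`)

**Gene catalog and MGS panels.** Random A/C/G/T genes (default 4000,
lengths uniform on 300–1200 nt, all ≥ 150 nt so a 150 nt read can lie
inside any gene). 40 metagenomic species (MGS) of 50 genes each, every
member also a marker (the 50-marker panel); genus labels cycle through 12
common gut genera so each genus holds several MGS. The remaining ~2000
genes form a background pool.

**Community model.** Three planted enterotypes with genus Dirichlet
parameters: a Prevotella-led type, a mixed Firmicutes type, and a
concentrated Bacteroides type (low α elsewhere → low diversity). Mixture
weights 0.35/0.35/0.30. Each subject draws genus proportions from its
enterotype's Dirichlet, spreads them over the genus's MGS and member genes
with Gamma(1) weights, and keeps each gene with a per-subject retention
probability drawn Beta around the enterotype mean (0.88/0.82/0.55,
concentration 60). Retention is the richness plant: the Bacteroides type
carries markedly fewer genes, giving the bimodal richness distribution the
low/high gene-count split needs. True richness = number of genes with
nonzero planted abundance.

**ImP model.** On the natural-log nM scale:
`log ImP = 3.4 + shift(group) + (−0.3)·z(richness) + 0.25·urdA burden +
ε`, ε ~ N(0, 0.3²) truncated at ±4 SD, group shifts (0, 0.3, 0.5) for
healthy/prediabetes/type 2 diabetes. The truncation keeps iterative Grubbs
at α = 0.05 from flagging genuine draws in ~2000-record cohorts, so
planted-outlier accounting is exact; it removes only ~0.006% of the
distribution's mass. Functional-urdA carriage probability is
enterotype-specific (0.25/0.25/0.80, highest in the low-richness
Bacteroides type); carriers get a log-normal burden that feeds both the
ImP model and the read simulator.

**Clinical covariates.** Age, BMI, glucose, insulin, HbA1c, triglycerides,
post-load values, creatinine clearance, serum creatinine etc. are drawn
from truncated-normal/log-normal scenario distributions with mild group
shifts. These are configuration defaults, not estimates of any cohort;
they exist so covariate adjustment has realistic material to work on.

**Nutrition.** 37 food groups (a refinement of a 22-group FFQ) with fixed
plausible histidine (mg/g) and energy (kcal/g) densities in
`foods.FOOD_GROUPS`. Per-subject intakes are log-normal around typical
amounts, rescaled so declared energy ≈ appetite × 1.6 × Harris–Benedict
BMR (appetite log-normal, σ = 0.25) — which makes the < 0.5·BMR / >
3.5·BMR plausibility rule bite only in the tails, as intended. Histidine
intake is independent of ImP by default (the planted null); a nonzero
`histidine_imp_beta` scales protein-rich group intakes with standardized
log ImP for power studies.

**Reads.** Single-end 150 nt reads drawn per subject: source gene
proportional to planted abundance × gene length, start positions uniform,
substitution errors at rate 0.002, constant FASTQ quality. On top of the
catalog reads, a small fraction of reads is injected from the urdA
reference genes — fraction 0.004 × burden for functional references in
carriers, 0.004 × log-normal noise for non-functional references in
everyone — so the marker stage has a planted signal to recover. Not
modelled: sequencer-specific error profiles, paired ends, host/food
contamination, GC bias. The mapping stage only needs identity-threshold
behaviour, which substitution-only errors exercise.

**urdA references.** Back-translated random proteins (length 450) with a
controlled residue at position 373 ('H' for non-functional references,
any other residue for functional ones) and an annotated FAD active-site
span covering codons 371–375 — in particular nucleotides 1117–1119
(codon 373). Gap-free single reading frame; position 373 is a raw
sequence position, not an alignment column.

**Planted exclusions.** The config can mark disjoint subject sets as
non-metabolic-CVD (flag), ImP outlier (log ImP set to baseline + 6, ~12
noise SD above the mean) and incomplete biochemistry (glucose, insulin,
HbA1c set to missing), enabling exact three-rule exclusion accounting.

Every generator is a pure function of (config, seed); identical seeds give
byte-identical outputs.

## Gene quantification (`gene_quant`)

**Mapping.** Exact 31-mer seeding (integer-coded k-mers against a sorted
full-position index of the catalog) at read positions {0, middle, end},
followed by ungapped full-length verification; the read must lie entirely
inside the gene. All genes tied for the best match count are kept as
shared hits, then the identity threshold (default 0.95 over the read
length) is applied to the best score. Reads with no forward hit get a
reverse-complement pass. This is a deliberate desk-scale mapper: no gaps,
no clipped alignments, no quality awareness. With the synthetic read model
(reads always inside genes, substitution-only errors) it is essentially
exhaustive; on real data one would substitute a production aligner
upstream and enter the chain at the counting step.

**Counting, downsizing, richness.** Smart shared counting as defined in
the README. Downsizing subsamples *reads* (the retained integer
read-to-gene assignments), not fractional counts, and re-runs the shared
split on each subsample — the only reading under which "subsampling reads"
is well defined once fractional attribution exists; averaged over
`n_rarefactions` (default 10) draws. Richness uses the same machinery,
counting genes with attributed count > 0. Samples with fewer mapped reads
than the target depth are excluded and reported, never silently kept. At
exactly the target depth the identity case is returned without sampling.
A shared read whose candidates all have zero unique counts is split
equally (symmetry-preserving; keeps conservation exact).

**Low/high gene count.** The split threshold defaults to the density
valley between the two components of a 2-component Gaussian mixture fit
on log₁₀ richness of the healthy stratum; the boundary is strictly-below
= low, at-or-above = high. In the pipeline the rarefaction depth defaults
to 90% of the simulated read depth.

## Community profiling (`community_profile`)

MGS abundance applies the 50-marker rule with a strict > 10% detection
guard (5/50 positive ⇒ 0; 6/50 ⇒ the panel mean). Genus collapse sums MGS
abundances by genus and rescales each sample to integer pseudo-counts
(default total 10⁴) because the DMM needs count data; proportions are
unchanged by the scaling.

The DMM omits the multinomial coefficient (constant per sample; cancels
in responsibilities, and BIC differences at fixed data). EM details:
k-means initialization on proportion vectors with α initialized to
cluster mean proportions × 50; the M-step updates π in closed form and
each α_k by L-BFGS-B in log-α space (α floor 10⁻⁶, cap 10⁶), accepting
the optimizer's result only if the weighted objective did not worsen —
which guarantees a monotone log-likelihood trace (asserted to −10⁻⁸).
Best of `n_init` restarts is kept; convergence when the gain drops below
`tol` (default 10⁻⁴). Model selection minimizes BIC with
p = K·J + (K−1). The pipeline fixes K = 3 by default (matching the
planted world; set `k_enterotypes=None` for BIC selection).

"Bacteroides 2" is identified *operationally*: among components whose
largest α share belongs to the configured Bacteroides-like genus, the one
with the lowest member mean richness. It is an analog of the published
enterotype taxonomy, not a nomenclature match.

## Marker quantification (`marker_quant`)

Window counting is exact-overlap matching: a read counts toward a window
iff some placement (either strand, overhangs allowed) matches the
overlapping segment with zero mismatches and no gaps over strictly more
than 100 nt (`min_overlap = 101`, configurable). Only the overlap must
match; read bases hanging past the window edges are unconstrained. A
k-mer prefilter (stride min_overlap − k) makes the scan linear without
any false negatives, since a qualifying overlap necessarily contains a
window 31-mer at a probed position. Samples with < 10 total window reads
are flagged excluded — an outcome, not an error — and excluded samples
carry no abundance value. Abundance is reads per million sample reads per
class (true/false urdA). A read matching several windows counts toward
each; with randomly generated references cross-matching is negligible.

*hutH* abundance is the FPKM sum over catalog genes annotated to KO
K01745, with the annotation supplied as an input table (the generator
annotates ~2% of MGS member genes).

## Cohort statistics (`cohort_stats`)

* **Grubbs**: iterative two-sided test, critical value
  ((n−1)/√n)·√(t²/(n−2+t²)) with t = t_{α/(2n), n−2}; zero-variance
  samples flag nothing. The pipeline's ImP outlier rule runs Grubbs on
  log ImP (ImP is generated log-normal; the test assumes normality).
* **Exclusions** apply in order (CVD etiology → Grubbs → completeness);
  a record counts under the first rule it matches, so per-rule counts sum
  exactly to input − output.
* **Indices**: closed-form HOMA1-style surrogates (÷ 22.5; HOMA-B
  20·ins/(glu−3.5), undefined at glu ≤ 3.5 → missing) stand in for the
  iterative HOMA2 computer model and are labelled surrogates; QUICKI and
  TyG use mg/dl conversions (glucose × 18.016, TG × 88.57) internally;
  Stumvoll ISI (0.226 − 0.0032·BMI − 0.0000645·ins₁₂₀[pmol/l] −
  0.0037·glu₁₂₀) and MDRD eGFR (175·Scr⁻¹·¹⁵⁴·age⁻⁰·²⁰³·0.742 if female)
  coefficients live in `IndexCoefficients` and are configurable. The
  cohort exposes both creatinine clearance (generated) and MDRD eGFR
  (derived); covariate Models 2–3 use creatinine clearance.
* **Quartiles**: empirical 25/50/75 percentiles (linear interpolation,
  NumPy default); ties go to the lower quartile, so a constant vector is
  all Q1.
* **Multinomial ORs**: Newton ML fit (statsmodels MNLogit), healthy and
  Q1 as references, Wald 95% CIs; non-convergence (separation) is flagged
  and estimates withheld rather than reported. Quartile levels absent
  from the data are dropped from the design.
* **Partial correlation**: least-squares projection of x and y on
  [1, covariates], Pearson on residuals; Spearman ranks all variables
  first. p from t with n − 2 − k df where k is the *rank*-based covariate
  count — so adding a zero-variance covariate (e.g. diabetes status in a
  single-status stratum) leaves the result exactly unchanged, and
  rank-deficient designs warn and project on the column space. CI by
  Fisher z with 1/√(n − k − 3).
* **Log-transform policy**: Shapiro–Wilk on raw values; p < 0.05 ⇒
  natural log (non-positive values then error); constant vectors are
  flagged degenerate and left alone.
* **BH-FDR** via statsmodels `multipletests`; one family per analysis
  block (the pipeline's four primary associations form one family).
* **Random forest**: regression forest with max_leaf_nodes = 50,
  impurity-decrease importances averaged over the training sides of
  (default) 100 CV folds, with per-taxon Spearman p and BH q. Fold count
  shrinks with a warning when n < folds.

## Pipeline and problem sizes

`run_pipeline` chains the stages on one synthetic world. Default study
conditions: 500 subjects, 5 × 10⁴ reads/sample, rarefaction depth 45 000,
10 rarefactions, K = 3, 3 DMM restarts. The four-association block is
ImP~richness (partial r, Model 1 covariates), ImP~status (2-df joint
test), true-urdA~Bacteroides-2 membership (Spearman partial, marker-QC
samples only), and ImP~histidine (partial r, Model 1 + energy), BH
adjusted together. Tests exercise the same chain at compact sizes
(40–60 subjects, 8–20 × 10³ reads) chosen so the whole suite stays
interactive; the compact smoke configuration raises the urdA read
fractions (0.02) so the 10-read marker QC retains most samples at shallow
depth.

## Numerical and degenerate-input choices

Identity ties in mapping are kept as shared hits (they feed the shared
split) rather than broken arbitrarily. FPKM is undefined (error) at zero
mapped reads. Genus rows summing to zero collapse to all-zero
pseudo-counts, which the DM likelihood handles (log DM = 0 at N = 0).
Responsibility rows and mixture weights are renormalized against
underflow (floors 10⁻¹², α floor 10⁻⁶). The richness threshold fit
requires ≥ 4 samples. Grubbs requires n ≥ 3. Quartiles require n ≥ 4.

## Known limitations

The mapper is not a production aligner (no gaps, no clipping, no base
qualities); the enterotype analog is operational, not nomenclature-true;
diet-quality scores are simplified threshold sums, not the published
EPIC-derived definitions; the HOMA surrogate is HOMA1-form, not HOMA2;
clinical and dietary distributions are scenario choices. Because all
signals are planted, effect-size recovery says nothing about real-world
effect sizes — only that the chain preserves sign and detectability under
its stated model.
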