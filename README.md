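# imppipe

Shotgun-metagenome quantification and cohort statistics for microbial
**imidazole propionate (ImP)** production.

ImP is a gut-microbial metabolite of dietary histidine (histidine →
urocanate → ImP) that impairs insulin signalling and is elevated in people
with prediabetes and type 2 diabetes. Linking serum ImP to the microbiome
takes a chain of computational steps that are usually scattered across ad
hoc scripts: counting catalog genes from shotgun reads, estimating gene
richness by rarefaction, profiling metagenomic species (MGS) and
enterotypes, quantifying the functional genes of the histidine pathway
(*urdA*, *hutH*), and running covariate-adjusted association statistics on
the joined clinical table. `imppipe` implements that chain as a tested,
importable Python library, together with a synthetic-cohort generator that
plants the expected statistical structure so every stage can be exercised
and validated without access to restricted patient data.

Who it is for: microbiome researchers and biostatisticians who want a
transparent, desk-scale reference implementation of this analysis chain —
to study its behaviour, validate derived pipelines against planted truth,
or teach it.

## The methods at the core

* **Smart shared counting.** Reads mapping a gene catalog at ≥ 95% identity
  are counted in two steps: uniquely-mapping reads add 1 to their gene;
  each read shared between genes \(g_1..g_m\) is then split proportionally
  to the genes' unique counts \(u_i\): gene \(g_i\) receives
  \(u_i / \sum_j u_j\) (equal split if all \(u_j = 0\)). Per sample,
  counts always sum to the number of mapped reads.
* **Rarefaction gene richness.** Richness = mean, over 10 independent
  subsamples of reads to a fixed depth, of the number of genes detected at
  least once. Subjects split into *low* vs *high* gene count at the valley
  of the bimodal richness distribution of the healthy stratum
  (strictly-below = low).
* **MGS abundance (50-marker rule).** An MGS's abundance is the mean FPKM
  of its 50 marker genes, reported only when strictly more than 10% of the
  markers are positive, else 0. FPKM = count / (gene kb) / (mapped reads
  in millions).
* **DMM enterotypes.** Genus-level pseudo-counts are clustered with a
  Dirichlet multinomial mixture fit by EM
  (log DM(x|α) = logΓ(A) − logΓ(N+A) + Σ_j [logΓ(x_j+α_j) − logΓ(α_j)],
  A = Σα, N = Σx), K chosen by BIC or fixed. The component combining a
  Bacteroides-dominated α with the lowest member richness is tagged as the
  low-richness "Bacteroides 2" analog.
* **urdA quantification.** Urocanate-reductase homologs are classified by
  protein position 373 (histidine there ⇒ non-functional, `false_urda`).
  Reads are counted against ±90 nt windows around the FAD active site,
  requiring an exact (0-mismatch, gapless) overlap of > 100 nt; samples
  with < 10 window reads are excluded; abundances are reads per million.
  *hutH* is the per-sample FPKM sum over genes annotated to KEGG ortholog
  K01745.
* **Cohort statistics.** Iterative Grubbs outlier exclusion; surrogate
  indices (HOMA-IR surrogate, QUICKI, TyG, Stumvoll ISI, MDRD eGFR,
  Harris–Benedict BMR with the < 0.5·BMR / > 3.5·BMR energy-intake
  plausibility rule); histidine intake over 37 FFQ food groups;
  diet-quality scores; ImP quartiles with multinomial-logit odds ratios;
  partial correlations under nested covariate models (Model 1: age, sex,
  BMI, ethnicity; Model 2: + creatinine clearance; Model 3: + diabetes
  status); Benjamini–Hochberg FDR per analysis block; residualized
  random-forest taxon importance.

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`python examples/06_end_to_end.py`, ~1 minute at its compact size)
prints, for a 60-subject synthetic cohort:

```
richness threshold (bimodal split): 1775 genes
             dominant_genus  dominant_share  mean_richness  n_members
component
1          Faecalibacterium            0.29        2158.15         20
2               Bacteroides            0.75        1235.37         16
3                Prevotella            0.50        2144.57         24
Bacteroides-2 analog: component 2

association block (BH-FDR adjusted as one family):
                           estimate       p       q   n
imp_vs_richness             -0.6575  0.0000  0.0000  60
imp_vs_status                0.4498  0.0815  0.1087  60
true_urda_vs_bacteroides2    0.3906  0.0591  0.1087  29
imp_vs_histidine            -0.1051  0.4493  0.4493  60
```

Reading the numbers: the partial correlation between log ImP and gene
richness is strongly negative (fewer microbial genes, more circulating
ImP); ImP trends upward with diabetes status and functional *urdA* is
enriched in the low-richness Bacteroides-like enterotype, though at this
compact size (60 subjects) those two do not clear FDR < 0.05; the
histidine-intake association is a planted null and stays non-significant.
At the default study scale (500 subjects, 5 × 10⁴ reads/sample) all three
planted effects pass FDR < 0.05 decisively — that configuration is what
the acceptance script runs.

A thin CLI mirrors the stages (`imppipe simulate | count | enterotype |
markers | run-all`); see `imppipe --help`.

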