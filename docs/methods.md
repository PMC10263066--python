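# Methods

## Gating model

Events are classified by a DAG of single-marker threshold gates.  Every
channel carries two fixed thresholds, `negative` and `positive` (default 1.5
and 2.5 on the log10 intensity scale): `positive`/`high` means intensity ≥
positive threshold, `low` means the interval between the two thresholds
(dim expression, needed for HLA-DRlo and the three FOXP3 levels that
discriminate the Treg fractions), and `negative` is the complement of
positive so that a +/− split partitions its parent exactly.  Thresholds are
config values, not data-derived: the reference workflow uses static manual
gates, and the synthetic templates ship intensities matched to the packaged
thresholds.  Macrophages are gated CD68+ with side scatter above a
dedicated scatter threshold.

The packaged tree resolves **30 populations from a 26-marker panel**: 23
base cell types — NKT (total, CD4+, CD8+), CD4+ T with naive/CM/EM/EMRA
memory quadrants (CD45RA × CD197) and the three FOXP3 Treg fractions
(Fr. I CD45RA+FOXP3lo, Fr. II CD45RA−FOXP3hi, Fr. III CD45RA−FOXP3lo),
CD8+ T with the same four memory quadrants, B, NK, cDC, pDC, macrophage
(CD68+SSChi), mMDSC (HLA-DRlo CD14+CD11b+CD33+) and CD14+ monocyte — plus
7 aggregate functional overlays (Ki-67+ CD4 T, Ki-67+ CD8 T, PD-1+ CD4 T,
PD-1+ CD8 T, PD-L1+ CD8 T, PD-L1+ mMDSC, CTLA-4+ eTreg).  Overlay gates are
non-exclusive children of their parent populations; exclusive splits
partition.  Design choices fixed here because the source enumerates the
population list only in prose: CD14+ monocytes are a separate CD3− myeloid
population (distinct from mMDSC), and the overlay membership above is the
packaged definition of the 30-list; the 23 base types are exposed as the
`fig1g_23` feature preset.  The named gating markers number 21; the panel is
padded to its stated 26 channels with CD25, CD127, CD16, CD38 and CD69,
which the default tree does not gate on.

## Features and clustering

Each population contributes two features: cell density
`log10(count/mass_g + 1)` (log10 cells per gram) and `%CD45` (percent of
total CD45+ leukocytes).  Both blocks are z-scaled across exactly the
samples being clustered (sample standard deviation, n−1, the convention of
`scale()` in the R stack this mirrors) and concatenated.  Constant features
z-scale to 0 with a warning rather than propagate NaN; zero denominators
yield missing fractions, never zeros.  The scaling cohort is an explicit
argument: tumors + NATs are scaled together for the two-clade analysis,
tumors alone for subtype discovery.

Sample distance is 1 − Spearman ρ (average ranks for ties,
pairwise-complete over missing features).  Agglomeration is Ward.D2: the
Lance–Williams recurrence with Ward coefficients applied to squared
dissimilarities, heights reported unsquared.  It is implemented natively so
the merge order is fully specified — ties break toward the pair containing
the lowest leaf index — and is verified in the tests against both a
brute-force minimum-variance-increase agglomerator and scipy's Ward linkage
on Euclidean data.  k = 3 is a default, not auto-selected.

Cluster→subtype naming is automated by the composition rule stated
qualitatively in the narrative the analysis follows: the cluster with the
lowest mean total CD45+ density is Cold; of the other two, the one with the
higher mean macrophage + mMDSC + CD14+ monocyte %CD45 is Myeloid and the
other CD8, with ties broken toward CD8 by T-cell %CD45 and a warning.

**Feature presets per analysis.** Tumor-only subtype clustering uses the
`fig2` preset (the 10 top-level cell types, density + %CD45 = 20 features).
The combined tumor + NAT clustering uses `fig1g_23` (23 base types): the
tumor/NAT contrast is carried largely by memory architecture — tumors are
effector-memory-rich where NAT is naive/NK-rich — which the top-level set
cannot see, whereas both feature sets separate the three tumor subtypes.

## Synthetic cohorts

The generator exists because the raw cytometry and sequencing data are
access-controlled; it plants the qualitative structure the analysis is
designed to recover and emits the ground truth on a separate channel that no
analysis stage reads.

* **Events.** Marker intensities are independent lognormals per population
  (no spillover/compensation; gating is threshold-based, so marginal
  separation is what matters).  Positive modes sit ≥ 3 sd above the
  positive threshold, "lo" modes between thresholds, so misclassification
  is negligible and recovery tolerances test the pipeline, not the gates.
  Per-sample composition is drawn around subtype templates (Dirichlet
  jitter, concentration 150 for top-level fractions) and per-sample counts
  are multinomial.
* **Subtype templates.** Immune fraction of acquired events: Cold 0.08,
  Myeloid 0.45, CD8 0.42, NAT 0.30 (the rest is dead-cell and CD326+
  epithelial contamination).  Myeloid-lineage %CD45 ≈ 64% in Myeloid vs
  18% in CD8; T-cell %CD45 ≈ 57% in CD8 vs 22% in Myeloid; NAT is
  naive/NK-rich.  Tissue mass is lognormal with mean 0.5 g, sd 0.2 g
  (surgical-fragment scale, exercising the per-gram normalization).
  Acquisition is 12 000 events per sample in the study templates and 5 000
  in `mini` — a deliberately down-sampled acquisition budget that keeps
  cohort simulation laptop-friendly while leaving multinomial noise well
  below the recovery tolerances.  No absolute density scales are published
  for the source cohort, so these settings encode its qualitative orderings
  only.
* **Templates.** `study_luad` = 85 tumors (19 Cold / 36 Myeloid / 30 CD8),
  `study_lusq` = 50 (14/19/17), `study_full` adds 157 NATs, `mini` is a
  20-sample fast template.  LUAD and LUSQ currently share composition
  templates; the histology label drives cohort layout only.
* **Expression.** log-normal TPM around per-gene baselines (uniform 2–8
  log2), planted log2 shifts: effector/chemokine genes +1.5 in CD8,
  type-I-IFN genes +1.0, checkpoint genes +1.0, antigen-presentation +0.8,
  suppressive myeloid genes +1.2 in Myeloid; 200 exchangeable background
  genes.
* **TCR.** Clonotype frequencies are symmetric Dirichlet (richness R,
  concentration α) sampled into UMI counts at the configured depth; the
  closed form E[H] = ψ(Rα + 1) − ψ(α + 1) makes planted diversity gaps
  testable.  Defaults: R = 600 with α = 1.0 (CD8), 0.45 (Cold), 0.25
  (Myeloid), 0.7 (NAT); TRD/TRG use one-fifth richness.  Entropy-gap
  recovery is validated pre-filter; the minimum-UMI filter truncates rare
  clonotypes and shifts absolute entropies, so the filtered check is on
  direction (CD8 highest), not the gap magnitude.
* **Clinical.** Exponential EFS times (proportional hazards by
  construction) with subtype multipliers Myeloid 3.0 / Cold 1.8 / CD8 1.0
  over a baseline median of 80 months, independent exponential censoring
  (median 120 months) plus administrative censoring at 60 months, and
  categorical clinicopathologic factors with planted subtype associations
  and (optionally disabled) hazard contributions of their own — disabling
  them gives an exact exchangeable null for calibration tests.

What passing on these cohorts does **not** show: robustness to spectral
spillover, doublets, batch effects, non-lognormal intensity shapes,
histology-specific composition differences, non-proportional hazards, or
transcriptional heterogeneity beyond mean shifts.  Results on real cohorts
additionally depend on threshold placement, which is assumed correct here.

## Expression scoring choices

The signature-score reduction is not specified by the source; the default is
the mean across set genes of per-gene z-scores of log2(TPM + 1), the
simplest reduction consistent with "scores" that has a closed-form oracle;
constant genes contribute 0.  Centroid assignment log-transforms TPM + 1
(natural log by default), centers each gene at its cohort median and takes
the Pearson-correlation argmax; after median centering a change of log base
rescales every centered profile by one positive constant, so labels are
base-invariant (tested).  Centroid matrices are user inputs; the package
ships only synthetic test centroids.  Immunogram axes are scaled to [0, 5]
by cohort rank percentile with min→0/max→1 normalization
(p = (rank − 1)/(n − 1)), which pins cohort extremes to 0 and 5 and the
median of an odd cohort to 2.5; inverted axes map p to 5(1 − p).  The exact
published axis formulas are external; the packaged gene sets are synthetic-
data placeholders that real analyses should replace.

## Survival and association conventions

The univariate Cox fit is a native Newton solver on the Efron partial
likelihood (ties: Efron approximation), cross-checked against lifelines to
~1e-5 and fast enough for 500-replicate null calibration; the multivariate
model delegates to lifelines.  Factor tables use the exp(−coef) orientation:
the contrast "A vs. B" codes A = 1 and reports exp(−coef), i.e. the hazard
of B relative to A, excluding samples at other levels (so "CD8 vs. Myeloid"
drops Cold).  Factors enter the multivariate model iff univariate
p < 0.05; a rank-deficient joint design raises an error naming the
collinear contrasts.  Fisher tests are exact for 2×2 (scipy) and for r×c
tables by native enumeration up to a grand total of 80 (validated against
R's fisher.test), with seeded Monte-Carlo beyond.  Holm adjustment is per
scan family (one figure-panel's worth of factors); the dual flags are raw
p ≤ 0.05 and Holm-adjusted p ≤ 0.2.

## Numerical and engineering notes

* Determinism: one run seed fans out to stage seeds by SHA-256 of
  `"{seed}:{stage}"` (taken mod 2^31), and cohort seeds fan out per sample
  via `SeedSequence.spawn`; identical configs reproduce byte-identical
  outputs, and event tables are regenerated lazily from per-sample child
  seeds so large cohorts never hold all events in memory.
* Degenerate inputs: empty event tables gate to zero counts; zero
  denominators become missing values; constant features/genes contribute 0;
  non-convergent Cox fits are reported as failed without aborting the scan;
  undefined Spearman correlations (constant rank vectors) are treated as
  ρ = 0 with a warning.
* The `mini` template trades power for speed: at 14 tumors a single
  boundary Cold/Myeloid sample occasionally swaps clusters (replicate
  simulation shows exact recovery in most seeds, at most one swap
  otherwise); the study-scale templates recover the planted partition at
  ARI ≥ 0.94 across seeds.
* Event tables are read/written as CSV; FCS container I/O is out of scope
  for this package.

## Known limitations

Gate thresholds are global per channel rather than per-sample; no automated
gate inference, embedding, compensation, batch correction, imputation,
competing-risks or time-varying covariate support.  Cluster number is a
parameter (default 3), not selected by a criterion.  The immunogram's
axis-2 (tumor antigenicity) requires neoantigen burden input the package
does not model.
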