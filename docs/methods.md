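# Methods

## The analysis model

`pannetsub` treats PanNET subtype discovery as a two-level unsupervised
problem with downstream contrasts.

**Consensus clustering.** Samples are repeatedly subsampled (fraction
`p_item = 0.8` of columns, without replacement; `reps` repetitions; all
features kept, `p_feature = 1`) and hierarchically clustered on the
dissimilarity d(i,j) = 1 − PearsonCorr(i,j) with Ward-type linkage
(scipy's `ward` on a precomputed condensed distance matrix, which matches
R `hclust`'s `ward.D2`). The consensus matrix entry M_k[i,j] is the
fraction of co-sampled repetitions in which i and j landed in the same
of k clusters; pairs never co-sampled (possible at very small `reps`)
get 0 with a warning, a deliberately conservative connectivity choice.
Final assignments cut an average-linkage tree of 1 − M_k; labels are
renumbered by first occurrence so they are stable across runs. Two
caveats are worth stating. Ward linkage formally assumes squared
Euclidean distances and 1 − correlation is not one; the combination is
nevertheless the de-facto standard configuration in tumor subtyping and
is reproduced deliberately. And the model-selection statistic — the
area under the consensus CDF, computed as the exact integral of the
empirical step function, with delta(2) = A_2 and
delta(k) = (A_k − A_{k−1})/A_{k−1} — is a heuristic: the pipeline
reports the full curve for every k and leaves the final k a
configuration choice (defaults: k = 2 on methylation, k = 4 on
expression).

**Cluster naming is marker-driven.** Consensus cluster indices are
arbitrary, so the k = 2 methylation cluster with the higher fraction of
DAXX/ATRX-lost samples is named ADM and the other alpha-like. If the
marker column is missing the clusters are emitted unnamed and the
downstream two-group contrasts are skipped.

**Differential methylation** is per-probe ordinary least squares of β on
a group indicator (plus optional covariates), with the two-sided t
p-value and BH adjustment across probes; Δβ is the raw ADM − alpha-like
group mean difference. limma-style empirical-Bayes moderation is *not*
applied: at the cohort sizes targeted here moderation perturbs p-values
only mildly, and the planted effects the tests check are robust to the
difference. Default significance gates: adjusted p < 0.001 and
|Δβ| > 0.2. Chromatin-state over-representation uses the shared
one-sided Fisher routine (hypergeometric upper tail; sample odds ratio
with a 0.5 continuity correction only when a cell is zero; BH across
states).

**Structural regions.** Sub-telomeric means within `tel_window_bp` of
either chromosome end; peri-centromeric means within `cen_window_bp` of
the centromere interval; both windows default to 2 Mb (no canonical
value exists; 2 Mb captures the region-scale hypomethylation the
analysis targets while leaving most of each arm untouched, and every
output records the windows used). A probe in both windows counts as
peri-centromeric, with a warning. Per sample, the region statistic is
the median β over the region's probes; groups are compared by Welch's
unequal-variance t-test (the field's "t-test" is usually unspecified;
Welch is the safer default).

**Differential expression.** Genes need ≥ 5 reads in ≥ 2 samples.
Size factors are median-of-ratios (median over all-positive genes of
count/geometric-mean). The one-vs-rest test fits, per gene, an NB GLM
with offset log(size factor) and a group indicator (statsmodels IRLS)
and reports the Wald z test of the group coefficient; log2FC is the
coefficient divided by ln 2. Dispersion is estimated per gene by method
of moments on normalized counts using within-group residuals, then
shrunk 50/50 toward a fitted mean-dispersion trend a + b/mean and
floored at 1e-8. This is a transparent substitute for DESeq2's
machinery (Cox-Reid adjusted likelihood, apeglm shrinkage, outlier and
independent filtering are all intentionally absent): it recovers
planted fold changes on NB-simulated data, which is what the test suite
verifies, and will not numerically match DESeq2 on real data. One
consequence worth knowing: global normalization absorbs composition
shifts, so a matrix where several percent of genes are strongly
up-regulated in one group induces a small opposite bias in all null
genes — a property of median-of-ratios, not of the estimator.
`vst_like` is log2(count/factor + 1); its downstream uses (clustering,
Spearman correlation, rank-sum scores) are rank- or distance-based,
where any strictly monotone variance-stabilizing transform agrees.
Significance gates: |log2FC| > 1 and adjusted p < 0.05. Transcriptomic
clusters smaller than `min_cluster_size` (default 3) are excluded from
testing but remain in the "rest" pool.

**Integration screen.** Pairs are (significant DEG, probe annotated to
an active or weak promoter of that gene). Spearman ρ uses mid-ranks;
the p-value is exact (full permutation enumeration) for n ≤ 9 complete
pairs and the t-approximation otherwise. BH is applied over all tested
pairs pooled — the stricter and simpler reading versus a per-gene
family. A pair passes at ρ < −0.6 strictly and adjusted p < 0.05; the
gene-level summary counts distinct genes with at least one passing
probe.

**Signatures and enrichment.** The signature score ranks samples per
gene (ascending, mid-ranks) and sums ranks over signature genes, so a
high score means coordinately high expression; rank direction is chosen
so an MLP1-like signature reads "higher in the hypoxia-like and
immune-like subtypes". Preranked GSEA uses the weighted (weight 1)
Kolmogorov-Smirnov running sum; p comes from gene-label permutation
(random same-size sets, +1-corrected one-tailed frequency on the
observed ES's side) and NES divides ES by the mean |permuted ES| of
that side. The ranking statistic for subtype contrasts is the NB Wald
statistic.

**Survival and associations.** Kaplan-Meier product-limit with
simultaneous ties, the standard multi-group log-rank quadratic form
(df = groups − 1), and Pearson chi-squared with a simulated p-value —
tables drawn uniformly at fixed margins via Patefield's algorithm
(scipy's `random_table`), with the +1 correction so p is never 0.
Tumor size is dichotomized at 2.5 cm with the boundary assigned to the
"larger" class (a documented flag, since the cut is conventionally
stated as "smaller or larger than").

## The synthetic cohort

The generator emulates what the pipeline must detect, not the raw
measurement process. A toy genome of six 50 Mb autosomes with
centromeres at 24–26 Mb keeps per-chromosome region summaries
meaningful at test scale. Probe baselines come from the bimodal mixture
Beta(0.5, 5)/Beta(5, 0.5), mimicking array-like β bimodality. Planted
effects, all recorded in a `GroundTruth` ledger: signed Δβ (default
magnitude 0.3) on 600 of 10 000 probes in ADM samples, drawn with
chromatin-state weights favoring enhancers and lowly-methylated regions
(so the state ORA has signal to find); −0.15 β shifts on sub-telomeric
and peri-centromeric probes in ADM; per-subtype expression programs
(150 genes each, |log2FC| uniform on 1.5–3, 70% up) over NB counts with
dispersion 0.05 and log-uniform base means 20–2000; a 30-gene signature
planted up in two subtypes; and 40 promoter-coupled genes whose log2
mean decreases linearly in the sample's promoter-probe M value, with
the slope calibrated against the NB noise so the realized Spearman ρ
approximates a target (default −0.85). The default cohort is 100
samples (30 alpha-like, 25/25/18 ADM subtypes plus a deliberate
2-sample cluster that exercises the small-cluster exclusion path).
Effect sizes are chosen for testability — the real study never states
its generative effect sizes — and clinical annotations (grade, ALT,
CNA, tumor size, exponential disease-free survival with independent
censoring) are sampled with subtype-dependent probabilities so the
association tests have planted signal.

Noise is added on the logit scale and back-transformed, which keeps β
in [0, 1] without truncation artifacts; `noise_sd` is interpreted as
the approximate β-scale standard deviation near mid-range (the
logit-scale sd is 4·noise_sd, the inverse slope of the logistic at
1/2). Because medians commute with the monotone logit, planted median
shifts are preserved exactly, and mean shifts to second order.

What the generator does **not** emulate: probe-level detection
failures beyond an externally supplied mask, platform batch effects
(single batch by default; per-batch centering exists as plumbing),
spatial autocorrelation of methylation along the genome, gene length
or GC effects on counts, and sex chromosomes. Passing tests therefore
demonstrate that the pipeline recovers the effects it is designed to
detect under an idealized generative model — not that it is robust to
every artifact of real array/RNA-seq data.

## Numerical and reproducibility choices

- β values are clipped to [ε, 1 − ε] with ε = 0.001 before the M
  transform; ε is configurable and recorded.
- "More than 10% of samples" for probe-failure exclusion is read
  literally: a probe failing exactly 10% is kept.
- MAD omits the 1.4826 consistency constant (rank-only use); feature
  ties break lexicographically by id.
- BH is one shared routine pipeline-wide; NaN p-values are excluded
  from the family size.
- All randomness flows from a single integer seed. Consensus
  repetition r uses RNG substream (seed, r), so results are independent
  of any parallel execution order; cohort components use fixed
  substream indices. Fixed float formatting (%.6g) makes run
  directories byte-stable.
- Test and acceptance runs use scaled-down problem sizes (2000–8000
  probes, 800–2500 genes, reps 40–250) chosen so planted effects are
  recovered with wide margins; the pipeline defaults (reps = 1000,
  maxK configurable up to 20) remain the study-scale settings.
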