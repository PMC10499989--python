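# Methods

## Scope and data model

`svcis` analyses a cohort of tumors (or cell lines) described by: somatic
SV calls as pairs of oriented breakends (BEDPE, 0-based), gene models
(BED6), feature × sample matrices for protein, mRNA and phospho-site
abundance and for CpG-island (CGI) methylation beta values, gene-level
absolute copy number, MAF-lite small-mutation calls, chimeric-read fusion
candidates, enhancer/repeat/TAD interval tracks, a clinical table, and a
cell-line gene-effect matrix. All intervals are half-open 0-based;
breakends are single positions. Sample joining across matrices is strict
string matching; unmatched samples are dropped with a logged count, never
imputed.

## Normalization

Expression is brought onto "standard deviations from the median" units in
two stages: (1) per sample profile, `(x − median)/SD` over observed
values; (2) per feature within each cancer-type × batch group, the same
transform across samples. Duplicate profiles of one tumor are averaged
after stage 1. Conventions fixed for bit-reproducibility: the median of
an even-length vector is the lower middle value; SD is the population
(ddof = 0) SD over observed values, with no outlier exclusion. Features
with zero spread or fewer than 3 observations in a group are masked.
Stage 2 is exactly idempotent on complete data; the full two-stage chain
is not (stage 1 re-centres per profile), which is why the idempotence
guarantee — and its test — attach to the group stage.

Missing values stay missing throughout: the scans look for expression
outliers, which by definition cannot be imputed.

Copy number: absolute gene copies are divided by the sample's mean copy
value (a ploidy proxy) and thresholded to {−2, −1, 0, +1, +2} at relative
copy cutpoints 0.25 / 0.75 / 1.25 / 2.0 (config-exposed; the category
names constrain but do not fix them). Two overrides are absolute: zero
copies → −2, ≥5 copies → +2. The mapping is invariant under uniform
whole-genome scaling, so tetraploid genomes are not called amplified.

Methylation: probes are restricted to CGI probes off chrX/chrY; beta
values are clamped to [1e−3, 1−1e−3] and logit-transformed
(`log2(b/(1−b))`) before linear modeling; probe position categories
(TSS200/TSS1500/5'UTR/body/3'UTR) are retained for promoter-vs-body
summaries.

## Breakpoint matrices

Both breakends of every SV are eligible and all SV classes are treated
identically; the guard against amplification-driven artefacts is the CNA
covariate, not breakend filtering. Regions: gene body; 100 kb upstream
and downstream, strand-aware (upstream = 5' of the transcription start;
genomic-left/right available by flag since the choice changes results);
and a 1 Mb window anchored at the transcription start. The anchor choice
(rather than gene span ± 1 Mb) follows the rule that when multiple
breakpoints occur near the gene, the one closest to the gene start is
used; it also makes the binary 1 Mb matrix and the relative-distance
matrix share exactly the same support, a property the tests rely on.
The relative-distance weight is `w(d) = log2(W+2) − log2(d+2)` for the
nearest breakend at distance d — strictly decreasing, ≈18.93 at d = 0 for
W = 1 Mb, exactly 0 at the window edge. Ties between equidistant
breakends resolve to the smaller position, then the smaller SV id.

## Association scan

Per feature: OLS of normalized expression (or logit beta) on
[intercept, breakpoint term, CNA level, reference-coded cancer-type
one-hots] over samples with observed values. The CNA term enters as one
numeric covariate (one-hot mode available). The p-value is a two-sided t
test on the breakpoint coefficient with residual degrees of freedom;
features whose breakpoint term is constant over the used samples are
flagged untestable, and designs with condition number above 1e8 are
flagged collinear. Filters: protein-type analytes require ≥400 observed
tumors; the gene-body and 100 kb scans require ≥3 breakpoint tumors; the
1 Mb scan does not (FDR there is computed over all min-obs passers).
Methylation rows additionally require ≥1 breakpoint tumor whose beta
deviates >0.2 from the sample median. BH FDR is computed within each
region × analyte scan over the filter-passing features. The "filtered
mRNA" variant masks every mRNA value absent from the protein matrix, so
protein/mRNA discordance can be separated from detection gaps.

Expression inputs are assumed already normalized; a log-transform flag
exists for raw-scale inputs but is off by default because
double-transforming SD units is incoherent.

## Mechanism detectors

Breakend orientation follows the BEDPE dialect in which `+` means the
segment toward lower coordinates is retained at the junction
(config-switchable — callers disagree). Detectors are pure functions of
one breakend plus annotation:

- TAD disruption: true unless both breakends of the SV share one TAD;
  interchromosomal SVs always disrupt; a breakend in no TAD shares none
  (both-outside behaviour configurable).
- Enhancer hijack: from the mate breakend, scan the retained direction up
  to 0.5 Mb; the call requires a translocated enhancer there AND a
  junction-path distance (|breakend − anchor| + |enhancer − mate|)
  strictly smaller than the nearest native enhancer within 1 Mb of the
  gene anchor (no native enhancer ⇒ condition holds).
- Retrotransposon translocation: the same retained-side scan with a 20 kb
  window over LINE/SINE elements, applied to breakends within 20 kb
  upstream (strand-aware) of the gene.
- Methylation transfer: cohort-mean beta of probes in the retained
  mate-side 0.5 Mb, minus the cohort-mean beta of the gene's CGI probe;
  flagged low/high beyond ∓0.1. Cohort means are used because arrays
  cannot measure the rearranged allele per sample; the per-sample
  criteria (beta >0.2 below the sample median plus >0.4 SD
  over-expression) are applied on top.

Enrichment of a mechanism among SV-associated over-expression (scan
p < 0.01 for the 1 Mb mRNA region and per-tumor expression > +0.4 SD) is
a Pearson chi-square without continuity correction on the 2×2 table.

## Fusions, pathways

Fusion candidates lose low-confidence rows, then every identity whose
original calls were ≥50 % low confidence, then intergenic rows. WGS
support is a within-gene breakend for either partner in the same tumor,
or — for tumors without one — ≥20 % of the identity's tumors having such
support. Over-expression (>0.4 SD, max over the two partners) is
classified in a fixed precedence (mRNA+protein → mRNA-not-protein →
mRNA-with-no-protein-data → protein-not-mRNA → cross-sample ≥20 % →
none); the assignment is total and mutually exclusive, property-tested
over random evidence. Fusion identity is the ordered 5'–3' pair
(unordered mode available); the 20 % denominators use the filtered set.

Pathway tabulation resolves each (tumor, gene) to at most one alteration
in the order SNV/indel → fusion → deep deletion (−2) → high-level
amplification (+2) → SV-with-expression. Mutations qualify per role:
oncogenes need hotspot SNVs (promoter-activating events are modeled as a
hotspot flag); tumor suppressors accept hotspot SNVs or inactivating
indel/nonsense/nonstop. SV-with-expression: oncogene = breakpoint within
1 Mb and expression > +0.4 SD (protein if observed, else mRNA); tumor
suppressor = breakpoint inside the gene body and expression < −0.4 SD.
A tumor is "SV-uniquely altered" for a pathway when its only qualifying
member-gene calls are SV-associated; fusion counts as SV-associated by
default (configurable). Per-type enrichment is a one-sided Fisher test
of each cancer type versus the rest.

## Survival

One tumor per patient (first listed); times capped (default 200 months;
285 for pediatric-style cohorts) with events beyond the cap censored at
the cap. Cox fits use lifelines with Efron ties and cancer-type strata.
The breakpoint scan's covariate is log2(d+2) of the nearest breakend
within 1 Mb (ceiling log2(W+2) for non-carriers — chosen over a sentinel
for continuity), with the CNA level as a second covariate; worse outcome
is shorter distance, i.e. a negative coefficient, and one-sided p is
Wald p/2 when the sign matches. Monotone likelihood is detected by an
exploding Wald SE; the coefficient is capped at ±20 and the p-value taken
from the Cox score test at β = 0, which for a two-group covariate without
ties is exactly the log-rank statistic (tested to 1e−10). Signature
scores are per-sample means of normalized member-gene expression;
tertile binning sends ties to the lower bin; the three-group log-rank
supports stratification by summing score vectors and covariances across
strata.

## Cell lines

Two proteomic sources merge by ordered precedence (secondary fills
primary's gaps) followed by per-gene z-normalization across lines. Per
gene × line: breakpoint within 1 Mb, protein > 0.4 SD above the line
median, gene effect < −0.5. The overlap test is the 2×2 chi-square of
{breakpoint & over-expression} × {sensitive} over all pairs; recurrence
filters keep genes with joint events in ≥7 lines and in ≥5 % of lines
(both inclusive). Rank enrichment is an unweighted Kolmogorov–Smirnov
running sum over the gene-effect variability ranking (variability =
per-gene SD across lines; the choice of statistic was open) with
set-size-preserving permutation p-values (≥10,000 draws, seeded,
Monte-Carlo SE reported).

## Synthetic cohort

Defaults describe the study conditions: 600 tumors in 6 cancer types
(one type split into two batches; 7 patients contribute two tumors with
shared outcome), 2000 genes of 20 kb every 100 kb on four 50 Mb
chromosomes, alternating strands. Background SVs: Poisson(2) calls per
tumor (4 breakends), mates log-uniform 10 kb–10 Mb away or translocated;
this reproduces the real-data sparsity of roughly ≤4 % of tumors having a
breakpoint within 1 Mb of a given gene, which is the power regime the
method must work in. (A higher raw breakend count would be realistic for
a 3 Gb genome but not for a 200 Mb toy genome — occupancy, not count, is
the condition that matters.)

Expression = per-gene cancer-type offset (SD 0.5) + shared
protein/mRNA biology (SD 0.7) + analyte noise (SD 0.7) + 0.5·(copies − 2)
+ planted effects, then the same two-stage normalization as real data.
Protein values are missing completely at random at 15 % (an
abundance-dependent logistic mode exists to emulate the difficulty of
detecting low-abundance proteins, off by default for test simplicity),
and 10 % of non-planted genes are down-sampled below the 400-tumor
observation filter; mRNA misses 2 %.

Planted families (each recorded in a truth list and re-checked by a
self-audit): 40 cis effects (±1.5–2.5 SD in 2–4 % of tumors), 20
CNA-only confounders (SVs always co-occurring with copy gain 4–5, zero
direct effect; an equal number of gain-without-SV tumors breaks exact
collinearity so the CNA covariate is identifiable), 12 fusions (4 tumors
each: chimeric calls from two callers, a gene-body-to-gene-body
translocation, +2 SD on both partners), 6 enhancer hijacks, 6 LINE
translocations and 6 low-methylation-region transfers (constructed so
the orientation-aware detectors must fire), 10 survival genes (a
correlated signature driving an exponential hazard with HR 2.0 per score
unit, plus 5 %-prevalence breakpoint carriers at HR 2.0 placed within
100 kb so the log-distance covariate separates them from the ceiling),
and 8 cell-line dependency genes (10 lines each with breakpoint,
+2 SD protein and gene effect N(−0.9, 0.1) against N(0, 0.15)
background). Censoring is uniform-administrative (~30 %). Genes whose
recovery depends on a clean breakpoint window (cis, confounder,
survival) sit on a 2.1 Mb grid so their 1 Mb windows never overlap;
enhancer annotations exist only on chr3/chr4 while hijack genes sit on
chr1, which realizes the "no native enhancer within 1 Mb" precondition
by construction.

What the generator does not emulate — and hence what green tests do not
establish about real data: realistic SV size/class distributions and
clustered rearrangements (chromothripsis), copy-number segments spanning
many genes, correlated missingness between analytes, batch effects that
do not align with cancer type, subclonality, or measurement error in the
SV calls themselves.

## Numerical and design notes

- Region membership, tie-breaks, and float formatting (`%.6g`) are fixed
  so identical config + seed reproduce byte-identical outputs end to end.
- The self-audit scores carriers within cancer type (matching the
  per-type over-expression definition) and requires a majority of
  observed carriers beyond ±0.4 SD; with 4-carrier families a shuffled
  cohort still passes a given record with probability ≈0.4, so audits of
  corrupted data are asserted in aggregate, not per record.
- The association scan's OLS is a direct least-squares solve (explicit
  rank/condition handling, ~1 ms per gene); statsmodels and a
  normal-equations solve are used as independent oracles in the tests,
  never as the implementation path being tested.
- Problem sizes in tests and in `scripts/acceptance.py` (10 seeds for
  recovery/confounders, 20 for survival in the test suite, 5 in the
  script; 2000 × 600 null scans) were chosen to keep Monte-Carlo error
  well inside the asserted margins while the whole suite stays in the
  minutes range on one CPU.

## Known limitations

Single coordinate system per run (no liftover); no mixed models or
permutation p-values for the main scan; enhancer activity and TAD
boundaries are taken as given annotation, not inferred; the methylation
transfer detector characterizes regions by cohort means and cannot see
allele-specific methylation; fusion frame and breakpoint sequence are out
of scope.
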