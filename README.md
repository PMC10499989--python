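# svcis

Somatic structural variants (SVs) deregulate genes not only by changing
coding sequence but by moving non-coding DNA: a breakpoint near a gene can
hijack an enhancer, break a topologically associating domain (TAD),
translocate a retrotransposon or a block of differently methylated DNA,
or create a fusion transcript. `svcis` is a pipeline for asking, across a
multi-cancer cohort with whole-genome SV calls and proteogenomic
profiling, which genes have protein, mRNA, phospho-site or CpG-island
methylation levels that track the presence of a nearby breakpoint — after
removing what copy-number alteration (CNA) and cancer type explain on
their own.

It is written for computational biologists working with tumor WGS plus
expression compendia (or cell-line panels with CRISPR screens), and it
ships a synthetic-cohort generator with planted, machine-readable ground
truth so that every stage can be validated end to end without any
controlled-access download.

## The model at the core

For each gene *g* and region window *w* (gene body, 100 kb upstream,
100 kb downstream, or a 1 Mb window around the transcription start), a
gene × sample breakpoint matrix **B** is built: binary occupancy, or a
relative-distance weight `log2(W+2) − log2(d+2)` that gives breakpoints
close to the gene more influence. Expression is normalized to
SD-from-median units in two stages (within each sample profile, then per
feature within cancer-type × batch groups; never imputed). Each feature
is then fit by ordinary least squares:

```
y_g = β0 + β1·B_gw + β2·CNA_g + Σ_k γ_k·1[type = k] + ε
```

with a two-sided t test on β1 and Benjamini–Hochberg FDR within each
region × analyte scan. Genes survive only if the breakpoint pattern
explains expression beyond CNA and cancer type. Downstream stages
consume these associations: fusion-evidence integration (chimeric calls ×
within-gene breakpoints × >0.4 SD over-expression), cis-regulatory
mechanism detectors (TAD disruption, enhancer hijacking with the
"closer-than-native" rule, LINE/SINE translocation within 20 kb,
rearranged-region methylation transfer), pathway alteration tabulation
with a fixed precedence order (SNV/indel → fusion → deep deletion →
high-level amplification → SV-with-expression), stratified Cox survival
scans on log2 breakpoint distance and expression, and the cell-line
overlap of {breakpoint + protein over-expression} with CRISPR knockout
sensitivity (gene effect < −0.5).

## Worked example

```
python examples/02_association_scan.py
```

generates a 600-tumor, 2000-gene synthetic cohort with 40 planted
cis-effects (|Δ| 1.5–2.5 SD in 2–4 % of tumors), runs the corrected 1 Mb
protein scan, and prints:

```
scanned 1800 genes with protein in >=400 tumors
significant at FDR<10%: 44
planted cis-effects recovered: 35/40
feature_id  coefficient  p_two_sided       fdr_bh  n_bp_samples
  gene0772     1.338703 8.627547e-14 9.195936e-11            35
  gene0919     1.423242 1.021771e-13 9.195936e-11            31
  gene1377    -1.225310 3.399697e-13 2.039818e-10            45
  gene0835     1.148176 1.588104e-10 6.852568e-08            42
  gene0419     0.936679 1.903491e-10 6.852568e-08            54
```

A positive coefficient means tumors with a nearby breakpoint express the
gene above the cohort median, in SD units per breakpoint-indicator unit;
`n_bp_samples` counts the tumors carrying a breakpoint in the window.
The other `examples/*.py` scripts walk through cohort simulation and
auditing, fusion evidence, the mechanism detectors, the survival scans
and the cell-line dependency overlap in the same style.

A thin CLI mirrors the stages (`svcis simulate | normalize | matrix |
associate | fusions | mechanisms | pathways | survival | depmap |
report`); identical config and seed give byte-identical outputs.

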