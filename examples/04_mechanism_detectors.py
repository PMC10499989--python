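"""Annotate cis-regulatory mechanisms behind breakpoint-expression links.

For each planted rearrangement the detectors ask: does the junction span
two TADs, does the retained mate side carry an enhancer within 0.5 Mb
(closer than any native enhancer within 1 Mb of the gene), a LINE/SINE
within 20 kb, or a block of low-methylation DNA?
"""
from svcis.breakpoints import breakends_from_calls
from svcis.mechanisms import (enhancer_hijack, meth_transfer_delta,
                              retro_translocation)
from svcis.simulate import SimConfig, generate_cohort

cohort, truth = generate_cohort(SimConfig(seed=1))
genes = {g.gene_id: g for g in cohort.genes}
by_sv = {}
for be in breakends_from_calls(cohort.svs):
    by_sv.setdefault((be.sample_id, be.sv_id), []).append(be)


def near_breakend(rec, s, sv_id):
    gene = genes[rec.gene_id]
    return next(b for b in by_sv[(s, sv_id)] if b.chrom == gene.chrom)


for kind, fn in (
    ("enhancer_hijack", lambda be, rec: enhancer_hijack(
        be, genes[rec.gene_id], cohort.enhancers)[0]),
    ("retro_hijack", lambda be, rec: retro_translocation(
        be, cohort.repeats)[0]),
    ("meth_transfer", lambda be, rec: meth_transfer_delta(
        be, cohort.meth_beta, cohort.probe_annotation,
        rec.details["probe_id"])[1] == "low_meth"),
):
    hit = tot = 0
    for rec in truth.by_kind(kind):
        for s, sv_id in zip(rec.sample_ids, rec.sv_ids):
            tot += 1
            hit += bool(fn(near_breakend(rec, s, sv_id), rec))
    print(f"{kind:16s} detector recovers {hit}/{tot} planted events")
# the detectors are pure functions of a breakend and an annotation track;
# the breakend-mate orientation decides which flanking DNA travels with
# the rearrangement.
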