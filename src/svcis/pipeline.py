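"""End-to-end pipeline stages over a cohort bundle.

Each stage is a pure function of the bundle (plus earlier stage outputs)
returning DataFrames; the CLI wraps these and writes TSVs. Stages follow
the published order: normalize -> breakpoint matrices -> association scans
-> fusion evidence -> mechanism annotation -> pathway tabulation ->
survival scans -> cell-line dependency overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (association, breakpoints, depmap, fusions, mechanisms,
               normalize, pathways, survival)
from .association import ScanFilterPolicy
from .breakpoints import RegionSpec, breakends_from_calls
from .io import Matrix, RunConfig
from .simulate import Cohort


def stage_normalize(cohort: Cohort) -> dict:
    """Two-stage expression normalization, CNA thresholding and
    methylation transforms for every analyte in the bundle."""
    groups = cohort.groups().to_dict()
    out = {
        "protein": normalize.normalize_two_stage(cohort.protein, groups),
        "mrna": normalize.normalize_two_stage(cohort.mrna, groups),
        "phospho": normalize.normalize_two_stage(cohort.phospho, groups),
        "cna": normalize.threshold_cna(cohort.cna_copies),
    }
    probes = normalize.filter_cgi_probes(cohort.probe_annotation)
    beta = cohort.meth_beta.loc[
        [p for p in probes["probe_id"] if p in cohort.meth_beta.index]]
    out["probes"] = probes
    out["beta"] = beta
    out["meth_logit"] = Matrix(normalize.logit_beta(beta))
    out["mrna_filtered"] = association.mask_mrna_to_protein(
        out["mrna"], out["protein"])
    return out


def stage_matrices(cohort: Cohort, config: RunConfig | None = None) -> dict:
    """Binary occupancy matrices for all four region windows plus the
    relative-distance 1 Mb matrix."""
    config = config or RunConfig()
    bes = breakends_from_calls(cohort.svs)
    samples = [r.sample_id for r in cohort.samples]
    regions = breakpoints.default_regions(config.upstream_window,
                                          config.downstream_window,
                                          config.flank_window)
    out = {name: breakpoints.build_binary_matrix(bes, cohort.genes,
                                                 samples, spec)
           for name, spec in regions.items()}
    out["relative_distance"] = breakpoints.build_relative_distance_matrix(
        bes, cohort.genes, samples, config.flank_window)
    return out


def probe_breakpoint_matrix(matrices: dict, probes: pd.DataFrame,
                            region: str):
    """Lift a gene-level breakpoint matrix to probe level via the
    probe -> gene link."""
    gene_bp = matrices[region].values
    rows, idx = [], []
    for r in probes.itertuples(index=False):
        if r.gene_id in gene_bp.index:
            rows.append(gene_bp.loc[r.gene_id].to_numpy())
            idx.append(r.probe_id)
    values = pd.DataFrame(np.array(rows), index=idx,
                          columns=gene_bp.columns)
    m = matrices[region]
    return breakpoints.BreakpointMatrix(values, m.mode, m.region,
                                        m.provenance)


def stage_associate(cohort: Cohort, norm: dict, matrices: dict,
                    analyte: str = "protein",
                    regions: tuple = ("gene_body", "upstream_100kb",
                                      "downstream_100kb", "flank_1mb"),
                    policy: ScanFilterPolicy | None = None,
                    gene_subset=None) -> pd.DataFrame:
    """Association scans for one analyte over the requested regions."""
    policy = policy or ScanFilterPolicy()
    expr = norm[analyte]
    if gene_subset is not None:
        expr = Matrix(expr.values.loc[
            [g for g in gene_subset if g in expr.values.index]])
    groups = cohort.cancer_types()
    tables = []
    for region in regions:
        tables.append(association.run_scan(
            expr, matrices[region], norm["cna"], groups, policy,
            analyte=analyte))
    return pd.concat([t for t in tables if not t.empty], ignore_index=True)


def stage_associate_methylation(cohort: Cohort, norm: dict, matrices: dict,
                                policy: ScanFilterPolicy | None = None
                                ) -> pd.DataFrame:
    """Methylation scan: logit beta vs breakpoints, with the beta-outlier
    tumor rule; CNA covariate comes from the linked gene."""
    policy = policy or ScanFilterPolicy(min_obs=3)
    probes = norm["probes"]
    probes = probes[probes["gene_id"] != "."]
    groups = cohort.cancer_types()
    bp = probe_breakpoint_matrix(matrices, probes, "flank_1mb")
    gene_of = dict(zip(probes["probe_id"], probes["gene_id"]))
    cna = norm["cna"]
    probe_cna = pd.DataFrame(
        {p: cna.loc[g] for p, g in gene_of.items() if g in cna.index}).T
    expr = Matrix(norm["meth_logit"].values.loc[
        [p for p in probes["probe_id"]
         if p in norm["meth_logit"].values.index]])
    return association.run_scan(expr, bp, probe_cna, groups, policy,
                                analyte="methylation", beta=norm["beta"])


def stage_fusions(cohort: Cohort, norm: dict, config: RunConfig | None = None
                  ) -> dict:
    config = config or RunConfig()
    cands = [fusions.FusionCandidate(r.sample_id, r.gene5, r.gene3,
                                     r.caller, r.confidence,
                                     bool(r.intergenic))
             for r in cohort.fusion_candidates.itertuples(index=False)]
    kept = fusions.filter_candidates(cands)
    bes = breakends_from_calls(cohort.svs)
    events = fusions.annotate_sv_support(kept, bes, cohort.genes,
                                         config.cross_sample_frac)
    events = fusions.annotate_expression_support(
        events, norm["protein"], norm["mrna"], config.oe_sd,
        config.cross_sample_frac)
    summary = fusions.summarize_fusions(events, cohort.cancer_types())
    return {"candidates": kept, "events": events, "summary": summary}


def stage_mechanisms(cohort: Cohort, norm: dict, matrices: dict,
                     assoc_mrna: pd.DataFrame,
                     config: RunConfig | None = None,
                     max_background_pairs: int = 2000,
                     seed: int = 0) -> dict:
    """Annotate mechanisms for flank-region (gene, sample) breakpoint
    pairs and test enrichment among SV-associated over-expression.

    OE-class pairs: the gene's 1 Mb mRNA scan p < 0.01 (corrected) and the
    tumor's expression > +0.4 SD. All OE-class pairs are annotated; the
    comparison background is a seeded subsample of the remaining pairs.
    """
    config = config or RunConfig()
    sig = assoc_mrna[(assoc_mrna["region"] == "flank_1mb")
                     & (assoc_mrna["p_two_sided"] < 0.01)]
    sig_genes = set(sig["feature_id"])
    prov = matrices["flank_1mb"].provenance
    mrna = norm["mrna"].values
    gene_map = {g.gene_id: g for g in cohort.genes}
    be_index = {}
    for be in breakends_from_calls(cohort.svs):
        be_index.setdefault((be.sample_id, be.sv_id), []).append(be)

    pairs = prov.drop_duplicates(["gene_id", "sample_id"])
    is_oe = []
    for r in pairs.itertuples(index=False):
        v = (mrna.at[r.gene_id, r.sample_id]
             if r.gene_id in mrna.index else np.nan)
        is_oe.append(bool(r.gene_id in sig_genes and not np.isnan(v)
                          and v > config.oe_sd))
    pairs = pairs.assign(oe_class=is_oe)
    rng = np.random.default_rng(seed)
    bg = pairs[~pairs["oe_class"]]
    if len(bg) > max_background_pairs:
        bg = bg.iloc[np.sort(rng.choice(len(bg), max_background_pairs,
                                        replace=False))]
    use = pd.concat([pairs[pairs["oe_class"]], bg], ignore_index=True)

    sv_by_id = {}
    for sv in cohort.svs:
        sv_by_id[(sv.sample_id, sv.sv_id)] = sv
    rows = []
    for r in use.itertuples(index=False):
        gene = gene_map[r.gene_id]
        sv = sv_by_id.get((r.sample_id, r.sv_id))
        bes = be_index.get((r.sample_id, r.sv_id), [])
        near = [b for b in bes if b.chrom == gene.chrom]
        near = min(near, key=lambda b: abs(b.pos - gene.anchor),
                   default=None)
        tad = mechanisms.tad_disrupting(sv, cohort.tads) if sv else None
        hij, hij_d = (mechanisms.enhancer_hijack(
            near, gene, cohort.enhancers, config.enh_scan, config.enh_ref)
            if near is not None else (False, np.nan))
        retro, rclass = (mechanisms.retro_translocation(
            near, cohort.repeats, config.retro_scan)
            if near is not None
            and abs(near.pos - gene.anchor) <= config.retro_scan
            else (False, ""))
        rows.append({"gene_id": r.gene_id, "sample_id": r.sample_id,
                     "sv_id": r.sv_id, "oe_class": r.oe_class,
                     "tad_disrupting": tad, "enhancer_hijack": hij,
                     "enhancer_distance": hij_d, "retro_hijack": retro,
                     "retro_class": rclass})
    ann = pd.DataFrame(rows)
    enrich = {
        name: mechanisms.mechanism_enrichment(ann[name].fillna(False),
                                              ann["oe_class"])
        for name in ("tad_disrupting", "enhancer_hijack", "retro_hijack")
    }
    return {"annotations": ann, "enrichment": enrich}


def protein_else_mrna(norm: dict) -> pd.DataFrame:
    """Expression matrix taking protein where observed, else mRNA."""
    prot = norm["protein"].values
    mrna = norm["mrna"].values
    genes = prot.index.union(mrna.index, sort=False)
    p = prot.reindex(index=genes, columns=mrna.columns)
    m = mrna.reindex(index=genes, columns=mrna.columns)
    return p.where(p.notna(), m)


def stage_pathways(cohort: Cohort, norm: dict, matrices: dict,
                   fusion_events: pd.DataFrame | None = None,
                   config: RunConfig | None = None) -> dict:
    config = config or RunConfig()
    defs = [pathways.PathwayDef(name, tuple(
        (r.gene_id, r.role) for r in sub.itertuples(index=False)))
        for name, sub in cohort.pathways.groupby("pathway", sort=True)]
    samples = [r.sample_id for r in cohort.samples]
    expr = protein_else_mrna(norm)
    fusion_pairs = set()
    if fusion_events is not None:
        supported = fusion_events[
            (fusion_events["sv_support"] != "none")
            & (fusion_events["expr_category"] != "none")]
        for r in supported.itertuples(index=False):
            fusion_pairs.add((r.sample_id, r.gene5))
            fusion_pairs.add((r.sample_id, r.gene3))
    status_frames, calls_all = [], []
    for pdef in defs:
        calls = pathways.call_gene_alterations(
            pdef, samples, cohort.mutations, fusion_pairs, norm["cna"],
            matrices["flank_1mb"].values, matrices["gene_body"].values,
            expr, config.oe_sd)
        calls_all.extend(calls)
        status_frames.append(pathways.tabulate_pathway(pdef, calls,
                                                       samples))
    status = pd.concat(status_frames, ignore_index=True)
    enrich = pathways.pathway_type_enrichment(
        status, cohort.cancer_types().to_dict())
    return {"status": status, "calls": calls_all, "enrichment": enrich}


def stage_survival(cohort: Cohort, norm: dict, gene_subset=None,
                   config: RunConfig | None = None) -> dict:
    config = config or RunConfig()
    genes = cohort.genes
    if gene_subset is not None:
        wanted = set(gene_subset)
        genes = [g for g in genes if g.gene_id in wanted]
    bes = breakends_from_calls(cohort.svs)
    bp_scan = survival.breakpoint_survival_scan(
        bes, genes, cohort.samples, norm["cna"],
        config.flank_window, config.survival_cap_months)
    expr = Matrix(norm["mrna"].values.loc[[g.gene_id for g in genes]])
    expr_scan = survival.expression_survival_scan(
        expr, cohort.samples, config.survival_cap_months)
    return {"breakpoint": bp_scan, "expression": expr_scan}


def stage_depmap(cohort: Cohort, config: RunConfig | None = None,
                 seed: int = 0) -> dict:
    config = config or RunConfig()
    bes = breakends_from_calls(cohort.line_svs)
    panel_ids = set(cohort.line_protein.values.index)
    panel_genes = [g for g in cohort.genes if g.gene_id in panel_ids]
    events = depmap.call_events(bes, panel_genes, cohort.line_protein,
                                cohort.gene_effect, config.flank_window,
                                config.oe_sd, config.effect_cut)
    overlap = depmap.overlap_test(events)
    recur = depmap.recurrence_filter(events, config.min_lines,
                                     config.min_line_frac)
    variability = cohort.gene_effect.std(axis=1, ddof=0)
    return {"events": events, "overlap": overlap, "recurrence": recur,
            "variability": variability}
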