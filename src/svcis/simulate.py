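"""Synthetic multi-omic cohort with planted, recorded ground truth.

The generator emulates the statistical structure of a pan-cancer
WGS-plus-proteogenomics compendium on a toy genome (4 chromosomes of
50 Mb, 2000 evenly spaced genes): sparse somatic SV breakpoints (each
planted gene has nearby breakpoints in 0.5-4% of tumors), cis-effects
planted in SD-from-median units against per-cancer-type backgrounds,
CNA-coupled confounder SVs with no direct cis effect, fusion transcripts
with chimeric-call and within-gene breakpoint support, enhancer / LINE-SINE
/ low-methylation-region translocations, exponential survival with
expression-linked hazards, and a small cell-line panel with CRISPR
gene-effect scores. Every planted effect is recorded in a truth list and
realized in the emitted files (checked by :func:`audit_truth`).

Cohort-level layout decisions (fixed so truths are placeable): enhancer
annotations live on chr3/chr4 only, so chr1 genes have no native enhancer
within 1 Mb; the low-methylation donor region sits on chr4 at 10.0-10.3 Mb;
all planted genes are drawn from chr1/chr2 index blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GeneModel, Matrix, SampleRecord, SVCall, write_gene_bed,
                 write_bed_intervals, write_matrix_tsv, write_samples_tsv,
                 write_sv_bedpe, write_table_tsv, read_sv_bedpe,
                 read_gene_bed, read_bed_intervals, read_matrix_tsv,
                 read_samples_tsv, read_table_tsv)

CHROMS = ("chr1", "chr2", "chr3", "chr4")
CHROM_LEN = 50_000_000
GENES_PER_CHROM = 500
GENE_SPACING = 100_000
GENE_LEN = 20_000

LOW_METH_REGION = ("chr4", 10_000_000, 10_300_000)


def planted_blocks(n_genes: int = 2000) -> dict:
    """Gene-index blocks for each planted-effect family.

    Genes whose recovery depends on their own breakpoint window (cis
    effects, CNA confounders, survival genes) sit on a 21-gene (2.1 Mb)
    grid so that no two share any part of their 1 Mb anchor windows.
    Enhancer-hijack genes live on chr1, which carries no enhancer
    annotation, so the "no native enhancer within 1 Mb" precondition holds
    by construction. Fusion partners and dependency genes do not need
    clean windows and use fixed off-grid blocks.
    """
    per = n_genes // len(CHROMS)

    def chrom_slots(c):
        return [c * per + 20 + 21 * k for k in range(per)
                if 20 + 21 * k < per]

    s1, s2, s3, s4 = (chrom_slots(c) for c in range(len(CHROMS)))
    return {
        "hijack": s1[0:6],
        "retro": s1[6:12],
        "meth": s1[12:18],
        "survival": s1[18:23] + s2[20:23] + s3[20:22],
        "cis_up": s2[0:20],
        "cis_down": s3[0:20],
        "confounder": s4[0:20],
        "fusion5": list(range(300, 312)),            # chr1
        "fusion3": list(range(per + 300, per + 312)),  # chr2
        "dependency": list(range(10, 18)),           # cell-line panel genes
        # genes carrying methylation probes: a null block plus the planted
        # methylation-transfer genes
        "probe_genes": list(range(0, 100)) + s1[12:18],
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 600
    n_cancer_types: int = 6
    n_genes: int = 2000
    # Poisson mean breakends per tumor; 4 breakends over the 200 Mb toy
    # genome reproduces the real-data sparsity of a few percent of tumors
    # with a breakpoint within 1 Mb of any given gene
    bp_rate: float = 4.0
    noise_sd: float = 1.0            # total expression noise, SD units
    cna_slope: float = 0.5           # expression SD per absolute copy - 2
    protein_missing_rate: float = 0.15
    mrna_missing_rate: float = 0.02
    frac_low_obs_genes: float = 0.1  # genes with protein in < min_obs tumors
    missing_mode: str = "mcar"       # or "abundance"
    # planted-effect counts (0 disables a family)
    n_cis_up: int = 20
    n_cis_down: int = 20
    cis_effect_range: tuple = (1.5, 2.5)
    cis_prevalence_range: tuple = (0.02, 0.04)
    n_confounders: int = 20
    n_fusions: int = 12
    n_hijack: int = 6
    n_retro: int = 6
    n_meth: int = 6
    n_survival: int = 10
    n_dependency: int = 8
    planted_oe: float = 2.0          # OE bump for fusion/hijack/retro/meth
    # survival
    baseline_hazard: float = np.log(2) / 40.0   # per month
    signature_hr: float = 2.0        # per unit signature score
    breakpoint_hr: float = 2.0       # carrier vs non-carrier
    survival_prevalence: float = 0.05
    censor_max_months: float = 150.0
    duplicate_patient_pairs: int = 7
    # cell lines
    n_cell_lines: int = 60
    panel_size: int = 200
    dependency_lines: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_genes != 2000 and self.n_genes % len(CHROMS):
            raise ValueError("n_genes must be divisible by 4")
        lo, hi = self.cis_prevalence_range
        if not (0.005 <= lo <= hi <= 0.04):
            raise ValueError("cis prevalence must stay within 0.5%-4% "
                             "of samples")


@dataclass
class TruthRecord:
    kind: str
    gene_id: str
    sample_ids: list
    effect_size: float
    sv_ids: list = field(default_factory=list)
    gene2: str = ""
    details: dict = field(default_factory=dict)


@dataclass
class PlantedTruth:
    records: list

    def by_kind(self, kind: str):
        return [r for r in self.records if r.kind == kind]

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(r) for r in self.records], fh,
                      indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls([TruthRecord(**r) for r in json.load(fh)])


@dataclass
class Cohort:
    """In-memory synthetic bundle (every file the pipeline reads)."""

    config: SimConfig
    genes: list
    samples: list                    # SampleRecord, clinical included
    svs: list                        # SVCall
    protein: Matrix                  # raw (pre-normalization) log-scale
    mrna: Matrix
    phospho: Matrix
    phospho_sites: pd.DataFrame      # site -> gene map
    cna_copies: pd.DataFrame         # absolute copies
    meth_beta: pd.DataFrame
    probe_annotation: pd.DataFrame
    mutations: pd.DataFrame          # MAF-lite
    fusion_candidates: pd.DataFrame
    enhancers: pd.DataFrame
    repeats: pd.DataFrame
    tads: pd.DataFrame
    pathways: pd.DataFrame
    line_protein: Matrix
    line_svs: list
    gene_effect: pd.DataFrame

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_bed(self.genes, outdir / "genes.bed")
        write_samples_tsv(self.samples, outdir / "samples.tsv")
        write_sv_bedpe(self.svs, outdir / "sv.bedpe")
        write_matrix_tsv(self.protein, outdir / "protein_raw.tsv", "gene_id")
        write_matrix_tsv(self.mrna, outdir / "mrna_raw.tsv", "gene_id")
        write_matrix_tsv(self.phospho, outdir / "phospho_raw.tsv", "site_id")
        write_table_tsv(self.phospho_sites, outdir / "phospho_sites.tsv")
        write_matrix_tsv(self.cna_copies, outdir / "cna_copies.tsv",
                         "gene_id")
        write_matrix_tsv(self.meth_beta, outdir / "methylation_beta.tsv",
                         "probe_id")
        write_table_tsv(self.probe_annotation,
                        outdir / "probe_annotation.tsv")
        write_table_tsv(self.mutations, outdir / "maf.tsv")
        write_table_tsv(self.fusion_candidates,
                        outdir / "fusion_candidates.tsv")
        write_bed_intervals(self.enhancers, outdir / "enhancers.bed")
        write_bed_intervals(self.repeats, outdir / "repeats.bed")
        write_bed_intervals(self.tads, outdir / "tads.bed")
        write_table_tsv(self.pathways, outdir / "pathways.tsv")
        write_matrix_tsv(self.line_protein, outdir / "line_protein.tsv",
                         "gene_id")
        write_sv_bedpe(self.line_svs, outdir / "line_sv.bedpe")
        write_matrix_tsv(self.gene_effect, outdir / "gene_effect.tsv",
                         "gene_id")

    @classmethod
    def read(cls, outdir, config: SimConfig | None = None):
        outdir = Path(outdir)
        return cls(
            config=config or SimConfig(),
            genes=read_gene_bed(outdir / "genes.bed"),
            samples=read_samples_tsv(outdir / "samples.tsv"),
            svs=read_sv_bedpe(outdir / "sv.bedpe"),
            protein=read_matrix_tsv(outdir / "protein_raw.tsv"),
            mrna=read_matrix_tsv(outdir / "mrna_raw.tsv"),
            phospho=read_matrix_tsv(outdir / "phospho_raw.tsv"),
            phospho_sites=read_table_tsv(outdir / "phospho_sites.tsv"),
            cna_copies=read_matrix_tsv(outdir / "cna_copies.tsv").values,
            meth_beta=read_matrix_tsv(outdir / "methylation_beta.tsv").values,
            probe_annotation=read_table_tsv(outdir / "probe_annotation.tsv"),
            mutations=read_table_tsv(outdir / "maf.tsv"),
            fusion_candidates=read_table_tsv(outdir / "fusion_candidates.tsv"),
            enhancers=read_bed_intervals(outdir / "enhancers.bed"),
            repeats=read_bed_intervals(outdir / "repeats.bed"),
            tads=read_bed_intervals(outdir / "tads.bed"),
            pathways=read_table_tsv(outdir / "pathways.tsv"),
            line_protein=read_matrix_tsv(outdir / "line_protein.tsv"),
            line_svs=read_sv_bedpe(outdir / "line_sv.bedpe"),
            gene_effect=read_matrix_tsv(outdir / "gene_effect.tsv").values,
        )

    def cancer_types(self) -> pd.Series:
        return pd.Series({r.sample_id: r.cancer_type for r in self.samples})

    def groups(self) -> pd.Series:
        return pd.Series({r.sample_id: f"{r.cancer_type}|{r.batch}"
                          for r in self.samples})


def make_genes(n_genes: int = 2000) -> list:
    genes = []
    per_chrom = n_genes // len(CHROMS)
    for i in range(n_genes):
        chrom = CHROMS[i // per_chrom]
        idx = i % per_chrom
        start = idx * GENE_SPACING + 40_000
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"gene{i:04d}", chrom, start,
                               start + GENE_LEN, strand))
    return genes


def _upstream_pos(gene: GeneModel, offset: int) -> int:
    """Position ``offset`` bp 5' of the transcription start (strand-aware)."""
    if gene.strand == "+":
        return max(0, gene.anchor - offset)
    return gene.anchor + offset


def _partner_sv(rng, sample_id, sv_id, chrom, pos, sv_class="TRA",
                mate=None) -> SVCall:
    """SV with one fixed breakend; the mate defaults to a random distal
    locus (log-uniform span or a translocation)."""
    if mate is None:
        if rng.random() < 0.2:
            mchrom = CHROMS[rng.integers(len(CHROMS))]
            mpos = int(rng.integers(0, CHROM_LEN))
        else:
            mchrom = chrom
            span = int(10_000 * 10 ** (rng.random() * 3))  # 10 kb - 10 Mb
            mpos = min(CHROM_LEN - 1, pos + span)
        mate = (mchrom, mpos, "+" if rng.random() < 0.5 else "-")
    return SVCall(sample_id, chrom, int(pos),
                  "+" if rng.random() < 0.5 else "-",
                  mate[0], int(mate[1]), mate[2], sv_class, "sim", sv_id)


def _pick_carriers(rng, n_samples: int, count: int) -> list:
    return sorted(rng.choice(n_samples, size=count, replace=False).tolist())


def generate_cohort(config: SimConfig | None = None):
    """Build the full synthetic bundle; returns (Cohort, PlantedTruth)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    blocks = planted_blocks(g)
    genes = make_genes(g)
    gene_ids = [x.gene_id for x in genes]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- samples: cancer types in contiguous blocks; one type split into
    # two batches; a few patients contribute two tumors -------------------
    per_type = n // cfg.n_cancer_types
    ctypes = [f"ct{min(i // per_type, cfg.n_cancer_types - 1)}"
              for i in range(n)]
    batches = []
    for i, ct in enumerate(ctypes):
        if ct == "ct0" and i >= per_type // 2:
            batches.append("ct0_b2")
        else:
            batches.append(f"{ct}_b1")
    patients = []
    pid = 0
    i = 0
    while i < n:
        if pid < cfg.duplicate_patient_pairs and i + 1 < n:
            patients += [f"P{pid:04d}", f"P{pid:04d}"]
            i += 2
        else:
            patients.append(f"P{pid:04d}")
            i += 1
        pid += 1
    patients = patients[:n]

    # --- background SVs --------------------------------------------------
    svs: list[SVCall] = []
    sv_counter = 0

    def new_sv(sample_id, chrom, pos, sv_class="TRA", mate=None) -> SVCall:
        nonlocal sv_counter
        sv = _partner_sv(rng, sample_id, f"sv{sv_counter:06d}", chrom, pos,
                         sv_class, mate)
        sv_counter += 1
        svs.append(sv)
        return sv

    classes = np.array(["DEL", "DUP", "INV", "TRA", "INS"])
    for si, s in enumerate(sample_ids):
        k = rng.poisson(cfg.bp_rate / 2.0)
        for _ in range(k):
            chrom = CHROMS[rng.integers(len(CHROMS))]
            pos = int(rng.integers(0, CHROM_LEN))
            new_sv(s, chrom, pos, str(classes[rng.integers(len(classes))]))

    # --- CNA: absolute copies, diploid background + random noise ---------
    copies = np.full((g, n), 2.0)
    n_noise = max(1, int(0.02 * g))
    for si in range(n):
        idx = rng.choice(g, size=n_noise, replace=False)
        copies[idx, si] = rng.choice([1.0, 3.0, 4.0], size=n_noise)

    # --- expression backbone ---------------------------------------------
    type_index = pd.Categorical(ctypes).codes
    ct_offset = rng.normal(0, 0.5, size=(g, cfg.n_cancer_types))
    shared = rng.normal(0, 0.7 * cfg.noise_sd, size=(g, n))
    protein = (ct_offset[:, type_index] + shared
               + rng.normal(0, 0.7 * cfg.noise_sd, size=(g, n)))
    mrna = (ct_offset[:, type_index] + shared
            + rng.normal(0, 0.7 * cfg.noise_sd, size=(g, n)))

    truth: list[TruthRecord] = []
    gid = {gidx: genes[gidx] for gidx in range(g)}

    def plant_bp(gene: GeneModel, sample_id: str, max_offset: int,
                 upstream_only=False, body=False, sv_class="TRA",
                 mate=None):
        if body:
            pos = int(rng.integers(gene.start + 100, gene.end - 100))
        elif upstream_only:
            pos = _upstream_pos(gene, int(rng.integers(1_000, max_offset)))
        else:
            off = int(rng.integers(-max_offset, max_offset))
            pos = max(0, gene.anchor + off)
        return new_sv(sample_id, gene.chrom, pos, sv_class, mate)

    # --- planted cis effects ---------------------------------------------
    lo_e, hi_e = cfg.cis_effect_range
    lo_p, hi_p = cfg.cis_prevalence_range
    for sign, block, count in ((1.0, blocks["cis_up"], cfg.n_cis_up),
                               (-1.0, blocks["cis_down"], cfg.n_cis_down)):
        for j, gidx in enumerate(block):
            if j >= count:
                break
            gene = gid[gidx]
            effect = sign * rng.uniform(lo_e, hi_e)
            prev = rng.uniform(lo_p, hi_p)
            carriers = _pick_carriers(rng, n, max(3, round(prev * n)))
            sv_ids = []
            for si in carriers:
                sv = plant_bp(gene, sample_ids[si], 900_000)
                sv_ids.append(sv.sv_id)
                protein[gidx, si] += effect
                mrna[gidx, si] += effect
            truth.append(TruthRecord(
                "cis_up" if sign > 0 else "cis_down", gene.gene_id,
                [sample_ids[si] for si in carriers], effect, sv_ids))

    # --- CNA-only confounders: SVs always co-occur with copy gain, zero
    # direct cis effect; extra CNA-gain samples without SVs break exact
    # collinearity between the breakpoint and CNA terms --------------------
    for j, gidx in enumerate(blocks["confounder"]):
        if j >= cfg.n_confounders:
            break
        gene = gid[gidx]
        carriers = _pick_carriers(rng, n, max(3, round(0.03 * n)))
        others = [si for si in _pick_carriers(rng, n, round(0.06 * n))
                  if si not in carriers][:round(0.03 * n)]
        sv_ids = []
        for si in carriers:
            sv = plant_bp(gene, sample_ids[si], 800_000, sv_class="DUP")
            sv_ids.append(sv.sv_id)
            copies[gidx, si] = rng.choice([4.0, 5.0])
        for si in others:
            copies[gidx, si] = rng.choice([4.0, 5.0])
        truth.append(TruthRecord(
            "cna_only_confounder", gene.gene_id,
            [sample_ids[si] for si in carriers], 0.0, sv_ids,
            details={"cna_samples": [sample_ids[si] for si in others]}))

    # --- fusions: chimeric call + within-gene breakends + OE --------------
    fusion_rows = []
    for j, (g5i, g3i) in enumerate(zip(blocks["fusion5"], blocks["fusion3"])):
        if j >= cfg.n_fusions:
            break
        g5, g3 = gid[g5i], gid[g3i]
        carriers = _pick_carriers(rng, n, 4)
        sv_ids = []
        for si in carriers:
            s = sample_ids[si]
            pos5 = int(rng.integers(g5.start + 100, g5.end - 100))
            pos3 = int(rng.integers(g3.start + 100, g3.end - 100))
            sv = new_sv(s, g5.chrom, pos5, "TRA", (g3.chrom, pos3, "-"))
            sv_ids.append(sv.sv_id)
            for gi in (g5i, g3i):
                protein[gi, si] += cfg.planted_oe
                mrna[gi, si] += cfg.planted_oe
            for caller in ("callerA", "callerB"):
                fusion_rows.append((s, g5.gene_id, g3.gene_id, caller,
                                    "high", 0))
        truth.append(TruthRecord(
            "fusion", g5.gene_id, [sample_ids[si] for si in carriers],
            cfg.planted_oe, sv_ids, gene2=g3.gene_id))

    # decoy candidates: low-confidence identities, an intergenic call and
    # an unsupported pair (no SV, no planted OE)
    decoys = [
        (sample_ids[0], "gene0750", "gene0760", "callerB", "low", 0),
        (sample_ids[1], "gene0750", "gene0760", "callerB", "low", 0),
        (sample_ids[2], "gene0770", "gene0780", "callerB", "low", 0),
        (sample_ids[3], "gene0770", "gene0780", "callerB", "high", 0),
        (sample_ids[4], "gene0790", "gene0795", "callerA", "high", 1),
        # kept but unsupported: no SV, no planted over-expression
        (sample_ids[5], "gene0820", "gene0830", "callerA", "high", 0),
    ]
    fusion_rows.extend(decoys)
    fusion_candidates = pd.DataFrame(
        fusion_rows, columns=["sample_id", "gene5", "gene3", "caller",
                              "confidence", "intergenic"])

    # --- annotation tracks ------------------------------------------------
    enh_rows = []
    for chrom in ("chr3", "chr4"):
        for _ in range(120):
            s0 = int(rng.integers(0, CHROM_LEN - 2_000))
            enh_rows.append((chrom, s0, s0 + 1_000, "enhancer"))
    enhancers = (pd.DataFrame(enh_rows,
                              columns=["chrom", "start", "end", "name"])
                 .sort_values(["chrom", "start"]).reset_index(drop=True))
    rep_rows = []
    for chrom in ("chr3", "chr4"):
        for _ in range(150):
            s0 = int(rng.integers(0, CHROM_LEN - 10_000))
            klass = "LINE" if rng.random() < 0.5 else "SINE"
            rep_rows.append((chrom, s0, s0 + int(rng.integers(300, 6_000)),
                             klass))
    repeats = (pd.DataFrame(rep_rows,
                            columns=["chrom", "start", "end", "name"])
               .sort_values(["chrom", "start"]).reset_index(drop=True))
    tad_rows = [(chrom, i * 1_000_000, (i + 1) * 1_000_000,
                 f"TAD_{chrom}_{i}")
                for chrom in CHROMS for i in range(CHROM_LEN // 1_000_000)]
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "name"])

    # --- enhancer hijacking: breakend upstream of an enhancer-free gene,
    # mate retaining a chr4 enhancer within the scan window ---------------
    chr4_enh = enhancers[enhancers["chrom"] == "chr4"].reset_index(drop=True)
    for j, gidx in enumerate(blocks["hijack"]):
        if j >= cfg.n_hijack:
            break
        gene = gid[gidx]
        carriers = _pick_carriers(rng, n, 4)
        sv_ids = []
        for si in carriers:
            enh = chr4_enh.iloc[int(rng.integers(len(chr4_enh)))]
            mate_pos = int(enh["end"] - 1 + rng.integers(5_000, 100_000))
            pos = _upstream_pos(gene, int(rng.integers(20_000, 200_000)))
            sv = new_sv(sample_ids[si], gene.chrom, pos, "TRA",
                        ("chr4", mate_pos, "+"))
            sv_ids.append(sv.sv_id)
            protein[gidx, si] += cfg.planted_oe
            mrna[gidx, si] += cfg.planted_oe
        truth.append(TruthRecord(
            "enhancer_hijack", gene.gene_id,
            [sample_ids[si] for si in carriers], cfg.planted_oe, sv_ids))

    # --- retrotransposon translocation: same shape, 20 kb windows ---------
    chr4_line = repeats[(repeats["chrom"] == "chr4")
                        & (repeats["name"] == "LINE")].reset_index(drop=True)
    for j, gidx in enumerate(blocks["retro"]):
        if j >= cfg.n_retro:
            break
        gene = gid[gidx]
        carriers = _pick_carriers(rng, n, 4)
        sv_ids = []
        for si in carriers:
            rep = chr4_line.iloc[int(rng.integers(len(chr4_line)))]
            mate_pos = int(rep["end"] - 1 + rng.integers(500, 10_000))
            pos = _upstream_pos(gene, int(rng.integers(1_000, 15_000)))
            sv = new_sv(sample_ids[si], gene.chrom, pos, "TRA",
                        ("chr4", mate_pos, "+"))
            sv_ids.append(sv.sv_id)
            protein[gidx, si] += cfg.planted_oe
            mrna[gidx, si] += cfg.planted_oe
        truth.append(TruthRecord(
            "retro_hijack", gene.gene_id,
            [sample_ids[si] for si in carriers], cfg.planted_oe, sv_ids,
            details={"element_class": "LINE"}))

    # --- methylation probes and beta matrix -------------------------------
    probe_rows = []
    for gidx in blocks["probe_genes"]:
        gene = gid[gidx]
        probe_rows.append((f"cg_{gene.gene_id}_p", gene.chrom,
                           max(0, gene.anchor - 200), 1, gene.gene_id,
                           "TSS200"))
        probe_rows.append((f"cg_{gene.gene_id}_b", gene.chrom,
                           (gene.start + gene.end) // 2, 1, gene.gene_id,
                           "body"))
    lm_chrom, lm_lo, lm_hi = LOW_METH_REGION
    for k in range(12):
        pos = lm_lo + k * (lm_hi - lm_lo) // 12
        probe_rows.append((f"cg_lowmeth_{k:02d}", lm_chrom, pos, 1, ".",
                           "body"))
    for k in range(20):   # non-CGI decoys, dropped by the probe filter
        probe_rows.append((f"cg_open_{k:02d}", "chr2",
                           int(rng.integers(0, CHROM_LEN)), 0, ".", "body"))
    probe_annotation = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "cgi_flag",
                             "gene_id", "position_category"])
    p_ids = probe_annotation["probe_id"].tolist()
    base = np.empty(len(p_ids))
    for i, row in enumerate(probe_annotation.itertuples(index=False)):
        if row.probe_id.startswith("cg_lowmeth"):
            base[i] = rng.uniform(0.05, 0.15)
        elif row.position_category == "TSS200":
            base[i] = rng.uniform(0.5, 0.8)
        else:
            base[i] = rng.uniform(0.3, 0.6)
    beta = np.clip(base[:, None] + rng.normal(0, 0.05, (len(p_ids), n)),
                   0.01, 0.99)
    meth_beta = pd.DataFrame(beta, index=pd.Index(p_ids, name="probe_id"),
                             columns=sample_ids)

    # --- methylation-region transfer: rearranged low-meth region + per-
    # sample CGI hypomethylation + over-expression -------------------------
    for j, gidx in enumerate(blocks["meth"]):
        if j >= cfg.n_meth:
            break
        gene = gid[gidx]
        carriers = _pick_carriers(rng, n, 4)
        sv_ids = []
        probe = f"cg_{gene.gene_id}_p"
        for si in carriers:
            mate_pos = lm_hi + 50_000
            pos = _upstream_pos(gene, int(rng.integers(5_000, 80_000)))
            sv = new_sv(sample_ids[si], gene.chrom, pos, "TRA",
                        (lm_chrom, mate_pos, "+"))
            sv_ids.append(sv.sv_id)
            meth_beta.loc[probe, sample_ids[si]] = 0.08
            protein[gidx, si] += cfg.planted_oe
            mrna[gidx, si] += cfg.planted_oe
        truth.append(TruthRecord(
            "meth_transfer", gene.gene_id,
            [sample_ids[si] for si in carriers], cfg.planted_oe, sv_ids,
            details={"probe_id": probe}))

    # --- survival: correlated signature + breakpoint-linked hazards -------
    sig_factor = rng.normal(0, 1, n)
    surv_gene_ids = []
    surv_carrier_sets = []
    for j, gidx in enumerate(blocks["survival"]):
        if j >= cfg.n_survival:
            break
        gene = gid[gidx]
        surv_gene_ids.append(gene.gene_id)
        base_expr = 0.8 * sig_factor + 0.6 * rng.normal(0, 1, n)
        protein[gidx, :] = ct_offset[gidx, type_index] + base_expr
        mrna[gidx, :] = ct_offset[gidx, type_index] + base_expr \
            + rng.normal(0, 0.3, n)
        carriers = _pick_carriers(rng, n,
                                  round(cfg.survival_prevalence * n))
        sv_ids = []
        for si in carriers:
            # hazard-linked breakpoints sit close to the gene so the
            # log-distance covariate separates carriers from the ceiling
            sv = plant_bp(gene, sample_ids[si], 100_000)
            sv_ids.append(sv.sv_id)
            protein[gidx, si] += 1.5
            mrna[gidx, si] += 1.5
        surv_carrier_sets.append(set(carriers))
        truth.append(TruthRecord(
            "survival_gene", gene.gene_id,
            [sample_ids[si] for si in carriers],
            np.log(cfg.breakpoint_hr), sv_ids))

    sig_rows = [gene_ids.index(gidx) for gidx in surv_gene_ids]
    score = protein[sig_rows, :].mean(axis=0) if sig_rows else np.zeros(n)
    log_h = np.log(cfg.baseline_hazard) \
        + np.log(cfg.signature_hr) * score
    for carriers in surv_carrier_sets:
        for si in carriers:
            log_h[si] += np.log(cfg.breakpoint_hr)
    # two tumors of one patient share the patient's survival outcome
    t_event = rng.exponential(1.0 / np.exp(log_h))
    t_censor = rng.uniform(0, cfg.censor_max_months, n)
    os_months = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    first_of_patient: dict[str, int] = {}
    for i, p in enumerate(patients):
        if p in first_of_patient:
            j0 = first_of_patient[p]
            os_months[i] = os_months[j0]
            os_event[i] = os_event[j0]
        else:
            first_of_patient[p] = i

    samples = [SampleRecord(sample_ids[i], patients[i], ctypes[i],
                            batches[i], float(round(os_months[i], 3)),
                            int(os_event[i]))
               for i in range(n)]

    # --- CNA-coupled expression term then analyte missingness -------------
    protein = protein + cfg.cna_slope * (copies - 2.0)
    mrna = mrna + cfg.cna_slope * (copies - 2.0)

    planted_idx = sorted(set().union(
        blocks["cis_up"], blocks["cis_down"], blocks["confounder"], blocks["fusion5"],
        blocks["fusion3"], blocks["hijack"], blocks["retro"], blocks["meth"],
        blocks["survival"], blocks["dependency"]))
    eligible_low = np.array([i for i in range(g) if i not in planted_idx])
    n_low = int(cfg.frac_low_obs_genes * g)
    low_obs = rng.choice(eligible_low, size=n_low, replace=False)

    if cfg.missing_mode == "abundance":
        abundance = rng.normal(0, 1, g)
        pmiss = 1.0 / (1.0 + np.exp((abundance[:, None]
                                     + 1.7) / 0.8))
        pmiss = np.broadcast_to(pmiss, (g, n)).copy()
        pmiss *= cfg.protein_missing_rate / max(pmiss.mean(), 1e-9)
        pmiss = np.clip(pmiss, 0, 0.95)
        prot_missing = rng.random((g, n)) < pmiss
    else:
        prot_missing = rng.random((g, n)) < cfg.protein_missing_rate
    for gi in low_obs:
        keep = rng.random(n) < 0.3
        prot_missing[gi, ~keep] = True
    mrna_missing = rng.random((g, n)) < cfg.mrna_missing_rate
    protein = np.where(prot_missing, np.nan, protein)
    mrna = np.where(mrna_missing, np.nan, mrna)

    protein_m = Matrix(pd.DataFrame(
        protein, index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids))
    mrna_m = Matrix(pd.DataFrame(
        mrna, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids))

    # --- phospho: sites track their parent protein with extra noise -------
    site_rows = []
    ph_vals = []
    for gi in range(150):
        for k in (1, 2):
            site = f"{gene_ids[gi]}_S{k}"
            site_rows.append((site, gene_ids[gi]))
            ph_vals.append(np.where(
                prot_missing[gi], np.nan,
                np.nan_to_num(protein[gi]) + rng.normal(0, 0.5, n)))
    phospho_sites = pd.DataFrame(site_rows, columns=["site_id", "gene_id"])
    phospho = Matrix(pd.DataFrame(
        np.array(ph_vals),
        index=pd.Index(phospho_sites["site_id"], name="site_id"),
        columns=sample_ids))

    cna_copies = pd.DataFrame(copies,
                              index=pd.Index(gene_ids, name="gene_id"),
                              columns=sample_ids)

    # --- MAF-lite + pathway definitions ------------------------------------
    onc_genes = [gid[i].gene_id for i in blocks["cis_up"][:4]]
    tsg_genes = [gid[i].gene_id for i in blocks["cis_down"][:4]]
    path_rows = ([("RTK_like", x, "oncogene") for x in onc_genes]
                 + [("p53Rb_like", x, "tsg") for x in tsg_genes])
    pathways_df = pd.DataFrame(path_rows,
                               columns=["pathway", "gene_id", "role"])
    mut_rows = []
    vclasses = ["missense", "nonsense", "frameshift_indel", "silent"]
    for _ in range(40):
        s = sample_ids[int(rng.integers(n))]
        gidx = int(rng.integers(g))
        mut_rows.append((s, gene_ids[gidx],
                         vclasses[int(rng.integers(len(vclasses)))],
                         int(rng.random() < 0.2)))
    for x in onc_genes[:2]:   # guaranteed hotspot drivers
        mut_rows.append((sample_ids[int(rng.integers(n))], x,
                         "missense", 1))
    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene_id", "variant_class",
                           "is_hotspot"])

    # --- cell-line panel ---------------------------------------------------
    lines = [f"CL{i:03d}" for i in range(cfg.n_cell_lines)]
    panel = list(range(cfg.panel_size))
    line_prot = rng.normal(0, 1, (len(panel), cfg.n_cell_lines))
    effect = rng.normal(0, 0.15, (len(panel), cfg.n_cell_lines))
    line_svs: list[SVCall] = []
    line_counter = 0

    def new_line_sv(line_id, chrom, pos):
        nonlocal line_counter
        sv = _partner_sv(rng, line_id, f"lsv{line_counter:05d}", chrom, pos)
        line_counter += 1
        line_svs.append(sv)
        return sv

    for li, line in enumerate(lines):
        for _ in range(rng.poisson(3)):
            chrom = CHROMS[rng.integers(len(CHROMS))]
            new_line_sv(line, chrom, int(rng.integers(0, CHROM_LEN)))
    for j, gidx in enumerate(blocks["dependency"]):
        if j >= cfg.n_dependency:
            break
        gene = gid[gidx]
        dep_lines = _pick_carriers(rng, cfg.n_cell_lines,
                                   cfg.dependency_lines)
        sv_ids = []
        for li in dep_lines:
            off = int(rng.integers(-500_000, 500_000))
            sv = new_line_sv(lines[li], gene.chrom,
                             max(0, gene.anchor + off))
            sv_ids.append(sv.sv_id)
            line_prot[gidx, li] = 2.0
            effect[gidx, li] = rng.normal(-0.9, 0.1)
        truth.append(TruthRecord(
            "dependency_gene", gene.gene_id, [lines[li] for li in dep_lines],
            -0.9, sv_ids))

    line_protein = Matrix(pd.DataFrame(
        line_prot, index=pd.Index([gene_ids[i] for i in panel],
                                  name="gene_id"), columns=lines))
    gene_effect = pd.DataFrame(
        effect, index=pd.Index([gene_ids[i] for i in panel],
                               name="gene_id"), columns=lines)

    cohort = Cohort(cfg, genes, samples, svs, protein_m, mrna_m, phospho,
                    phospho_sites, cna_copies, meth_beta, probe_annotation,
                    mutations, fusion_candidates, enhancers, repeats,
                    pd.DataFrame(tad_rows, columns=["chrom", "start", "end",
                                                    "name"]),
                    pathways_df, line_protein, line_svs, gene_effect)
    return cohort, PlantedTruth(truth)


# ---------------------------------------------------------------------------
# Truth audit
# ---------------------------------------------------------------------------

def _gene_lookup(cohort: Cohort) -> dict:
    return {g.gene_id: g for g in cohort.genes}


def _sd_units(values: pd.Series, groups: pd.Series) -> pd.Series:
    """(x - median) / population SD over observed values, within each
    cancer type (mirroring the per-type over-expression definition)."""
    out = values.copy()
    for _, cols in groups.groupby(groups).groups.items():
        sub = values.loc[cols].to_numpy(dtype=float)
        obs = sub[~np.isnan(sub)]
        if obs.size == 0:
            continue
        med = float(np.median(obs))
        sd = float(np.std(obs))
        out.loc[cols] = (values.loc[cols] - med) / (sd if sd > 0 else 1.0)
    return out


def audit_truth(cohort: Cohort, truth: PlantedTruth,
                oe_sd: float = 0.4) -> pd.DataFrame:
    """Check that every planted truth record is realized in the bundle.

    Two families of checks: structural (every carried-by SV id is present
    with a breakend on the right chromosome) and expression-dependent
    (carriers of a planted effect are expression outliers in the planted
    direction, in at least half of the carriers). Returns one row per truth
    record with ``ok`` and a reason for failures.
    """
    genes = _gene_lookup(cohort)
    sv_index = {}
    for sv in cohort.svs:
        sv_index.setdefault(sv.sv_id, []).append(sv)
    line_sv_index = {}
    for sv in cohort.line_svs:
        line_sv_index.setdefault(sv.sv_id, []).append(sv)

    def sv_near(sv_id, gene, window, index) -> bool:
        for sv in index.get(sv_id, ()):  # either breakend may be the near one
            for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
                if chrom == gene.chrom and abs(pos - gene.anchor) <= window:
                    return True
        return False

    ctypes = cohort.cancer_types()

    def oe_fraction(matrix: Matrix, gene_id, sample_ids, sign) -> float:
        if gene_id not in matrix.values.index:
            return 0.0
        z = _sd_units(matrix.values.loc[gene_id], ctypes)
        vals = z.reindex(sample_ids).to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return 0.0
        return float(np.mean(vals * sign > oe_sd))

    rows = []
    for i, rec in enumerate(truth.records):
        ok, reason = True, ""
        gene = genes.get(rec.gene_id)
        if gene is None:
            rows.append({"record": i, "kind": rec.kind,
                         "gene_id": rec.gene_id, "ok": False,
                         "reason": "gene missing"})
            continue
        index = line_sv_index if rec.kind == "dependency_gene" else sv_index
        window = {"retro_hijack": 20_000}.get(rec.kind, 1_000_000)
        missing_sv = [s for s in rec.sv_ids
                      if not sv_near(s, gene, window, index)]
        if rec.kind == "fusion":
            # fusion SVs join the two gene bodies; check the 5' side
            missing_sv = [s for s in rec.sv_ids
                          if not sv_near(s, gene, GENE_LEN, sv_index)]
        if missing_sv:
            ok, reason = False, f"sv not realized: {missing_sv[:3]}"
        if ok and rec.kind in ("cis_up", "cis_down", "fusion",
                               "enhancer_hijack", "retro_hijack",
                               "meth_transfer", "survival_gene"):
            sign = -1.0 if rec.kind == "cis_down" else 1.0
            frac = oe_fraction(cohort.mrna, rec.gene_id, rec.sample_ids,
                               sign)
            if frac < 0.5:
                ok, reason = False, f"carrier outlier fraction {frac:.2f}"
        if ok and rec.kind == "meth_transfer":
            probe = rec.details["probe_id"]
            row = cohort.meth_beta.loc[probe]
            med = float(row.median())
            bad = [s for s in rec.sample_ids if not row[s] < med - 0.2]
            if bad:
                ok, reason = False, f"no beta outlier in {bad[:3]}"
        if ok and rec.kind == "cna_only_confounder":
            cn = cohort.cna_copies.loc[rec.gene_id]
            bad = [s for s in rec.sample_ids if cn[s] < 4]
            if bad:
                ok, reason = False, f"carrier without CNA gain: {bad[:3]}"
        if ok and rec.kind == "dependency_gene":
            prot = cohort.line_protein.values.loc[rec.gene_id]
            med = float(prot.median())
            eff = cohort.gene_effect.loc[rec.gene_id]
            bad = [s for s in rec.sample_ids
                   if not (prot[s] - med > oe_sd and eff[s] < -0.5)]
            if bad:
                ok, reason = False, f"line flags not realized: {bad[:3]}"
        rows.append({"record": i, "kind": rec.kind, "gene_id": rec.gene_id,
                     "ok": ok, "reason": reason})
    return pd.DataFrame(rows)
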