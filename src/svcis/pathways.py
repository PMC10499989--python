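"""Per-tumor gene- and pathway-level somatic alteration tabulation.

Evidence for a (tumor, gene) pair is resolved to exactly one alteration
type in a fixed precedence order: SNV/indel, gene fusion, deep deletion
(thresholded CNA -2), high-level amplification (+2), then SV with altered
expression. The SV-with-expression criterion depends on the gene's role:
oncogenes need a breakpoint within 1 Mb plus expression > +0.4 SD (protein
if observed, else mRNA); tumor suppressors need a breakpoint inside the
gene body plus expression < -0.4 SD. A tumor is "SV-uniquely altered" for
a pathway when its only qualifying alterations among member genes are
SV-associated ones (fusion counts as SV-associated by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_one_sided

ALTERATION_ORDER = ("snv_indel", "fusion", "deep_deletion",
                    "high_amplification", "sv_expression")
INACTIVATING_CLASSES = {"frameshift_indel", "inframe_indel", "nonsense",
                        "nonstop"}


@dataclass(frozen=True)
class PathwayDef:
    name: str
    members: tuple  # of (gene_id, role in {"oncogene", "tsg"})

    def genes(self):
        return [g for g, _ in self.members]

    def role_of(self, gene_id: str) -> str:
        for g, r in self.members:
            if g == gene_id:
                return r
        raise KeyError(gene_id)


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    gene_id: str
    type: str
    detail: str = ""


def read_pathways_tsv(path) -> list[PathwayDef]:
    """Pathway definition TSV: pathway <tab> gene_id <tab> role."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, sub in df.groupby("pathway", sort=True):
        out.append(PathwayDef(name, tuple(
            (r.gene_id, r.role) for r in sub.itertuples(index=False))))
    return out


def qualify_mutation(variant_class: str, is_hotspot: bool, role: str) -> bool:
    """Does a small-mutation record qualify as a driver alteration?

    Oncogenes: hotspot SNVs only (promoter-activating records ship with the
    hotspot flag set). Tumor suppressors: hotspot SNV, or an inactivating
    indel/nonsense/nonstop.
    """
    if role == "oncogene":
        return bool(is_hotspot)
    if role == "tsg":
        return bool(is_hotspot) or variant_class in INACTIVATING_CLASSES
    raise ValueError(f"unknown role {role!r}")


def sv_expression_alteration(bp_flank: float, bp_body: float,
                             expr_value: float, role: str,
                             oe_sd: float = 0.4) -> bool:
    """SV-with-expression criterion for one (tumor, gene).

    ``expr_value`` should already be protein-if-observed-else-mRNA in SD
    units; missing expression disqualifies.
    """
    if expr_value is None or np.isnan(expr_value):
        return False
    if role == "oncogene":
        return bp_flank > 0 and expr_value > oe_sd
    if role == "tsg":
        return bp_body > 0 and expr_value < -oe_sd
    raise ValueError(f"unknown role {role!r}")


def resolve_gene_call(sample_id: str, gene_id: str, *,
                      has_snv_indel: bool, has_fusion: bool,
                      cna_level: float | None,
                      has_sv_expression: bool) -> AlterationCall | None:
    """First satisfied alteration type in the published precedence wins."""
    if has_snv_indel:
        return AlterationCall(sample_id, gene_id, "snv_indel")
    if has_fusion:
        return AlterationCall(sample_id, gene_id, "fusion")
    if cna_level is not None and not np.isnan(cna_level):
        if cna_level == -2:
            return AlterationCall(sample_id, gene_id, "deep_deletion")
        if cna_level == 2:
            return AlterationCall(sample_id, gene_id, "high_amplification")
    if has_sv_expression:
        return AlterationCall(sample_id, gene_id, "sv_expression")
    return None


def call_gene_alterations(pathway: PathwayDef, samples: Sequence[str],
                          mutations: pd.DataFrame,
                          fusion_pairs: set[tuple[str, str]],
                          cna: pd.DataFrame | None,
                          bp_flank: pd.DataFrame, bp_body: pd.DataFrame,
                          expr: pd.DataFrame,
                          oe_sd: float = 0.4) -> list[AlterationCall]:
    """Resolve per-(sample, member-gene) alteration calls for one pathway.

    ``mutations`` is a MAF-lite frame (sample_id, gene_id, variant_class,
    is_hotspot); ``fusion_pairs`` is a set of (sample_id, gene_id);
    ``expr`` is the protein-else-mRNA matrix in SD units.
    """
    mut_idx: dict[tuple[str, str], list] = {}
    for r in mutations.itertuples(index=False):
        mut_idx.setdefault((r.sample_id, r.gene_id), []).append(r)
    calls = []
    for gene_id, role in pathway.members:
        for s in samples:
            recs = mut_idx.get((s, gene_id), [])
            has_mut = any(
                qualify_mutation(r.variant_class, bool(r.is_hotspot), role)
                for r in recs)
            has_fus = (s, gene_id) in fusion_pairs
            level = None
            if cna is not None and gene_id in cna.index \
                    and s in cna.columns:
                level = float(cna.at[gene_id, s])
            flank = (float(bp_flank.at[gene_id, s])
                     if gene_id in bp_flank.index else 0.0)
            body = (float(bp_body.at[gene_id, s])
                    if gene_id in bp_body.index else 0.0)
            ev = (float(expr.at[gene_id, s])
                  if gene_id in expr.index and s in expr.columns
                  else float("nan"))
            has_svx = sv_expression_alteration(flank, body, ev, role, oe_sd)
            call = resolve_gene_call(
                s, gene_id, has_snv_indel=has_mut, has_fusion=has_fus,
                cna_level=level, has_sv_expression=has_svx)
            if call is not None:
                calls.append(call)
    return calls


SV_TYPES_DEFAULT = ("sv_expression", "fusion")


def tabulate_pathway(pathway: PathwayDef, calls: Iterable[AlterationCall],
                     samples: Sequence[str],
                     sv_types: Sequence[str] = SV_TYPES_DEFAULT
                     ) -> pd.DataFrame:
    """Per-sample pathway status.

    A sample is altered iff any member gene has a call; it is SV-uniquely
    altered iff every one of its member-gene calls is of an SV-associated
    type (``sv_types``; fusion included by default).
    """
    member_genes = set(pathway.genes())
    by_sample: dict[str, list[AlterationCall]] = {s: [] for s in samples}
    for c in calls:
        if c.gene_id in member_genes and c.sample_id in by_sample:
            by_sample[c.sample_id].append(c)
    rows = []
    for s in samples:
        cs = by_sample[s]
        altered = bool(cs)
        sv_unique = altered and all(c.type in sv_types for c in cs)
        type_counts = {t: sum(c.type == t for c in cs)
                       for t in ALTERATION_ORDER}
        rows.append({"sample_id": s, "pathway": pathway.name,
                     "altered": altered, "sv_unique": sv_unique,
                     **type_counts})
    return pd.DataFrame(rows)


def pathway_type_enrichment(status: pd.DataFrame,
                            cancer_types: Mapping[str, str]) -> pd.DataFrame:
    """One-sided Fisher enrichment of pathway alteration within each cancer
    type versus the rest. ``status`` is the output of
    :func:`tabulate_pathway` (possibly concatenated over pathways)."""
    rows = []
    ct = status["sample_id"].map(cancer_types)
    for pathway, sub in status.groupby("pathway"):
        sub_ct = ct.loc[sub.index]
        altered = sub["altered"].astype(bool)
        if altered.sum() == 0:
            for t in sorted(sub_ct.unique()):
                rows.append({"pathway": pathway, "cancer_type": t,
                             "p": float("nan")})
            continue
        for t in sorted(sub_ct.unique()):
            in_type = sub_ct == t
            a = int((altered & in_type).sum())
            b = int((altered & ~in_type).sum())
            c = int((~altered & in_type).sum())
            d = int((~altered & ~in_type).sum())
            rows.append({"pathway": pathway, "cancer_type": t,
                         "p": fisher_one_sided([[a, b], [c, d]])})
    return pd.DataFrame(rows)
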