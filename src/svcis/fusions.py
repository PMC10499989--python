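"""Integration of chimeric-read fusion candidates with WGS SV breakpoints
and over-expression evidence.

Candidates are first filtered (low-confidence calls removed; any fusion
identity whose calls were >=50% low confidence dropped entirely; intergenic
candidates dropped). Each surviving event then gets WGS support (breakend
inside one or both partner gene bodies in the same tumor, or cross-sample
support when >=20% of tumors with the fusion have within-gene breakpoints)
and an expression category based on >0.4 SD over-expression of either
partner at the mRNA and/or protein level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .breakpoints import Breakend
from .io import GeneModel, Matrix

SV_SUPPORT = ("both_genes", "one_gene", "cross_sample", "none")
EXPR_CATEGORIES = (
    "mrna_and_protein_OE", "mrna_not_protein_OE", "mrna_OE_no_protein_data",
    "protein_not_mrna_OE", "cross_sample_OE", "none",
)


@dataclass(frozen=True)
class FusionCandidate:
    sample_id: str
    gene5: str
    gene3: str
    caller: str = "callerA"
    confidence: str = "high"   # high/medium/low
    intergenic: bool = False

    def __post_init__(self):
        if self.gene5 == self.gene3:
            raise ValueError("fusion partners must differ")

    def identity(self, ordered: bool = True):
        if ordered:
            return (self.gene5, self.gene3)
        return tuple(sorted((self.gene5, self.gene3)))


def filter_candidates(candidates: Sequence[FusionCandidate],
                      ordered: bool = True) -> list[FusionCandidate]:
    """Drop low-confidence calls, whole identities that were >=50% low
    confidence over their original calls, and intergenic candidates."""
    low_frac: dict[tuple, list[int]] = {}
    for c in candidates:
        key = c.identity(ordered)
        tally = low_frac.setdefault(key, [0, 0])
        tally[0] += int(c.confidence == "low")
        tally[1] += 1
    kept = []
    for c in candidates:
        if c.intergenic or c.confidence == "low":
            continue
        n_low, n_all = low_frac[c.identity(ordered)]
        if n_low / n_all >= 0.5:
            continue
        kept.append(c)
    return kept


def _gene_body_breakend(breakends_by_sample, sample_id: str,
                        gene: GeneModel | None) -> bool:
    if gene is None:
        return False
    for be in breakends_by_sample.get((sample_id, gene.chrom), ()):
        if gene.start <= be.pos < gene.end:
            return True
    return False


def annotate_sv_support(candidates: Sequence[FusionCandidate],
                        breakends: Sequence[Breakend],
                        genes: Sequence[GeneModel],
                        cross_sample_frac: float = 0.20,
                        ordered: bool = True) -> pd.DataFrame:
    """Per candidate: both_genes / one_gene / cross_sample / none."""
    gene_map = {g.gene_id: g for g in genes}
    by_sample: dict[tuple[str, str], list[Breakend]] = {}
    for be in breakends:
        by_sample.setdefault((be.sample_id, be.chrom), []).append(be)

    direct: list[str] = []
    for c in candidates:
        in5 = _gene_body_breakend(by_sample, c.sample_id, gene_map.get(c.gene5))
        in3 = _gene_body_breakend(by_sample, c.sample_id, gene_map.get(c.gene3))
        if in5 and in3:
            direct.append("both_genes")
        elif in5 or in3:
            direct.append("one_gene")
        else:
            direct.append("none")

    # cross-sample rescue: >=20% of tumors with this identity have
    # within-gene support
    supported_frac: dict[tuple, float] = {}
    by_identity: dict[tuple, list[int]] = {}
    for i, c in enumerate(candidates):
        by_identity.setdefault(c.identity(ordered), []).append(i)
    for key, idx in by_identity.items():
        samples = {candidates[i].sample_id: direct[i] != "none" for i in idx}
        supported_frac[key] = (sum(samples.values()) / len(samples)
                               if samples else 0.0)
    final = []
    for i, c in enumerate(candidates):
        if direct[i] != "none":
            final.append(direct[i])
        elif supported_frac[c.identity(ordered)] >= cross_sample_frac:
            final.append("cross_sample")
        else:
            final.append("none")
    return pd.DataFrame({
        "sample_id": [c.sample_id for c in candidates],
        "gene5": [c.gene5 for c in candidates],
        "gene3": [c.gene3 for c in candidates],
        "sv_support": final,
    })


def _oe(matrix: Matrix | None, gene: str, sample: str, oe_sd: float):
    """Is the gene over-expressed (> oe_sd) in this sample? None if no data."""
    if matrix is None or gene not in matrix.values.index \
            or sample not in matrix.values.columns:
        return None
    v = matrix.values.at[gene, sample]
    if np.isnan(v):
        return None
    return bool(v > oe_sd)


def annotate_expression_support(events: pd.DataFrame,
                                protein: Matrix | None, mrna: Matrix | None,
                                oe_sd: float = 0.4,
                                cross_sample_frac: float = 0.20,
                                ordered: bool = True) -> pd.DataFrame:
    """Assign each event one expression category (total, mutually
    exclusive), in the precedence order of :data:`EXPR_CATEGORIES`.

    "Either gene" over-expression uses the max over the two partners'
    values in the sample.
    """
    def pair_oe(matrix, g5, g3, s):
        o5, o3 = _oe(matrix, g5, s, oe_sd), _oe(matrix, g3, s, oe_sd)
        if o5 is None and o3 is None:
            return None
        return bool(o5) or bool(o3)

    base = []
    for row in events.itertuples(index=False):
        m = pair_oe(mrna, row.gene5, row.gene3, row.sample_id)
        p = pair_oe(protein, row.gene5, row.gene3, row.sample_id)
        if m and p:
            cat = "mrna_and_protein_OE"
        elif m and p is False:
            cat = "mrna_not_protein_OE"
        elif m and p is None:
            cat = "mrna_OE_no_protein_data"
        elif p and not m:
            cat = "protein_not_mrna_OE"
        else:
            cat = "none"
        base.append(cat)

    identity = [(g5, g3) if ordered else tuple(sorted((g5, g3)))
                for g5, g3 in zip(events["gene5"], events["gene3"])]
    oe_frac: dict[tuple, float] = {}
    per_identity: dict[tuple, dict[str, bool]] = {}
    for i, key in enumerate(identity):
        per_identity.setdefault(key, {})[events["sample_id"].iloc[i]] = (
            per_identity.get(key, {}).get(events["sample_id"].iloc[i], False)
            or base[i] != "none")
    for key, samples in per_identity.items():
        oe_frac[key] = sum(samples.values()) / len(samples)
    final = []
    for i, cat in enumerate(base):
        if cat == "none" and oe_frac[identity[i]] >= cross_sample_frac \
                and oe_frac[identity[i]] > 0:
            final.append("cross_sample_OE")
        else:
            final.append(cat)
    out = events.copy()
    out["expr_category"] = final
    return out


def summarize_fusions(evidence: pd.DataFrame,
                      cancer_types: pd.Series | None = None,
                      min_tumors: int = 3,
                      known_genes: set[str] | None = None) -> dict:
    """Counts per expression category, plus a recurrent-fusion x cancer-type
    matrix (fusions in more than two tumors, or two tumors with a partner in
    the user-supplied known-cancer-gene list)."""
    counts = (evidence["expr_category"].value_counts()
              .reindex(EXPR_CATEGORIES, fill_value=0))
    support_counts = (evidence["sv_support"].value_counts()
                      .reindex(SV_SUPPORT, fill_value=0)
                      if "sv_support" in evidence else None)
    matrix = None
    if cancer_types is not None and not evidence.empty:
        supported = evidence[
            evidence["expr_category"].isin(EXPR_CATEGORIES[:-1])
            & (evidence.get("sv_support", "none") != "none")].copy()
        supported["fusion"] = (supported["gene5"] + "--" + supported["gene3"])
        supported["cancer_type"] = supported["sample_id"].map(cancer_types)
        tumor_counts = supported.groupby("fusion")["sample_id"].nunique()
        keep = tumor_counts[tumor_counts >= min_tumors].index
        if known_genes:
            two = tumor_counts[tumor_counts == min_tumors - 1].index
            known = [f for f in two
                     if set(f.split("--")) & known_genes]
            keep = keep.union(known)
        sub = supported[supported["fusion"].isin(keep)]
        matrix = (sub.groupby(["fusion", "cancer_type"])["sample_id"]
                  .nunique().unstack(fill_value=0))
    return {"expr_counts": counts, "sv_counts": support_counts,
            "recurrent_matrix": matrix}
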