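"""Candidate cis-regulatory mechanisms behind SV-expression associations.

Detectors operate on single (breakend, annotation) inputs and are pure
functions: TAD disruption (the two breakends of an SV do not share a TAD),
enhancer hijacking (the rearrangement places a distal enhancer closer to
the gene than any native enhancer), retrotransposon translocation (a LINE
or SINE on the retained mate side within 20 kb), and rearranged-region
methylation transfer (the translocated region carries systematically
higher or lower cohort methylation than the gene's own CpG island).

Breakend orientation semantics (BEDPE dialect, config-switchable): '+' at a
breakend means the segment toward LOWER coordinates is retained at the
junction; '-' retains the segment toward higher coordinates. The retained
side of the mate breakend determines which flanking annotation travels with
the rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breakpoints import Breakend
from .io import GeneModel, SVCall
from .stats import chi2_2x2


@dataclass
class MechanismAnnotation:
    gene_id: str
    sample_id: str
    sv_id: str
    tad_disrupting: bool | None = None
    enhancer_hijack: bool = False
    enhancer_distance: float = float("nan")
    retro_hijack: bool = False
    retro_class: str = ""
    meth_transfer_delta: float = float("nan")
    expr_state: str = "neither"  # OE / UE / neither at +-0.4 SD


def _tad_of(pos: int, chrom: str, tads: pd.DataFrame):
    """Index of the TAD interval containing a position, or None."""
    sub = tads[(tads["chrom"] == chrom) & (tads["start"] <= pos)
               & (pos < tads["end"])]
    if sub.empty:
        return None
    return sub.index[0]


def tad_disrupting(sv: SVCall, tads: pd.DataFrame,
                   outside_is_disrupting: bool = True) -> bool:
    """True unless both breakends fall inside one common TAD.

    Interchromosomal SVs always disrupt. A breakend in no TAD shares no TAD
    with anything, so such SVs count as disrupting by default
    (``outside_is_disrupting=False`` treats both-outside as non-disrupting).
    """
    if sv.chrom1 != sv.chrom2:
        return True
    t1 = _tad_of(sv.pos1, sv.chrom1, tads)
    t2 = _tad_of(sv.pos2, sv.chrom2, tads)
    if t1 is None and t2 is None and not outside_is_disrupting:
        return False
    if t1 is None or t2 is None:
        return True
    return t1 != t2


def _retained_interval(pos: int, orient: str, span: int):
    """Half-open retained segment of length ``span`` from a breakend.

    '+' retains toward lower coordinates: [pos - span, pos]; '-' retains
    toward higher coordinates: [pos, pos + span].
    """
    if orient == "+":
        return max(0, pos - span), pos + 1
    if orient == "-":
        return pos, pos + span + 1
    raise ValueError(f"missing/invalid mate orientation {orient!r}")


def _nearest_in_retained(elements: pd.DataFrame, chrom: str, pos: int,
                         orient: str, span: int):
    """Nearest annotated interval within the retained segment.

    Returns (distance from the breakend, row) or (None, None). The distance
    to an interval is 0 if it covers the breakend position, else the gap to
    its nearest retained-side edge.
    """
    lo, hi = _retained_interval(pos, orient, span)
    sub = elements[(elements["chrom"] == chrom)
                   & (elements["end"] > lo) & (elements["start"] < hi)]
    best_d, best_row = None, None
    for row in sub.itertuples():
        if row.start <= pos < row.end:
            d = 0
        elif orient == "+":
            if row.end > pos + 1:
                continue  # entirely on the lost side
            d = pos - (row.end - 1)
        else:
            if row.start < pos:
                continue
            d = row.start - pos
        if d <= span and (best_d is None or d < best_d):
            best_d, best_row = d, row
    return best_d, best_row


def _nearest_native(elements: pd.DataFrame, gene: GeneModel, window: int):
    """Distance from the gene anchor to the nearest element within
    ``window`` on the gene's own chromosome, ignoring rearrangement."""
    sub = elements[(elements["chrom"] == gene.chrom)]
    best = None
    for row in sub.itertuples():
        if row.start <= gene.anchor < row.end:
            d = 0
        else:
            d = min(abs(gene.anchor - row.start),
                    abs(gene.anchor - (row.end - 1)))
        if d <= window and (best is None or d < best):
            best = d
    return best


def enhancer_hijack(breakend: Breakend, gene: GeneModel,
                    enhancers: pd.DataFrame, enh_scan: int = 500_000,
                    enh_ref: int = 1_000_000):
    """Does this breakend's rearrangement translocate an enhancer near the
    gene?

    The breakend is assumed to lie upstream of the gene with its mate on
    the distal side. The mate chromosome is scanned from the mate position
    in the retained direction (given by the mate orientation) up to
    ``enh_scan``. Hijack requires (a) an enhancer in that retained segment
    within ``enh_scan`` of the mate breakend, and (b) its junction-path
    distance to the gene (|breakend - anchor| + |enhancer - mate|) strictly
    smaller than the distance to any native enhancer within ``enh_ref`` of
    the gene anchor (no native enhancer means condition (b) holds).

    Returns (bool, junction-path distance or nan).
    """
    if breakend.mate_orient not in "+-":
        raise ValueError("missing mate orientation")
    d_mate, _row = _nearest_in_retained(
        enhancers, breakend.mate_chrom, breakend.mate_pos,
        breakend.mate_orient, enh_scan)
    if d_mate is None:
        return False, float("nan")
    junction_distance = abs(breakend.pos - gene.anchor) + d_mate
    native = _nearest_native(enhancers, gene, enh_ref)
    if native is not None and junction_distance >= native:
        return False, float(junction_distance)
    return True, float(junction_distance)


def retro_translocation(breakend: Breakend, repeats: pd.DataFrame,
                        retro_scan: int = 20_000):
    """LINE/SINE translocated to within ``retro_scan`` of the junction?

    Same retained-segment scan as :func:`enhancer_hijack`; ``repeats`` must
    carry the element class (LINE/SINE) in its ``name`` column. Returns
    (bool, class).
    """
    if breakend.mate_orient not in "+-":
        raise ValueError("missing mate orientation")
    retro = repeats[repeats["name"].isin(("LINE", "SINE"))]
    d, row = _nearest_in_retained(retro, breakend.mate_chrom,
                                  breakend.mate_pos, breakend.mate_orient,
                                  retro_scan)
    if d is None:
        return False, ""
    return True, row.name


def meth_transfer_delta(breakend: Breakend, beta: pd.DataFrame,
                        probe_annotation: pd.DataFrame, gene_probe: str,
                        region: int = 500_000,
                        low_cut: float = -0.1, high_cut: float = 0.1):
    """Cohort-mean methylation carried by the rearranged region, relative
    to the gene's own CpG island.

    delta = mean beta (over cohort samples and probes) in the retained
    mate-side region within ``region`` bp of the mate breakend, minus the
    cohort-mean beta of the gene's CGI probe. Returns (delta, flag) with
    flag in {"low_meth", "high_meth", ""}; (nan, "no_probes") if the
    retained region carries no probes.
    """
    lo, hi = _retained_interval(breakend.mate_pos, breakend.mate_orient,
                                region)
    sub = probe_annotation[
        (probe_annotation["chrom"] == breakend.mate_chrom)
        & (probe_annotation["pos"] >= lo) & (probe_annotation["pos"] < hi)]
    probes = [p for p in sub["probe_id"] if p in beta.index]
    if not probes:
        return float("nan"), "no_probes"
    region_mean = float(np.nanmean(beta.loc[probes].to_numpy()))
    gene_mean = float(np.nanmean(beta.loc[gene_probe].to_numpy()))
    delta = region_mean - gene_mean
    if delta < low_cut:
        return delta, "low_meth"
    if delta > high_cut:
        return delta, "high_meth"
    return delta, ""


def mechanism_enrichment(mechanism_flags: pd.Series,
                         oe_class: pd.Series) -> dict:
    """Pearson chi-square (no continuity correction) of {mechanism yes/no}
    x {OE-class yes/no}, plus the per-class mechanism fractions.

    ``oe_class`` marks associations with SV-associated altered expression
    (scan p < 0.01 for the 1 Mb region, corrected, and per-tumor expression
    beyond +-0.4 SD). Degenerate tables give p = nan with a flag.
    """
    m = mechanism_flags.astype(bool)
    o = oe_class.astype(bool)
    table = np.array([
        [int((m & o).sum()), int((m & ~o).sum())],
        [int((~m & o).sum()), int((~m & ~o).sum())],
    ])
    stat, p = chi2_2x2(table)
    frac_oe = table[0, 0] / table[:, 0].sum() if table[:, 0].sum() else np.nan
    frac_rest = (table[0, 1] / table[:, 1].sum()
                 if table[:, 1].sum() else np.nan)
    return {"table": table, "chi2": stat, "p": p,
            "fraction_mechanism_in_oe": frac_oe,
            "fraction_mechanism_in_rest": frac_rest,
            "degenerate": bool(np.isnan(p))}
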