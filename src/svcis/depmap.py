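"""Cell-line dependency analysis.

Per (gene, cell line) pair three flags are called: a somatic SV breakpoint
within 1 Mb of the gene, protein over-expression (> 0.4 SD from the median
across lines), and CRISPR knockout sensitivity (gene effect < -0.5). A
joint event is all three. The overlap between {breakpoint + OE} and
{sensitive} is tested by chi-square over all gene x line pairs; recurrence
filters keep genes with joint events in >= 7 lines and >= 5% of lines; and
an unweighted GSEA-style running-sum statistic tests whether a query gene
set ranks high in gene-effect variability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breakpoints import Breakend, build_binary_matrix, RegionSpec
from .io import GeneModel, Matrix
from .stats import chi2_2x2


def merge_proteomics(primary: Matrix, secondary: Matrix) -> Matrix:
    """Ordered-source merge of two cell-line proteomic matrices: values
    missing from the primary source are taken from the secondary, then the
    combined matrix is z-normalized per gene across lines."""
    lines = primary.values.columns.union(secondary.values.columns,
                                         sort=False)
    genes = primary.values.index.union(secondary.values.index, sort=False)
    a = primary.values.reindex(index=genes, columns=lines)
    b = secondary.values.reindex(index=genes, columns=lines)
    merged = a.where(a.notna(), b)
    mu = merged.mean(axis=1, skipna=True)
    sd = merged.std(axis=1, ddof=0, skipna=True).replace(0, np.nan)
    return Matrix(merged.sub(mu, axis=0).div(sd, axis=0))


def call_events(breakends: list[Breakend], genes: list[GeneModel],
                protein: Matrix, effect: pd.DataFrame,
                window: int = 1_000_000, oe_sd: float = 0.4,
                effect_cut: float = -0.5) -> pd.DataFrame:
    """Per (gene, line) flags: has_bp_1mb, protein_oe, sensitive.

    ``protein`` is the line x gene matrix in SD-from-median units across
    lines; ``effect`` is the gene x line CRISPR gene-effect matrix.
    """
    lines = list(protein.values.columns)
    bp = build_binary_matrix(breakends, genes, lines,
                             RegionSpec("flank_1mb", window))
    med = protein.values.median(axis=1)
    rows = []
    for g in genes:
        if g.gene_id not in protein.values.index \
                or g.gene_id not in effect.index:
            continue
        pvals = protein.values.loc[g.gene_id]
        evals = effect.loc[g.gene_id]
        for line in lines:
            p = pvals[line]
            e = evals.get(line, np.nan)
            rows.append({
                "gene_id": g.gene_id, "line_id": line,
                "has_bp_1mb": bool(bp.values.at[g.gene_id, line] > 0),
                "protein_oe": bool(p - med[g.gene_id] > oe_sd)
                if not np.isnan(p) else False,
                "sensitive": bool(e < effect_cut) if not np.isnan(e)
                else False,
            })
    df = pd.DataFrame(rows)
    df["joint"] = df["has_bp_1mb"] & df["protein_oe"] & df["sensitive"]
    return df


def overlap_test(events: pd.DataFrame) -> dict:
    """Chi-square of {breakpoint AND over-expression} x {sensitive} over
    all gene x line pairs; degenerate margins give p = nan with a flag."""
    bp_oe = events["has_bp_1mb"] & events["protein_oe"]
    sens = events["sensitive"]
    table = np.array([
        [int((bp_oe & sens).sum()), int((bp_oe & ~sens).sum())],
        [int((~bp_oe & sens).sum()), int((~bp_oe & ~sens).sum())],
    ])
    stat, p = chi2_2x2(table)
    return {"table": table, "chi2": stat, "p": p,
            "degenerate": bool(np.isnan(p))}


def recurrence_filter(events: pd.DataFrame, min_lines: int = 7,
                      min_frac: float = 0.05) -> dict:
    """Genes whose joint events recur: >= ``min_lines`` lines and >=
    ``min_frac`` of the lines examined (both thresholds inclusive)."""
    n_lines = events["line_id"].nunique()
    joint_counts = events[events["joint"]].groupby("gene_id")[
        "line_id"].nunique()
    bp_oe = events[events["has_bp_1mb"] & events["protein_oe"]]
    bp_oe_counts = bp_oe.groupby("gene_id")["line_id"].nunique()
    return {
        "joint_min_lines": sorted(
            joint_counts[joint_counts >= min_lines].index),
        "bp_oe_min_frac": sorted(
            bp_oe_counts[bp_oe_counts >= min_frac * n_lines].index),
        "n_lines": n_lines,
    }


def rank_enrichment(query: set, ranking: pd.Series, n_perm: int = 10_000,
                    seed: int = 0) -> dict:
    """Unweighted KS running-sum enrichment of ``query`` in ``ranking``.

    ``ranking`` maps gene -> the score to rank by (descending; e.g.
    per-gene SD of the gene-effect score across lines). The p-value comes
    from >= ``n_perm`` set-size-preserving permutations; the Monte-Carlo
    standard error of p is reported.
    """
    if not query:
        raise ValueError("empty query set")
    ranked = ranking.sort_values(ascending=False).index.to_numpy()
    in_set = np.isin(ranked, list(query))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("query has no gene in the ranking")
    n = len(ranked)

    def es(hits):
        up = hits / hits.sum()
        down = (~hits) / (n - hits.sum())
        run = np.cumsum(up - down)
        return run[np.argmax(np.abs(run))]

    observed = float(es(in_set))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        if abs(es(perm)) >= abs(observed):
            count += 1
    p = (count + 1) / (n_perm + 1)
    se = float(np.sqrt(p * (1 - p) / n_perm))
    return {"es": observed, "p": p, "mc_se": se, "n_hits": n_hit,
            "n_perm": n_perm}
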