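"""Shared statistics: one-sided Fisher set enrichment, chi-square on 2x2
tables, BH FDR, and gene-set over-representation over user-supplied
collections (GMT files)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def fisher_one_sided(table) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 table.

    ``table`` = [[a, b], [c, d]] with a the observed overlap; the p-value is
    the hypergeometric upper tail P(X >= a).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    M = a + b + c + d
    K = a + b   # query size
    N = a + c   # set size
    return float(sps.hypergeom.sf(a - 1, M, K, N))


def chi2_2x2(table):
    """Pearson chi-square without continuity correction on a 2x2 table.

    Returns (statistic, p). Degenerate margins (an all-zero row or column)
    give (nan, nan).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p are passed through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values outside [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def overlap_enrichment(set_a: set, set_b: set, background: set):
    """Overlap of two gene sets against a background.

    Returns (overlap count, chance-expected overlap |A||B|/|bg|, one-sided
    Fisher p via the hypergeometric upper tail).
    """
    a = set_a & background
    b = set_b & background
    k = len(a & b)
    expected = len(a) * len(b) / len(background) if background else float("nan")
    p = float(sps.hypergeom.sf(k - 1, len(background), len(a), len(b)))
    return k, expected, p


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def annotate_gene_sets(query: set[str], collection: Mapping[str, set[str]],
                       background: set[str]) -> pd.DataFrame:
    """Per-set one-sided Fisher enrichment of a query gene list.

    Sets with no member in the background are skipped (noted by the
    ``skipped`` flag in the returned frame with p missing). The background
    should be the scanned genes of the relevant analyte, not the genome.
    """
    q = query & background
    rows = []
    for name, members in collection.items():
        m = members & background
        if not m:
            rows.append((name, 0, 0, float("nan"), "", True))
            continue
        k = len(q & m)
        p = float(sps.hypergeom.sf(k - 1, len(background), len(q), len(m)))
        rows.append((name, k, len(m), p, ",".join(sorted(q & m)), False))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p",
                                     "overlap_genes", "skipped"])
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["p", "set"], na_position="last",
                          kind="mergesort").reset_index(drop=True)
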