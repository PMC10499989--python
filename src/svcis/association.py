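"""The core scan: per-feature linear model of expression (or logit
methylation) on a breakpoint term, correcting for gene-level CNA and cancer
type.

For each feature the model is

    y ~ intercept + bp + cna + C(group)

fit by ordinary least squares over samples with observed y, where ``bp`` is
the binary or relative-distance breakpoint term, ``cna`` the 5-level CNA
code treated as one numeric covariate, and ``group`` the cancer-type (or
batch) factor, reference-coded. The two-sided p-value for the bp
coefficient comes from the t distribution with residual degrees of freedom.
A gene is significant only if the breakpoint pattern lines up with
expression beyond what CNA or cancer type alone explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .breakpoints import BreakpointMatrix
from .io import Matrix
from .stats import bh_fdr, overlap_enrichment

COLLINEAR_COND = 1e8


@dataclass
class AssociationResult:
    feature_id: str
    analyte: str
    region: str
    coefficient: float
    t_statistic: float
    p_two_sided: float
    fdr_bh: float
    n_used: int
    n_bp_samples: int
    direction: str
    min_obs_pass: bool = True
    min_bp_pass: bool = True
    outlier_tumor_pass: bool = True
    untestable: bool = False
    collinear: bool = False


@dataclass
class ScanFilterPolicy:
    """Which features enter each region scan and its FDR computation."""

    min_obs: int = 400
    min_bp_tumors: int = 3
    #: regions where the >=3-breakpoint-tumor rule applies
    min_bp_regions: tuple = ("gene_body", "upstream_100kb", "downstream_100kb")
    #: methylation outlier rule: >=1 breakpoint tumor with
    #: |beta - sample median| > meth_delta
    meth_delta: float = 0.2

    def to_dict(self) -> dict:
        return {"min_obs": self.min_obs, "min_bp_tumors": self.min_bp_tumors,
                "min_bp_regions": list(self.min_bp_regions),
                "meth_delta": self.meth_delta}


def _design(bp, cna, grp):
    """Build [1, bp, cna, one-hot(grp, reference-coded)]; empty levels (after
    the missingness drop) are removed; reference level = lexicographically
    first."""
    n = len(bp)
    cols = [np.ones(n), np.asarray(bp, dtype=float)]
    names = ["intercept", "bp"]
    if cna is not None:
        cols.append(np.asarray(cna, dtype=float))
        names.append("cna")
    levels = sorted(pd.unique(np.asarray(grp)))
    for lev in levels[1:]:
        cols.append((np.asarray(grp) == lev).astype(float))
        names.append(f"grp[{lev}]")
    return np.column_stack(cols), names


def fit_association(y, bp, cna, grp, feature_id: str = "",
                    analyte: str = "", region: str = "") -> AssociationResult:
    """OLS of y on [intercept, bp, cna, one-hot(group)] over observed y.

    If the bp term is constant over the used samples, or the residual
    degrees of freedom are non-positive, the result is flagged untestable
    (p missing). Collinearity (design condition number > 1e8) is flagged
    but the coefficient is still reported from a rank-revealing solve.
    """
    y = np.asarray(y, dtype=float)
    bp = np.asarray(bp, dtype=float)
    grp = np.asarray(grp)
    obs = ~np.isnan(y)
    if cna is not None:
        cna = np.asarray(cna, dtype=float)
        obs &= ~np.isnan(cna)
    n_bp = int((bp > 0).sum())

    def _untestable():
        return AssociationResult(
            feature_id, analyte, region, np.nan, np.nan, np.nan, np.nan,
            int(obs.sum()), n_bp, "none", untestable=True)

    if obs.sum() < 1:
        return _untestable()
    yy, bb = y[obs], bp[obs]
    cc = cna[obs] if cna is not None else None
    gg = grp[obs]
    if np.ptp(bb) == 0:
        return _untestable()
    X, names = _design(bb, cc, gg)
    rank = np.linalg.matrix_rank(X)
    df_resid = len(yy) - rank
    if df_resid <= 0:
        return _untestable()
    beta, _, _, sv = np.linalg.lstsq(X, yy, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    collinear = bool(cond > COLLINEAR_COND)
    resid = yy - X @ beta
    sigma2 = float(resid @ resid) / df_resid
    XtX = X.T @ X
    try:
        cov = np.linalg.pinv(XtX) * sigma2
    except np.linalg.LinAlgError:
        return _untestable()
    j = names.index("bp")
    se = float(np.sqrt(max(cov[j, j], 0.0)))
    coef = float(beta[j])
    if se == 0:
        return _untestable()
    t = coef / se
    p = 2 * sps.t.sf(abs(t), df_resid)
    direction = "positive" if coef > 0 else "negative"
    return AssociationResult(feature_id, analyte, region, coef, float(t),
                             float(p), np.nan, int(obs.sum()), n_bp,
                             direction, collinear=collinear)


def run_scan(expr: Matrix, bp_matrix: BreakpointMatrix,
             cna: pd.DataFrame | None, groups: pd.Series,
             policy: ScanFilterPolicy | None = None,
             analyte: str = "protein",
             beta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scan every feature of ``expr`` against the breakpoint matrix.

    Matrices must be column-aligned on the same samples. BH FDR is computed
    within the region, over the features passing that region's filters
    (``min_obs`` everywhere; the >=3-breakpoint-tumor rule for the gene-body
    and 100 kb regions). For methylation scans, pass the raw ``beta`` matrix
    so the outlier-tumor rule (>=1 breakpoint tumor with
    |beta - sample median| > 0.2) can be evaluated; expr is then the logit
    matrix.
    """
    policy = policy or ScanFilterPolicy()
    samples = list(expr.samples)
    if list(bp_matrix.values.columns) != samples:
        raise ValueError("expression and breakpoint matrices not "
                         "column-aligned")
    grp = groups.loc[samples].to_numpy()
    region = bp_matrix.region.kind
    apply_min_bp = region in policy.min_bp_regions
    sample_beta_median = None
    if beta is not None:
        sample_beta_median = beta.median(axis=0)
    results: list[AssociationResult] = []
    for feat in expr.features:
        if feat not in bp_matrix.values.index:
            continue
        y = expr.values.loc[feat].to_numpy()
        n_obs = int(np.sum(~np.isnan(y)))
        if n_obs < policy.min_obs:
            continue
        bp = bp_matrix.values.loc[feat].to_numpy()
        cvec = None
        if cna is not None and feat in cna.index:
            cvec = cna.loc[feat].reindex(samples).to_numpy(dtype=float)
        res = fit_association(y, bp, cvec, grp, feature_id=feat,
                              analyte=analyte, region=region)
        res.min_bp_pass = (not apply_min_bp) or (
            res.n_bp_samples >= policy.min_bp_tumors)
        if beta is not None and feat in beta.index:
            b = beta.loc[feat]
            carriers = bp > 0
            delta = (b - sample_beta_median).to_numpy(dtype=float)[carriers]
            res.outlier_tumor_pass = bool(
                np.any(np.abs(delta[~np.isnan(delta)]) > policy.meth_delta))
        results.append(res)
    table = pd.DataFrame([vars(r) for r in results])
    if table.empty:
        import logging
        logging.getLogger(__name__).warning(
            "scan %s/%s: no features passed filters", analyte, region)
        return table
    eligible = table["min_bp_pass"] & ~table["untestable"]
    if beta is not None:
        eligible &= table["outlier_tumor_pass"]
    q = np.full(len(table), np.nan)
    q[eligible.to_numpy()] = bh_fdr(
        table.loc[eligible, "p_two_sided"].to_numpy())
    table["fdr_bh"] = q
    return table


def mask_mrna_to_protein(mrna: Matrix, protein: Matrix) -> Matrix:
    """Filtered mRNA dataset: any value not represented in the protein
    dataset is set missing; genes absent from the protein set drop out."""
    common = [g for g in mrna.features if g in set(protein.features)]
    vals = mrna.values.loc[common].copy()
    pmask = protein.mask.reindex(index=common, columns=mrna.samples,
                                 fill_value=False)
    vals[~pmask] = np.nan
    return Matrix(vals)


def concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                pa_cut: float, pb_cut: float, background: set[str],
                direction_match: bool = True):
    """Overlap of features significant in two scans, against a background.

    Returns (overlap count, chance-expected overlap, one-sided Fisher p,
    set A, set B). Direction matching requires the same coefficient sign.
    """
    def sig(t, cut):
        ok = t["p_two_sided"] < cut
        return t.loc[ok, ["feature_id", "direction"]]

    a = sig(table_a, pa_cut)
    b = sig(table_b, pb_cut)
    if direction_match:
        merged = a.merge(b, on="feature_id", suffixes=("_a", "_b"))
        joint = set(merged.loc[merged["direction_a"] == merged["direction_b"],
                               "feature_id"])
    else:
        joint = set(a["feature_id"]) & set(b["feature_id"])
    set_a = set(a["feature_id"]) & background
    set_b = set(b["feature_id"]) & background
    k = len(joint & background)
    expected = len(set_a) * len(set_b) / len(background)
    _, _, p = overlap_enrichment(set_a, set_b, background)
    return k, expected, p, set_a, set_b


def concordance_percentage(n_overlap: int, n_reference: int) -> float:
    """Percent of a reference significant set confirmed in the other
    analyte, rounded to the integer precision used in reporting."""
    return round(100.0 * n_overlap / n_reference)


def count_impacted_tumors(expr_row: pd.Series, bp_row: pd.Series,
                          cna_row: pd.Series | None, direction: str,
                          oe_sd: float = 0.4) -> int:
    """Tumors in which the association is realized as an expression outlier.

    Positive associations count breakpoint tumors with expression
    > +0.4 SD, excluding tumors with high-level amplification (CNA +2);
    negative associations count breakpoint tumors with expression
    < -0.4 SD.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    carriers = bp_row > 0
    if direction == "positive":
        hit = carriers & (expr_row > oe_sd)
        if cna_row is not None:
            hit &= cna_row < 2
    else:
        hit = carriers & (expr_row < -oe_sd)
    return int(hit.fillna(False).sum())
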