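"""Stratified Cox survival scans and signature scoring.

The breakpoint scan associates overall survival with the log2-transformed
distance to the nearest SV breakpoint per gene (patients without a
breakpoint within the window get the ceiling log2(window+2)), correcting
for gene-level CNA and stratifying by cancer type; shorter distance with
higher hazard (a negative distance coefficient) is the worse-outcome
direction. The expression scan uses the normalized expression value, with
higher expression / higher hazard as the worse direction. Partial
likelihoods use Efron tie handling; one tumor per patient (the first
listed); survival times are capped before fitting (events beyond the cap
become censored at the cap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .breakpoints import Breakend, nearest_distance_vector
from .io import Matrix, SampleRecord

COEF_CAP = 20.0


@dataclass
class CoxResult:
    coefficient: float
    se: float
    p_two_sided: float
    one_sided_p: float
    n: int
    n_events: int
    n_strata: int
    separation: bool = False
    untestable: bool = False


def cap_times(time, event, cap_months: float):
    """Censor events beyond the cap at the cap; a cap >= max(time) is a
    no-op."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    over = time > cap_months
    return np.where(over, cap_months, time), np.where(over, 0, event)


def one_per_patient(records: list[SampleRecord]) -> list[SampleRecord]:
    """First-listed tumor per patient."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.patient_id in seen:
            continue
        seen.add(r.patient_id)
        out.append(r)
    return out


def _score_test_p(time, event, x, strata) -> tuple[float, float]:
    """Cox score test at beta=0 for one covariate (Breslow ties),
    stratified. For a two-group covariate without ties this is exactly the
    log-rank statistic."""
    U, V = 0.0, 0.0
    df = pd.DataFrame({"t": time, "e": event, "x": x, "s": strata})
    for _, sub in df.groupby("s"):
        t = sub["t"].to_numpy()
        e = sub["e"].to_numpy().astype(bool)
        xv = sub["x"].to_numpy(dtype=float)
        order = np.argsort(-t, kind="mergesort")
        t, e, xv = t[order], e[order], xv[order]
        # risk set = prefix of the reverse-time ordering
        cum_x = np.cumsum(xv)
        cum_x2 = np.cumsum(xv ** 2)
        n_at = np.arange(1, len(t) + 1)
        for i in np.flatnonzero(e):
            # include later entries tied with t[i]
            j = i
            while j + 1 < len(t) and t[j + 1] == t[i]:
                j += 1
            n = n_at[j]
            mean = cum_x[j] / n
            var = cum_x2[j] / n - mean ** 2
            U += xv[i] - mean
            V += var
    if V <= 0:
        return float("nan"), float("nan")
    stat = U * U / V
    return float(np.sign(U) * np.sqrt(stat)), float(sps.chi2.sf(stat, 1))


def cox_fit(time, event, covariates: pd.DataFrame,
            strata=None, worse_direction: str = "positive",
            ties: str = "efron") -> CoxResult:
    """Stratified Cox PH fit; Wald p on the first covariate.

    ``worse_direction`` gives the coefficient sign corresponding to worse
    outcome; the one-sided p is Wald p/2 when the estimated sign matches,
    else 1 - p/2. Monotone likelihood (perfect separation) is flagged, the
    coefficient capped, and the p-value taken from the score test.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, len(time), 0, 0,
                         untestable=True)
    df = covariates.reset_index(drop=True).copy()
    target = df.columns[0]
    if df[target].nunique() <= 1:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, len(time),
                         int(event.sum()), 0, untestable=True)
    df["_T"] = time
    df["_E"] = event
    strata_col = None
    n_strata = 1
    if strata is not None:
        df["_S"] = np.asarray(strata)
        strata_col = ["_S"]
        n_strata = df["_S"].nunique()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_T", event_col="_E",
                    strata=strata_col)
        coef = float(cph.params_[target])
        se = float(cph.standard_errors_[target])
        p = float(cph.summary.loc[target, "p"])
        # monotone likelihood: the Wald SE explodes relative to the scale
        # of the estimate
        separation = abs(coef) > COEF_CAP or not np.isfinite(se) \
            or se > 100.0
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        separation = True
        coef, se, p = np.nan, np.nan, np.nan
    if separation:
        z, p = _score_test_p(time, event, df[target].to_numpy(),
                             df["_S"].to_numpy() if strata is not None
                             else np.zeros(len(time)))
        coef = float(np.clip(np.sign(z) * COEF_CAP if np.isfinite(z)
                             else np.nan, -COEF_CAP, COEF_CAP))
        se = np.nan
    sign = 1.0 if worse_direction == "positive" else -1.0
    if np.isnan(p):
        one_sided = np.nan
    elif np.sign(coef) == sign or coef == 0:
        one_sided = p / 2
    else:
        one_sided = 1 - p / 2
    return CoxResult(coef, se, p, one_sided, len(time), int(event.sum()),
                     n_strata, separation=separation)


def breakpoint_survival_scan(breakends: list[Breakend], genes,
                             records: list[SampleRecord],
                             cna: pd.DataFrame | None = None,
                             window: int = 1_000_000,
                             cap_months: float = 200.0) -> pd.DataFrame:
    """Per-gene stratified Cox of survival on log2 breakpoint distance.

    Worse-outcome direction: shorter distance => higher hazard, i.e. a
    negative coefficient on the distance covariate.
    """
    records = one_per_patient(
        [r for r in records if r.os_months is not None])
    sample_ids = [r.sample_id for r in records]
    time, event = cap_times([r.os_months for r in records],
                            [r.os_event for r in records], cap_months)
    strata = np.array([r.cancer_type for r in records])
    ceiling = float(np.log2(window + 2))
    rows = []
    for g in genes:
        dist = nearest_distance_vector(breakends, g, sample_ids, window)
        covs = pd.DataFrame({"log2_distance": dist.to_numpy()})
        n_carriers = int((dist < ceiling).sum())
        if cna is not None and g.gene_id in cna.index:
            covs["cna"] = cna.loc[g.gene_id].reindex(sample_ids).to_numpy()
        if n_carriers == 0:
            res = CoxResult(np.nan, np.nan, np.nan, np.nan, len(time),
                            int(event.sum()), 0, untestable=True)
        else:
            res = cox_fit(time, event, covs, strata=strata,
                          worse_direction="negative")
        rows.append({"gene_id": g.gene_id, "variable": "breakpoint_distance",
                     "coefficient": res.coefficient,
                     "one_sided_p": res.one_sided_p,
                     "p_two_sided": res.p_two_sided, "n": res.n,
                     "n_carriers": n_carriers,
                     "n_strata": res.n_strata,
                     "untestable": res.untestable})
    return pd.DataFrame(rows)


def expression_survival_scan(expr: Matrix, records: list[SampleRecord],
                             cap_months: float = 200.0) -> pd.DataFrame:
    """Per-gene stratified Cox of survival on normalized expression
    (higher expression / higher hazard = worse direction)."""
    records = one_per_patient(
        [r for r in records
         if r.os_months is not None and r.sample_id in expr.values.columns])
    sample_ids = [r.sample_id for r in records]
    time, event = cap_times([r.os_months for r in records],
                            [r.os_event for r in records], cap_months)
    strata = np.array([r.cancer_type for r in records])
    rows = []
    for gene_id in expr.features:
        y = expr.values.loc[gene_id, sample_ids].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3 or event[ok].sum() == 0:
            rows.append({"gene_id": gene_id, "variable": "expression",
                         "coefficient": np.nan, "one_sided_p": np.nan,
                         "p_two_sided": np.nan, "n": int(ok.sum()),
                         "n_strata": 0, "untestable": True})
            continue
        res = cox_fit(time[ok], event[ok],
                      pd.DataFrame({"expr": y[ok]}), strata=strata[ok],
                      worse_direction="positive")
        rows.append({"gene_id": gene_id, "variable": "expression",
                     "coefficient": res.coefficient,
                     "one_sided_p": res.one_sided_p,
                     "p_two_sided": res.p_two_sided, "n": res.n,
                     "n_strata": res.n_strata, "untestable": res.untestable})
    return pd.DataFrame(rows)


def signature_score(expr: Matrix, gene_set) -> pd.Series:
    """Per-sample mean of the normalized expression of the set's observed
    members; samples with no observed member get missing."""
    members = [g for g in gene_set if g in expr.values.index]
    if not members:
        raise ValueError("no signature gene present in the matrix")
    return expr.values.loc[members].mean(axis=0, skipna=True)


def _stratified_logrank(time, event, group, strata) -> tuple[float, float]:
    """k-group log-rank chi-square, summing score vectors and covariance
    over strata."""
    groups = np.unique(group)
    k = len(groups)
    gidx = {g: i for i, g in enumerate(groups)}
    U = np.zeros(k)
    V = np.zeros((k, k))
    df = pd.DataFrame({"t": time, "e": event, "g": group, "s": strata})
    for _, sub in df.groupby("s"):
        t = sub["t"].to_numpy()
        e = sub["e"].to_numpy().astype(bool)
        g = np.array([gidx[x] for x in sub["g"]])
        for tt in np.unique(t[e]):
            at_risk = t >= tt
            n = at_risk.sum()
            d = int((e & (t == tt)).sum())
            if n <= 1:
                continue
            ng = np.bincount(g[at_risk], minlength=k)
            dg = np.bincount(g[e & (t == tt)], minlength=k)
            expd = d * ng / n
            U += dg - expd
            c = d * (n - d) / (n - 1) if n > 1 else 0.0
            V += c * (np.diag(ng) * n - np.outer(ng, ng)) / n ** 2
    Vr = V[:-1, :-1]
    Ur = U[:-1]
    try:
        stat = float(Ur @ np.linalg.solve(Vr, Ur))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    return stat, float(sps.chi2.sf(stat, k - 1))


def tertile_bins(score: pd.Series) -> pd.Series:
    """Tertile labels 0/1/2 (low/intermediate/high), ties to the lower
    bin."""
    s = score.dropna()
    q1, q2 = np.quantile(s.to_numpy(), [1 / 3, 2 / 3])
    bins = pd.Series(np.where(s <= q1, 0, np.where(s <= q2, 1, 2)),
                     index=s.index)
    return bins


def logrank_tertiles(score: pd.Series, time, event,
                     cap_months: float = 200.0, strata=None) -> dict:
    """Three-group log-rank test over score tertiles, optionally
    stratified. Returns the chi-square statistic, p and the bin labels."""
    if len(score.dropna()) < 3:
        raise ValueError("need at least 3 scored samples")
    bins = tertile_bins(score)
    time = pd.Series(np.asarray(time, dtype=float), index=score.index)
    event = pd.Series(np.asarray(event, dtype=int), index=score.index)
    t, e = cap_times(time.loc[bins.index], event.loc[bins.index], cap_months)
    s = (pd.Series(np.asarray(strata), index=score.index).loc[bins.index]
         if strata is not None else np.zeros(len(bins)))
    stat, p = _stratified_logrank(t, e, bins.to_numpy(), np.asarray(s))
    return {"chi2": stat, "p": p, "bins": bins}


def km_table(time, event, label: str = "all") -> pd.DataFrame:
    """Kaplan-Meier export (time, n_risk, survival) for one bin."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame({"bin": label, "time": ev.index,
                         "n_risk": ev["at_risk"].to_numpy(),
                         "survival": surv.reindex(ev.index).to_numpy()})


def survival_overlap(sv_protein_genes: set, breakpoint_worse: set,
                     expression_worse: set, background: set) -> dict:
    """Overlap of SV-protein genes with the poor-prognosis set (genes worse
    by both breakpoint pattern and expression); one-sided Fisher p."""
    from .stats import overlap_enrichment
    poor = breakpoint_worse & expression_worse
    k, expected, p = overlap_enrichment(sv_protein_genes, poor, background)
    return {"overlap": k, "expected": expected, "p": p,
            "poor_prognosis_genes": poor}
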