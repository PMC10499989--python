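"""Expression, CNA and methylation normalization.

Expression matrices are brought onto "SD from the median" units in two
stages: first within each sample profile, then per feature within each
cancer-type x batch group. This keeps expression outliers (the signal the
breakpoint scans look for) while removing tissue-dominant and
inter-laboratory differences. Missing values are carried through untouched;
nothing is ever imputed.

Conventions fixed for reproducibility: the median of an even-length vector
is the lower of the two middle values, and SD is the population (n) standard
deviation over observed values.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Matrix

log = logging.getLogger(__name__)


def low_median(x: np.ndarray) -> float:
    """Median using the lower of the two middle values for even n."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    return float(np.sort(x)[(x.size - 1) // 2])


def pop_sd(x: np.ndarray) -> float:
    """Population (ddof=0) standard deviation over observed values."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    return float(np.std(x))


def normalize_profiles(matrix: Matrix) -> Matrix:
    """Stage 1: per sample profile, (x - median) / SD over observed values."""
    values = matrix.values.copy()
    arr = values.to_numpy()
    for j in range(arr.shape[1]):
        med = low_median(arr[:, j])
        sd = pop_sd(arr[:, j])
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"profile {values.columns[j]!r} has zero/undefined spread; "
                "cannot normalize"
            )
        arr[:, j] = (arr[:, j] - med) / sd
    values.iloc[:, :] = arr
    return Matrix(values)


def normalize_group(matrix: Matrix, groups: Mapping[str, str]) -> Matrix:
    """Stage 2: per feature within each group, (x - median) / SD.

    ``groups`` maps sample_id -> group label (cancer_type x batch). Features
    with zero spread or fewer than 3 observed values in a group are masked
    out there, with a logged warning. Exactly idempotent on complete data.
    """
    values = matrix.values.copy()
    labels = pd.Series({s: groups[s] for s in values.columns})
    for grp, cols in labels.groupby(labels).groups.items():
        cols = list(cols)
        if len(cols) < 3:
            raise ValueError(f"group {grp!r} has <3 samples")
        sub = values[cols].to_numpy()
        n_masked = 0
        for i in range(sub.shape[0]):
            row = sub[i]
            obs = ~np.isnan(row)
            if obs.sum() < 3:
                sub[i] = np.nan
                n_masked += 1
                continue
            sd = pop_sd(row)
            if sd == 0:
                sub[i] = np.nan
                n_masked += 1
                continue
            sub[i] = (row - low_median(row)) / sd
        if n_masked:
            log.warning("group %s: masked %d features with <3 observations "
                        "or zero spread", grp, n_masked)
        values.loc[:, cols] = sub
    return Matrix(values)


def average_duplicate_profiles(matrix: Matrix,
                               profile_to_sample: Mapping[str, str]) -> Matrix:
    """Average already-normalized duplicate profiles of the same tumor.

    ``profile_to_sample`` maps each profile column to its tumor sample ID;
    profiles mapping to the same tumor are averaged over observed values.
    """
    values = matrix.values
    sample_ids = pd.Index([profile_to_sample[c] for c in values.columns])
    out = values.T.groupby(sample_ids).mean().T
    return Matrix(out)


def normalize_two_stage(matrix: Matrix, groups: Mapping[str, str],
                        profile_to_sample: Mapping[str, str] | None = None
                        ) -> Matrix:
    """Full normalization: per-profile stage, optional duplicate-profile
    averaging, then per-feature stage within cancer-type x batch groups."""
    stage1 = normalize_profiles(matrix)
    if profile_to_sample is not None:
        stage1 = average_duplicate_profiles(stage1, profile_to_sample)
    return normalize_group(stage1, groups)


# ---------------------------------------------------------------------------
# CNA
# ---------------------------------------------------------------------------

#: default cutpoints on ploidy-normalized relative copy r = copy / mean(copy):
#: r < 0.25 -> -2, r < 0.75 -> -1, r <= 1.25 -> 0, r < 2.0 -> +1, else +2.
DEFAULT_CNA_CUTS = (0.25, 0.75, 1.25, 2.0)


def threshold_cna(copies: pd.DataFrame,
                  cuts: Sequence[float] = DEFAULT_CNA_CUTS,
                  amp_copies: float = 5.0) -> pd.DataFrame:
    """Ploidy-normalize absolute gene copies and threshold to 5 levels.

    Each sample's gene copy values are divided by the sample mean copy value
    (the ploidy estimate), then mapped to {-2,-1,0,+1,+2}: homozygous
    deletion, loss, wild-type, gain, amplification. Zero copies always map
    to -2 and >= ``amp_copies`` absolute copies always map to +2, regardless
    of ploidy.
    """
    arr = copies.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative copy values")
    mean_copy = np.nanmean(arr, axis=0)
    if np.any(mean_copy == 0):
        bad = copies.columns[np.where(mean_copy == 0)[0]].tolist()
        raise ValueError(f"sample(s) with zero mean copy: {bad[:5]}")
    r = arr / mean_copy
    lo2, lo1, hi0, hi1 = cuts
    out = np.zeros_like(arr, dtype=float)
    out[r < lo1] = -1
    out[r < lo2] = -2
    out[(r > hi0) & (r < hi1)] = 1
    out[r >= hi1] = 2
    out[arr >= amp_copies] = 2
    out[arr == 0] = -2
    out[np.isnan(arr)] = np.nan
    return pd.DataFrame(out, index=copies.index, columns=copies.columns)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

BETA_CLAMP = 1e-3


def logit_beta(beta: pd.DataFrame | np.ndarray,
               clamp: float = BETA_CLAMP):
    """log2(b/(1-b)) with beta clamped to [clamp, 1-clamp]; monotone in beta."""
    arr = np.asarray(beta, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("beta values outside [0, 1]")
    b = np.clip(arr, clamp, 1 - clamp)
    m = np.log2(b / (1 - b))
    m[np.isnan(arr)] = np.nan
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def inverse_logit_beta(m, clamp: float = BETA_CLAMP):
    """Inverse of :func:`logit_beta` (recovers the clamped beta)."""
    x = 2.0 ** np.asarray(m, dtype=float)
    return x / (1.0 + x)


PROBE_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "body", "3'UTR")


def filter_cgi_probes(probes: pd.DataFrame,
                      sex_chroms: Sequence[str] = ("chrX", "chrY", "X", "Y")
                      ) -> pd.DataFrame:
    """Keep CpG-island probes off the sex chromosomes.

    ``probes`` needs columns probe_id, chrom, pos, cgi_flag, gene_id,
    position_category; position categories (TSS200/TSS1500/5'UTR/body/3'UTR)
    are retained for promoter-vs-gene-body summaries.
    """
    required = {"probe_id", "chrom", "cgi_flag"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    flag = probes["cgi_flag"].astype(str).str.lower().isin(
        ("1", "true", "yes", "cgi"))
    keep = flag & ~probes["chrom"].isin(sex_chroms)
    return probes.loc[keep].reset_index(drop=True)
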