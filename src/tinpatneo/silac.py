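"""AHA-pulse SILAC ratio analysis.

Newly synthesized proteins are quantified in heavy (treated) and medium
(control) SILAC channels across 7 biological replicates.  The analysis:

* keeps proteins with >= 4 valid H/M ratios of 7,
* detects one-channel "strongly translated" candidates (>= 4 intensities in
  exactly one channel, none in the other),
* imputes the silent channel from a left-censored normal distribution with
  mean 0.75 x the replicate's observed minimum intensity and the replicate's
  observed standard deviation (truncated at 0),
* tests per-protein mean log2 H/M against 0 (one-sample t, BH-adjusted).

Intensity matrices are wide frames with columns H_1..H_7 and M_1..M_7.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

N_REPS = 7
MIN_VALID = 4
CENSOR_FACTOR = 0.75


def _channel_cols(n_reps: int) -> Tuple[list, list]:
    return [f"H_{i}" for i in range(1, n_reps + 1)], [f"M_{i}" for i in range(1, n_reps + 1)]


def log_ratios(matrix: pd.DataFrame, n_reps: int = N_REPS) -> pd.DataFrame:
    """log2 H/M per replicate; defined only where both channels are present."""
    h_cols, m_cols = _channel_cols(n_reps)
    h = matrix[h_cols].to_numpy(dtype=float)
    m = matrix[m_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(h) - np.log2(m)
    r[~(np.isfinite(h) & np.isfinite(m))] = np.nan
    return pd.DataFrame(r, index=matrix.index, columns=[f"ratio_{i}" for i in range(1, n_reps + 1)])


def filter_valid(matrix: pd.DataFrame, min_valid: int = MIN_VALID, n_reps: int = N_REPS) -> pd.DataFrame:
    """Rows with >= ``min_valid`` H/M ratio values across the replicates."""
    ratios = log_ratios(matrix, n_reps)
    keep = ratios.notna().sum(axis=1) >= min_valid
    return matrix[keep].copy()


def one_channel_candidates(matrix: pd.DataFrame, min_valid: int = MIN_VALID, n_reps: int = N_REPS) -> pd.DataFrame:
    """Strongly translated candidates: >= ``min_valid`` intensities in exactly
    one channel and none in the other."""
    h_cols, m_cols = _channel_cols(n_reps)
    n_h = matrix[h_cols].notna().sum(axis=1)
    n_m = matrix[m_cols].notna().sum(axis=1)
    keep = ((n_h >= min_valid) & (n_m == 0)) | ((n_m >= min_valid) & (n_h == 0))
    return matrix[keep].copy()


def impute_left_censored(
    matrix: pd.DataFrame,
    factor: float = CENSOR_FACTOR,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_reps: int = N_REPS,
) -> pd.DataFrame:
    """Replace missing channel intensities by left-censored draws.

    Per replicate column, missing values are drawn from
    Normal(factor x min(observed), sd(observed)) truncated below at 0.
    Columns with < 2 observed values are left untouched (imputation refused).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = matrix.copy()
    h_cols, m_cols = _channel_cols(n_reps)
    for col in h_cols + m_cols:
        vals = out[col].to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        miss = ~np.isfinite(vals)
        if not miss.any():
            continue
        if obs.size < 2:
            continue
        mean = factor * obs.min()
        sd = obs.std(ddof=1)
        draws = rng.normal(mean, sd, size=int(miss.sum()))
        while np.any(draws < 0):
            neg = draws < 0
            draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
        vals[miss] = draws
        out[col] = vals
    return out


def median_center(ratios: pd.Series) -> pd.Series:
    """Subtract the median; rank order is unchanged."""
    return ratios - ratios.median()


def differential_translation(ratios: pd.DataFrame) -> pd.DataFrame:
    """One-sample two-sided t-test of mean log2 H/M against 0 per protein,
    BH-adjusted across proteins.  Zero-variance rows yield p = NA."""
    arr = ratios.to_numpy(dtype=float)
    means = np.full(arr.shape[0], np.nan)
    stat = np.full(arr.shape[0], np.nan)
    p = np.full(arr.shape[0], np.nan)
    for i, row in enumerate(arr):
        vals = row[np.isfinite(row)]
        if vals.size:
            means[i] = vals.mean()
        if vals.size < 2:
            continue
        if np.all(vals == 0):
            stat[i], p[i] = 0.0, 1.0
            continue
        if np.allclose(vals.std(ddof=1), 0):
            continue  # exact tie: p undefined
        t, pv = stats.ttest_1samp(vals, 0.0)
        stat[i], p[i] = t, pv
    out = pd.DataFrame(
        {
            "mean_log2_ratio": means,
            "t_statistic": stat,
            "p_value": p,
            "p_adj": bh_adjust(p),
        },
        index=ratios.index,
    )
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out
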