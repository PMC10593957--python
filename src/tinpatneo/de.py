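"""Differential induction: calling treatment-induced transcripts and TINPATs.

A deliberately small negative-binomial Wald caller in the spirit of the
standard RNA-seq DE tools: median-of-ratios size factors, a pooled
method-of-moments dispersion estimate (variance mu + alpha*mu^2, alpha shared
across conditions per transcript), and a per-transcript NB log-link
regression with the log size factors as offsets and a Wald test on the
treatment coefficient.  No dispersion or fold-change shrinkage is applied.

TINPATs (treatment-induced novel polyadenylated transcripts) are the novel
(chimeric or non-chimeric) transcripts passing adjusted p < 0.01 and
log2 fold change > 2; known transcripts passing the same thresholds are
flagged induced but are not TINPATs.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_MIN = 1e-8
LN2 = np.log(2.0)

TINPAT_PADJ = 0.01
TINPAT_LFC = 2.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    factor_j = median over all-sample-nonzero transcripts of
    count_ij / geometric_mean_i.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no transcript has nonzero counts in all samples")
    sub = mat[nonzero]
    gm = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / gm[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    sf: Optional[pd.Series] = None,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Pooled method-of-moments dispersion per transcript.

    On size-factor-normalized counts, within-condition sample variances are
    pooled and alpha_hat = max(alpha_min, (s2 - mean) / mean^2).
    """
    if sf is None:
        sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cond = np.array([condition[s] for s in counts.columns])
    levels = [lv for lv in np.unique(cond) if (cond == lv).sum() >= 2]
    if not levels:
        raise ValueError("need >= 2 replicates in at least one condition")
    ss = np.zeros(norm.shape[0])
    dof = 0
    for lv in levels:
        cols = norm[:, cond == lv]
        ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
        dof += cols.shape[1] - 1
    s2 = ss / dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def common_dispersion(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    sf: Optional[pd.Series] = None,
    alpha_min: float = ALPHA_MIN,
) -> float:
    """Single dispersion shared across transcripts (the caller's model).

    Ratio-of-sums method-of-moments over all transcripts:
    alpha_hat = sum_i(s2_i - mu_i) / sum_i(mu_i^2) on normalized counts,
    floored at ``alpha_min``.  Aggregating the moments across transcripts
    removes the small-sample noise that makes per-transcript plug-in
    estimates anti-conservative in the Wald test.
    """
    if sf is None:
        sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cond = np.array([condition[s] for s in counts.columns])
    levels = [lv for lv in np.unique(cond) if (cond == lv).sum() >= 2]
    if not levels:
        raise ValueError("need >= 2 replicates in at least one condition")
    ss = np.zeros(norm.shape[0])
    dof = 0
    for lv in levels:
        cols = norm[:, cond == lv]
        ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
        dof += cols.shape[1] - 1
    s2 = ss / dof
    mu = norm.mean(axis=1)
    denom = float(np.sum(mu**2))
    if denom == 0:
        return alpha_min
    return max(alpha_min, float(np.sum(s2 - mu) / denom))


def _design_matrix(
    samples: Sequence[str],
    condition: Mapping[str, str],
    contrast: Sequence[str],
    covariate: Optional[Mapping[str, str]],
):
    treated, control = contrast
    cond = [condition[s] for s in samples]
    keep = [i for i, c in enumerate(cond) if c in (treated, control)]
    if not keep:
        raise ValueError(f"no samples in contrast levels {contrast}")
    samples = [samples[i] for i in keep]
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    cols.append(np.array([1.0 if condition[s] == treated else 0.0 for s in samples]))
    names.append(f"condition[{treated}]")
    if covariate is not None:
        levels = sorted({covariate[s] for s in samples})
        for lv in levels[1:]:
            cols.append(np.array([1.0 if covariate[s] == lv else 0.0 for s in samples]))
            names.append(f"covariate[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names, keep


def _nb_irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             max_iter: int = 60, tol: float = 1e-10):
    """Batched Fisher-scoring IRLS for NB log-link regression, shared design.

    Y: (G, n) counts; X: (n, p); offset: (n,); alpha: (G,).
    Returns beta (G, p), se (G, p), converged (G,) boolean.
    """
    G, n = Y.shape
    p = X.shape[1]
    # init from OLS on log(y + 0.5) - offset
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, p)
    converged = np.zeros(G, dtype=bool)
    XtWX = np.zeros((G, p, p))
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)  # Fisher weights
        z = eta - offset[None, :] + (Y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        try:
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.array([
                np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(G)
            ])
        step = new - beta
        beta = new
        done = np.max(np.abs(step), axis=1) < tol
        converged |= done
        if done.all():
            break
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(XtWX)
            se = np.sqrt(np.einsum("gii->gi", cov))
        except np.linalg.LinAlgError:
            se = np.full((G, p), np.nan)
    return beta, se, converged


def wald_test(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    contrast: Sequence[str],
    covariate: Optional[Mapping[str, str]] = None,
    dispersion: Optional[pd.Series] = None,
    sf: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-transcript NB Wald test of ``contrast = (treated, control)``.

    Returns a frame with log2_fc, se (log2 units), p_value.  The model
    assumes a dispersion shared across transcripts; by default it is
    estimated with :func:`common_dispersion` (pass a per-transcript Series
    to override).  Transcripts with a degenerate fit (all-zero group,
    separation, non-convergence) are reported with p = NA rather than
    silently dropped.
    """
    if sf is None:
        sf = size_factors(counts)
    if dispersion is None:
        alpha_common = common_dispersion(counts, condition, sf=sf)
        dispersion = pd.Series(alpha_common, index=counts.index)
    X, names, keep = _design_matrix(list(counts.columns), condition, contrast, covariate)
    cols = [counts.columns[i] for i in keep]
    Y = counts[cols].to_numpy(dtype=float)
    offset = np.log(sf[cols].to_numpy())
    alpha = dispersion.to_numpy(dtype=float)
    beta, se, converged = _nb_irls(Y, X, offset, alpha)
    j = names.index(f"condition[{contrast[0]}]")
    b, s = beta[:, j], se[:, j]

    treated_mask = X[:, j] == 1
    bad = (
        ~converged
        | ~np.isfinite(b)
        | ~np.isfinite(s)
        | (s <= 0)
        | (np.abs(b) > 30)
        | (Y[:, treated_mask].sum(axis=1) == 0)
        | (Y[:, ~treated_mask].sum(axis=1) == 0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b / s
        p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "log2_fc": b / LN2,
            "se": s / LN2,
            "p_value": p,
        },
        index=counts.index,
    )
    out.loc[bad, ["log2_fc", "se", "p_value"]] = [np.nan, np.nan, np.nan]
    # exact-null shortcut keeps lfc at 0 when the fit collapses numerically
    out["p_value"] = out["p_value"].clip(upper=1.0)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NA p-values stay NA and are
    excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if not mask.any():
        return out
    ps = p[mask]
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def call_tinpats(
    de_results: pd.DataFrame,
    simple_class: Mapping[str, str],
    padj_cutoff: float = TINPAT_PADJ,
    lfc_cutoff: float = TINPAT_LFC,
) -> pd.DataFrame:
    """Flag induced transcripts and TINPATs.

    induced <=> p_adj < padj_cutoff and log2_fc > lfc_cutoff (strict
    inequalities); tinpat additionally requires a novel (chimeric or
    non-chimeric) simple class.  Transcripts without a class are excluded
    from TINPAT calling with a warning.
    """
    out = de_results.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    classes = pd.Series({t: simple_class.get(t) for t in out.index})
    missing = int(classes.isna().sum())
    if missing:
        warnings.warn(f"{missing} transcripts without a simple class excluded from TINPAT calling")
    out["simple_class"] = classes
    induced = (out["p_adj"] < padj_cutoff) & (out["log2_fc"] > lfc_cutoff)
    out["induced"] = induced.fillna(False)
    out["tinpat"] = out["induced"] & classes.isin(["chimeric", "non_chimeric"])
    return out


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    if np.any(~(lens > 0)):
        raise ValueError("all transcript lengths must be > 0")
    rate = counts.to_numpy(dtype=float) / lens[:, None]
    total = rate.sum(axis=0)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero samples reported as NA")
        total = np.where(zero, np.nan, total)
    return pd.DataFrame(1e6 * rate / total[None, :], index=counts.index, columns=counts.columns)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_condition: str,
    target_col: str = "ct_target",
    housekeeping_col: str = "ct_housekeeping",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    dCt = Ct_target - Ct_housekeeping per sample; ddCt subtracts the mean dCt
    of the reference (vehicle) condition; relative expression = 2^(-ddCt).
    Samples missing the housekeeping Ct are dropped with a warning.
    """
    table = ct_table.copy()
    missing = table[housekeeping_col].isna() | table[target_col].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} samples dropped (missing Ct)")
        table = table[~missing]
    if not (table[condition_col] == reference_condition).any():
        raise ValueError(f"no samples in reference condition {reference_condition!r}")
    table = table.copy()
    table["delta_ct"] = table[target_col] - table[housekeeping_col]
    ref_mean = table.loc[table[condition_col] == reference_condition, "delta_ct"].mean()
    table["delta_delta_ct"] = table["delta_ct"] - ref_mean
    table["relative_expression"] = 2.0 ** (-table["delta_delta_ct"])
    return table
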