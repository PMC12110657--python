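"""GLM activation estimation and group-level activation contrasts.

Per participant and channel, condition activation is the ordinary
least-squares beta of an HRF-convolved boxcar regressor fitted to the HbO
series, with rest as the unmodeled baseline absorbed by the intercept.
Group inference uses one-sample t-tests per channel (condition > rest,
private > inner) and two-sample t-tests for proficiency comparisons, with
Benjamini-Hochberg FDR correction across channels within each contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hrf import HRFParams, canonical_hrf
from .preprocess import HbSeries, PreprocessConfig, dct_highpass, hrf_lowpass
from .segmentation import ConditionTimeline

__all__ = [
    "MODELED_CONDITIONS",
    "ACTIVATION_CONTRASTS",
    "DesignMatrix",
    "ActivationBetas",
    "canonical_hrf",
    "HRFParams",
    "build_design",
    "fit_glm",
    "glm_betas",
    "one_sample_t",
    "two_sample_t",
    "fdr_bh",
    "activation_contrasts",
]

#: Conditions carrying their own regressor; rest is the implicit baseline.
MODELED_CONDITIONS = ("private", "inner", "outer")

#: The four group-level activation contrasts, as (name, weight vector over
#: MODELED_CONDITIONS). Condition-vs-rest contrasts test the condition beta
#: against zero (baseline-referenced).
ACTIVATION_CONTRASTS: dict[str, np.ndarray] = {
    "private_gt_rest": np.array([1.0, 0.0, 0.0]),
    "inner_gt_rest": np.array([0.0, 1.0, 0.0]),
    "outer_gt_rest": np.array([0.0, 0.0, 1.0]),
    "private_gt_inner": np.array([1.0, -1.0, 0.0]),
}


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (T, k) — condition regressors then intercept
    names: list[str]
    dropped: list[str] = field(default_factory=list)


@dataclass
class ActivationBetas:
    """Per-participant, per-channel, per-condition GLM betas."""

    beta: np.ndarray  # (participants, channels, conditions)
    residual_variance: np.ndarray  # (participants, channels)
    channel_ids: list[int]
    conditions: tuple[str, ...] = MODELED_CONDITIONS
    participant_ids: list[str] = field(default_factory=list)


def build_design(
    timeline: ConditionTimeline,
    fs: float | None = None,
    hrf_params: HRFParams | None = None,
    conditions: tuple[str, ...] = MODELED_CONDITIONS,
    filter_like: PreprocessConfig | None = None,
) -> DesignMatrix:
    """HRF-convolved boxcar design with intercept.

    Each modeled condition's {0,1} per-sample indicator is convolved with
    the unit-peak canonical HRF and truncated to the series length; a
    condition absent from the timeline is dropped with a warning. When
    ``filter_like`` is given, the condition regressors receive exactly the
    temporal filtering applied to the data (high-pass projection and/or
    hemodynamic low-pass), the standard GLM practice that keeps model and
    data in the same filtered space; the intercept is left unfiltered.
    """
    fs = fs or timeline.fs
    hrf = canonical_hrf(fs, hrf_params, norm="peak")
    T = timeline.n_samples
    cols, names, dropped = [], [], []
    for cond in conditions:
        box = timeline.mask(cond).astype(float)
        if box.sum() == 0:
            warnings.warn(f"condition {cond!r} has zero duration; regressor dropped")
            dropped.append(cond)
            continue
        reg = np.convolve(box, hrf)[:T]
        cols.append(reg)
        names.append(cond)
    if filter_like is not None and cols:
        X = np.column_stack(cols)
        if filter_like.run_highpass:
            X = dct_highpass(X, fs, filter_like.filters.highpass_cutoff_hz)
        if filter_like.run_lowpass:
            X = hrf_lowpass(X, fs, filter_like.filters.hrf_params)
        cols = [X[:, i] for i in range(X.shape[1])]
    cols.append(np.ones(T))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names, dropped=dropped)


def fit_glm(y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, float, int]:
    """OLS fit of one channel's series; returns (betas, residual variance, df).

    Residual variance uses df = T - rank(X). Rank deficiency raises with
    the names of the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [
            design.names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.shape[0] - rank
    sigma2 = float(resid @ resid / df) if df > 0 else float("nan")
    return beta, sigma2, df


def glm_betas(
    hb: HbSeries,
    timeline: ConditionTimeline,
    hrf_params: HRFParams | None = None,
    filter_like: PreprocessConfig | None = None,
    channel_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, DesignMatrix]:
    """Condition betas for every channel of one participant-block.

    Returns (beta [channels x len(MODELED_CONDITIONS)], residual variance
    [channels], design). Channels masked out (QC-excluded) get NaN rows.
    Conditions dropped from the design also yield NaN betas.
    """
    design = build_design(timeline, hb.fs, hrf_params, filter_like=filter_like)
    C = hb.hbo.shape[1]
    beta = np.full((C, len(MODELED_CONDITIONS)), np.nan)
    sigma2 = np.full(C, np.nan)
    col = {name: i for i, name in enumerate(design.names)}
    for c in range(C):
        if channel_mask is not None and not channel_mask[c]:
            continue
        b, s2, _ = fit_glm(hb.hbo[:, c], design)
        for k, cond in enumerate(MODELED_CONDITIONS):
            if cond in col:
                beta[c, k] = b[col[cond]]
        sigma2[c] = s2
    return beta, sigma2, design


# ---------------------------------------------------------------------------
# group statistics


def one_sample_t(values: np.ndarray) -> tuple[float, float, int]:
    """Two-sided one-sample t-test against zero: t = mean / (sd/sqrt(n))."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("one-sample t-test needs at least 2 finite values")
    sd = v.std(ddof=1)
    if sd == 0:
        if v.mean() == 0:
            return 0.0, 1.0, n - 1
        raise ZeroDivisionError(
            "zero variance with nonzero mean: t statistic undefined"
        )
    t = v.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), n - 1


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Two-sided pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs at least 2 finite values per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), a.size + b.size - 2


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask at p_fdr < q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def _contrast_table(
    t: np.ndarray, p: np.ndarray, df: np.ndarray, channel_ids: list[int], q: float
) -> pd.DataFrame:
    finite = np.isfinite(p)
    p_fdr = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if finite.any():
        p_fdr[finite], sig[finite] = fdr_bh(p[finite], q)
    return pd.DataFrame(
        {
            "channel": channel_ids,
            "t": t,
            "p": p,
            "p_fdr": p_fdr,
            "significant": sig,
            "df": df,
        }
    )


def activation_contrasts(
    betas: ActivationBetas,
    groups: list[str] | np.ndarray,
    q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Group activation maps for every contrast, FDR-corrected per contrast.

    ``groups`` assigns each participant to a proficiency group. Within each
    group the four contrasts (three condition-vs-rest, private-vs-inner)
    are one-sample t-tests over participants; in addition each modeled
    condition is compared between the two groups with a two-sample t-test
    per channel. Keys: ``"<group>/<contrast>"`` and
    ``"between/<condition>"``.
    """
    groups = np.asarray(groups)
    if betas.beta.shape[0] != groups.size:
        raise ValueError("groups length must match number of participants")
    names = sorted(set(groups.tolist()))
    for g in names:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
    C = betas.beta.shape[1]
    out: dict[str, pd.DataFrame] = {}
    for g in names:
        sub = betas.beta[groups == g]  # (n_g, C, K)
        for cname, w in ACTIVATION_CONTRASTS.items():
            vals = sub @ w  # (n_g, C)
            t = np.full(C, np.nan)
            p = np.full(C, np.nan)
            df = np.full(C, np.nan)
            for c in range(C):
                v = vals[:, c]
                v = v[np.isfinite(v)]
                if v.size >= 2:
                    t[c], p[c], df[c] = one_sample_t(v)
            out[f"{g}/{cname}"] = _contrast_table(t, p, df, betas.channel_ids, q)
    if len(names) == 2:
        g1, g2 = names
        for k, cond in enumerate(betas.conditions):
            a = betas.beta[groups == g1, :, k]
            b = betas.beta[groups == g2, :, k]
            t = np.full(C, np.nan)
            p = np.full(C, np.nan)
            df = np.full(C, np.nan)
            for c in range(C):
                va, vb = a[:, c], b[:, c]
                va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
                if va.size >= 2 and vb.size >= 2:
                    t[c], p[c], df[c] = two_sample_t(va, vb)
            out[f"between/{cond}"] = _contrast_table(t, p, df, betas.channel_ids, q)
    return out
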