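"""Channel-wise functional connectivity and group contrast matrices.

Per participant and condition, Pearson correlations between the HbO series
of every valid channel pair are computed over the condition's samples
(each condition segment demeaned individually before concatenation),
Fisher-Z transformed, and averaged across the two task blocks. Matrices
are ordered by brain-region groups. Group contrasts are connection-wise
paired t-tests reported as t, p and -log10(p), with uncorrected
significance masks at p < 0.005 split by the sign of t, plus FDR-adjusted
p so either reporting rule can be applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .activation import fdr_bh
from .montage import ChannelMap, region_ordered_ids
from .preprocess import HbSeries
from .segmentation import ConditionTimeline

__all__ = [
    "FC_CONTRASTS",
    "ConnectivityMatrix",
    "ContrastMatrix",
    "condition_fc",
    "fisher_z",
    "average_blocks",
    "paired_contrast",
    "render_contrast",
    "contrast_to_csv",
]

#: The three group-level connectivity contrasts, per proficiency group.
FC_CONTRASTS = (
    ("private", "outer"),
    ("inner", "outer"),
    ("private", "inner"),
)

DEFAULT_R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-Z connectivity matrix in region order."""

    z: np.ndarray  # (n, n), diagonal NaN
    condition: str
    participant_id: str = ""
    channel_ids: list[int] = field(default_factory=list)  # region-ordered
    n_samples_used: int = 0
    n_blocks: int = 1

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        off = ~np.eye(z.shape[0], dtype=bool)
        finite = np.isfinite(z[off])
        if finite.any() and not np.allclose(
            np.where(np.isfinite(z), z, 0.0),
            np.where(np.isfinite(z), z, 0.0).T,
            atol=1e-10,
        ):
            raise ValueError("z matrix must be symmetric")
        self.z = z


@dataclass
class ContrastMatrix:
    """Connection-wise paired-contrast statistics in region order."""

    t: np.ndarray
    p: np.ndarray
    neglog10p: np.ndarray
    mask_pos: np.ndarray
    mask_neg: np.ndarray
    p_fdr: np.ndarray
    label: str
    df: int
    channel_ids: list[int] = field(default_factory=list)


def fisher_z(r: np.ndarray | float, clip: float = DEFAULT_R_CLIP):
    """Variance-stabilizing Fisher transform z = arctanh(r).

    Correlations within 1e-7 of +-1 are clipped before the transform;
    |r| > 1 is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) > 1 + 1e-12):
        raise ValueError("|r| > 1 is not a correlation")
    out = np.arctanh(np.clip(arr, -clip, clip))
    out = np.where(np.isfinite(arr), out, np.nan)
    return float(out) if np.isscalar(r) else out


def condition_fc(
    hb: HbSeries,
    timeline: ConditionTimeline,
    condition: str,
    cmap: ChannelMap | None = None,
    min_segment_s: float = 1.0,
    min_samples: int = 30,
    r_clip: float = DEFAULT_R_CLIP,
    channel_mask: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Fisher-Z connectivity of one condition for one participant-block.

    Condition segments of at least ``min_segment_s`` are demeaned
    individually (removing segment-level offsets that would inflate
    correlations) and concatenated; Pearson r is computed over the pooled
    samples for every channel pair. When a channel map is given, rows and
    columns follow its region ordering and only valid channels enter.
    """
    segs = [
        (s, e)
        for s, e in timeline.segments(condition)
        if (e - s) >= int(round(min_segment_s * hb.fs))
    ]
    total = sum(e - s for s, e in segs)
    if len(segs) == 0 or total < min_samples:
        raise ValueError(
            f"condition {condition!r} has only {total} usable samples "
            f"(minimum {min_samples})"
        )
    if cmap is not None:
        ordered = region_ordered_ids(cmap)
        idx = [hb.channel_ids.index(cid) for cid in ordered]
    else:
        ordered = list(hb.channel_ids)
        idx = list(range(len(ordered)))
    data = hb.hbo[:, idx]
    pooled = np.concatenate(
        [data[s:e] - data[s:e].mean(axis=0, keepdims=True) for s, e in segs], axis=0
    )
    if channel_mask is not None:
        channel_mask = np.asarray(channel_mask, dtype=bool)[idx]
    sd = pooled.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant channels in condition {condition!r}: "
            f"{[ordered[i] for i in np.flatnonzero(constant)]}; entries masked"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(pooled, rowvar=False)
    z = fisher_z(r, clip=r_clip)
    bad = constant
    if channel_mask is not None:
        bad = bad | ~channel_mask
    z[bad, :] = np.nan
    z[:, bad] = np.nan
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(
        z=z,
        condition=condition,
        participant_id=hb.participant_id,
        channel_ids=ordered,
        n_samples_used=total,
        n_blocks=1,
    )


def average_blocks(
    a: ConnectivityMatrix, b: ConnectivityMatrix | None
) -> ConnectivityMatrix:
    """Elementwise mean of two blocks' Fisher-Z matrices.

    A missing second block passes the single-block matrix through with its
    block count left at 1 so downstream code can see the degenerate case.
    """
    if b is None:
        return replace(a)
    if a.condition != b.condition:
        raise ValueError(f"condition mismatch: {a.condition!r} vs {b.condition!r}")
    if a.participant_id != b.participant_id:
        raise ValueError("participant mismatch between blocks")
    if a.channel_ids != b.channel_ids:
        raise ValueError("channel ordering differs between blocks")
    return ConnectivityMatrix(
        z=(a.z + b.z) / 2.0,
        condition=a.condition,
        participant_id=a.participant_id,
        channel_ids=list(a.channel_ids),
        n_samples_used=a.n_samples_used + b.n_samples_used,
        n_blocks=a.n_blocks + b.n_blocks,
    )


def paired_contrast(
    zA: list[ConnectivityMatrix] | np.ndarray,
    zB: list[ConnectivityMatrix] | np.ndarray,
    label: str = "",
    alpha: float = 0.005,
    q: float = 0.05,
    channel_ids: list[int] | None = None,
) -> ContrastMatrix:
    """Connection-wise paired t-test between two conditions.

    Accepts participant-stacked arrays (P, n, n) or lists of matrices from
    the same participants in the same order. Zero-variance connections
    yield t = 0, p = 1 when every paired difference is zero and are an
    error otherwise (the statistic is undefined). Uncorrected masks use
    two-sided p < ``alpha`` split by the sign of t; BH-adjusted p over the
    upper-triangle connections is also reported.
    """
    if isinstance(zA, list):
        pidsA = [m.participant_id for m in zA]
        pidsB = [m.participant_id for m in zB]
        if pidsA != pidsB:
            raise ValueError("participant mismatch between conditions")
        if channel_ids is None:
            channel_ids = list(zA[0].channel_ids)
        zA = np.stack([m.z for m in zA])
        zB = np.stack([m.z for m in zB])
    zA = np.asarray(zA, float)
    zB = np.asarray(zB, float)
    if zA.shape != zB.shape:
        raise ValueError("condition stacks must have identical shapes")
    P, n, _ = zA.shape
    if P < 2:
        raise ValueError("paired contrast needs at least 2 participants")
    diff = zA - zB  # (P, n, n)
    df = P - 1
    finite = np.isfinite(diff)
    cnt = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(np.where(finite, diff, 0.0), axis=0) / cnt
        ss = np.nansum(np.where(finite, (diff - mean) ** 2, 0.0), axis=0)
        sd = np.sqrt(ss / np.maximum(cnt - 1, 1))
    degenerate = (sd == 0) & (cnt >= 2)
    if np.any(degenerate & (mean != 0)):
        i, j = np.argwhere(degenerate & (mean != 0))[0]
        raise ZeroDivisionError(
            f"connection ({i}, {j}): identical nonzero paired differences, "
            "t statistic undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(cnt))
        p = 2 * stats.t.sf(np.abs(t), cnt - 1)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    t = np.where(cnt >= 2, t, np.nan)
    p = np.where(cnt >= 2, p, np.nan)
    np.fill_diagonal(t, np.nan)
    np.fill_diagonal(p, np.nan)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    mask_pos = (p < alpha) & (t > 0)
    mask_neg = (p < alpha) & (t < 0)
    p_fdr = np.full((n, n), np.nan)
    pv = p[iu]
    finite = np.isfinite(pv)
    if finite.any():
        adj = np.full(pv.shape, np.nan)
        adj[finite], _ = fdr_bh(pv[finite], q)
        p_fdr[iu] = adj
        p_fdr.T[iu] = adj
    return ContrastMatrix(
        t=t,
        p=p,
        neglog10p=neglog,
        mask_pos=mask_pos,
        mask_neg=mask_neg,
        p_fdr=p_fdr,
        label=label,
        df=df,
        channel_ids=channel_ids or list(range(1, n + 1)),
    )


def contrast_to_csv(cm: ContrastMatrix, path, which: str = "neglog10p") -> None:
    """Write one statistic matrix as CSV with region-ordered channel labels."""
    mat = getattr(cm, which)
    labels = [f"CH{c}" for c in cm.channel_ids]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)


def read_contrast_csv(path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, index_col=0)
    ids = [int(c.lstrip("CH")) for c in df.columns]
    return df.to_numpy(dtype=float), ids


def render_contrast(
    cm: ContrastMatrix,
    cmap: ChannelMap | None = None,
    path=None,
    group_boundaries: list[int] | None = None,
):
    """Heatmap of -log10(p) in region order with significance boxes.

    Positive (condition A > B) and negative significant connections at the
    uncorrected threshold are outlined. Returns the matplotlib figure;
    saves to ``path`` when given (vector formats supported by matplotlib).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n = cm.t.shape[0]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(np.where(np.isfinite(cm.neglog10p), cm.neglog10p, 0.0), cmap="viridis")
    fig.colorbar(im, ax=ax, label="-log10(p)")
    if cmap is not None and group_boundaries is None:
        # boundaries where the region label changes along the ordered axis
        regions = []
        lookup = {ch.channel_id: ch.region for ch in cmap.channels}
        for cid in cm.channel_ids:
            regions.append(lookup.get(cid))
        group_boundaries = [
            i for i in range(1, len(regions)) if regions[i] != regions[i - 1]
        ]
    for b in group_boundaries or []:
        ax.axhline(b - 0.5, color="w", lw=0.8)
        ax.axvline(b - 0.5, color="w", lw=0.8)
    for i, j in zip(*np.where(cm.mask_pos)):
        ax.add_patch(Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="red", lw=1.2))
    for i, j in zip(*np.where(cm.mask_neg)):
        ax.add_patch(Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="cyan", lw=1.2))
    step = max(1, n // 20)
    ticks = list(range(0, n, step))
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"CH{cm.channel_ids[i]}" for i in ticks], rotation=90, fontsize=6)
    ax.set_yticks(ticks)
    ax.set_yticklabels([f"CH{cm.channel_ids[i]}" for i in ticks], fontsize=6)
    ax.set_title(cm.label or "connectivity contrast")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
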