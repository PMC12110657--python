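"""Canonical double-gamma hemodynamic response function.

The kernel serves two roles in the pipeline: peak-normalized it is the
convolution kernel for GLM condition regressors; sum-normalized it is the
impulse response of the hemodynamic low-pass filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "canonical_hrf"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma parameters (seconds): response peaking at ``peak_delay``
    with an undershoot at ``undershoot_delay`` scaled by ``undershoot_ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def canonical_hrf(
    fs: float, params: HRFParams | None = None, norm: str = "peak"
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at rate ``fs``.

    h(t) = g(t; a1, b) - r * g(t; a2, b) with gamma pdfs g, shape
    a = delay / dispersion and scale b = dispersion, over [0, duration).

    norm="peak" scales to unit maximum (GLM regressors); norm="sum" scales
    to unit sum (low-pass kernel, preserving the mean of filtered signals).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    p = params or HRFParams()
    t = np.arange(0, p.duration, 1.0 / fs)
    peak = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - p.undershoot_ratio * under
    if norm == "peak":
        return h / h.max()
    if norm == "sum":
        return h / h.sum()
    raise ValueError(f"unknown norm {norm!r}")
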