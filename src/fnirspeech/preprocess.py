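"""Intensity-to-hemoglobin conversion and the preprocessing chain.

Stages, in order: optical-density change, modified Beer-Lambert inversion
(two wavelengths, two chromophores), sliding-window quality control on HbO,
temporal derivative distribution repair (TDDR) motion correction, DCT
high-pass drift removal (0.0078 Hz), and a hemodynamic low-pass filter
whose kernel is the sum-normalized canonical HRF.

Concentration changes are expressed in mM*mm (molar concentration change
times effective pathlength); no differential-pathlength factor is applied,
so units cancel in all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssig

from .hrf import HRFParams, canonical_hrf
from .io import RawRecording

__all__ = [
    "HbSeries",
    "QCConfig",
    "QCReport",
    "FilterConfig",
    "TDDRConfig",
    "PreprocessConfig",
    "EXTINCTION_COEFFS",
    "intensity_to_od",
    "mbll",
    "sliding_window_qc",
    "tddr",
    "dct_highpass",
    "hrf_lowpass",
    "preprocess_recording",
]

#: Molar extinction coefficients, 1/(mM*mm), from the standard literature
#: compilation for hemoglobin, keyed by wavelength in nm:
#: {wavelength: (epsilon_HbO, epsilon_HbR)}.
EXTINCTION_COEFFS: dict[float, tuple[float, float]] = {
    695.0: (0.03174, 0.18628),
    830.0: (0.09740, 0.06930),
}


@dataclass
class HbSeries:
    """Hemoglobin concentration-change series, time x channel, mM*mm."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_ids: list[int] = field(default_factory=list)
    participant_id: str = ""
    block_id: int = 1

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr shapes differ")
        if not self.channel_ids:
            self.channel_ids = list(range(1, self.hbo.shape[1] + 1))

    @property
    def thb(self) -> np.ndarray:
        """Total hemoglobin; identically HbO + HbR at every stage."""
        return self.hbo + self.hbr

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]


@dataclass(frozen=True)
class QCConfig:
    """Sliding-window artifact detection: non-overlapping ``window_s``
    windows; samples beyond ``sd_multiplier`` window SDs are artifacts;
    channels with more than ``max_artifact_fraction`` flagged are excluded.
    """

    window_s: float = 5.0
    sd_multiplier: float = 3.0
    max_artifact_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.sd_multiplier <= 0:
            raise ValueError("window_s and sd_multiplier must be positive")
        if not 0 < self.max_artifact_fraction < 1:
            raise ValueError("max_artifact_fraction must lie in (0, 1)")


@dataclass
class QCReport:
    artifact_fraction: dict[int, float]
    excluded_channels: set[int]
    artifact_mask: np.ndarray  # (T, C) bool

    def to_dict(self) -> dict:
        return {
            "artifact_fraction": {str(k): v for k, v in self.artifact_fraction.items()},
            "excluded_channels": sorted(self.excluded_channels),
        }


@dataclass(frozen=True)
class TDDRConfig:
    biweight_c: float = 4.685
    tol: float = 1e-8
    max_iter: int = 50
    deriv_lowpass_hz: float = 0.5


@dataclass(frozen=True)
class FilterConfig:
    highpass_cutoff_hz: float = 0.0078
    hrf_params: HRFParams = field(default_factory=HRFParams)


@dataclass(frozen=True)
class PreprocessConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    tddr: TDDRConfig = field(default_factory=TDDRConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    baseline_window_s: tuple[float, float] | None = None  # None = whole recording
    run_tddr: bool = True
    run_highpass: bool = True
    run_lowpass: bool = True
    manual_exclusions: frozenset[int] = frozenset()


def intensity_to_od(
    rec: RawRecording, baseline_window_s: tuple[float, float] | None = None
) -> np.ndarray:
    """Optical-density change relative to the baseline-window mean intensity.

    dOD(t) = -log10(I(t) / mean_baseline(I)); zero-mean over the baseline
    window only in the sense that the reference is that window's mean.
    """
    i0, i1 = (0.0, rec.duration_s) if baseline_window_s is None else baseline_window_s
    s0, s1 = int(round(i0 * rec.fs)), int(round(i1 * rec.fs))
    if s1 <= s0:
        raise ValueError("baseline window is empty")
    ref = rec.intensities[s0:s1].mean(axis=0, keepdims=True)
    return -np.log10(rec.intensities / ref)


def extinction_matrix(
    wavelengths: tuple[float, float],
    table: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    table = table if table is not None else EXTINCTION_COEFFS
    try:
        rows = [table[float(w)] for w in wavelengths]
    except KeyError as err:
        raise KeyError(f"no extinction coefficients for wavelength {err}") from None
    E = np.asarray(rows, dtype=float)  # (2 wavelengths, 2 species)
    if abs(np.linalg.det(E)) < 1e-12:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    return E


def mbll(
    od: np.ndarray,
    wavelengths: tuple[float, float] = (695.0, 830.0),
    extinction_table: dict[float, tuple[float, float]] | None = None,
    fs: float = 10.0,
    channel_ids: list[int] | None = None,
) -> HbSeries:
    """Modified Beer-Lambert inversion of dOD to (dHbO, dHbR) per sample.

    Solves E @ [dHbO, dHbR] = dOD for each sample and channel, where E is
    the 2x2 extinction matrix; linear in dOD by construction.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise ValueError(f"od must be (T, C, 2), got {od.shape}")
    E = extinction_matrix(wavelengths, extinction_table)
    Einv = np.linalg.inv(E)
    hb = od @ Einv.T  # (T, C, 2) -> species axis
    return HbSeries(
        hbo=hb[:, :, 0], hbr=hb[:, :, 1], fs=fs, channel_ids=channel_ids or []
    )


def sliding_window_qc(hbo: np.ndarray, fs: float, cfg: QCConfig | None = None) -> QCReport:
    """Flag artifact samples per channel using non-overlapping windows.

    Within each ``window_s`` window the HbO mean and SD are computed;
    samples with |x - mean| > k*SD are artifacts. A trailing remainder of
    at least 2 samples forms its own (shorter) final window, otherwise it
    joins the previous window. Channels whose artifact fraction exceeds
    the threshold are reported excluded.
    """
    cfg = cfg or QCConfig()
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    T, C = hbo.shape
    win = int(round(cfg.window_s * fs))
    if T < win:
        raise ValueError(f"series length {T} is shorter than one {cfg.window_s} s window")
    edges = list(range(0, T - win + 1, win))
    bounds = [(s, s + win) for s in edges]
    rem = T - (edges[-1] + win)
    if rem >= 2:
        bounds.append((edges[-1] + win, T))
    elif rem > 0:
        bounds[-1] = (bounds[-1][0], T)

    mask = np.zeros((T, C), dtype=bool)
    for s, e in bounds:
        seg = hbo[s:e]
        mu = seg.mean(axis=0)
        sd = seg.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore"):
            flagged = np.abs(seg - mu) > cfg.sd_multiplier * sd
        flagged[:, sd == 0] = False  # constant window: nothing to flag
        mask[s:e] = flagged
    frac = mask.mean(axis=0)
    return QCReport(
        artifact_fraction={c + 1: float(frac[c]) for c in range(C)},
        excluded_channels={c + 1 for c in range(C) if frac[c] > cfg.max_artifact_fraction},
        artifact_mask=mask,
    )


def tddr(series: np.ndarray, fs: float, cfg: TDDRConfig | None = None) -> np.ndarray:
    """Temporal Derivative Distribution Repair motion correction.

    Robustly reweights the temporal derivative of the low-frequency part of
    the signal with a Tukey biweight (iteratively reweighted location
    estimate on derivatives scaled by 1.4826*MAD), reintegrates, and adds
    back the untouched high-frequency residual. Deterministic; preserves
    slow trends while collapsing spike and step artifacts.
    """
    cfg = cfg or TDDRConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim == 2:
        out = np.empty_like(x)
        for c in range(x.shape[1]):
            out[:, c] = tddr(x[:, c], fs, cfg)
        return out
    if np.any(~np.isfinite(x)):
        raise ValueError("TDDR input contains NaN or infinite samples")
    if x.size < 3:
        return x.copy()

    mean = x.mean()
    signal = x - mean
    # split off fluctuations faster than the artifact band
    wn = 2 * cfg.deriv_lowpass_hz / fs
    if wn < 1:
        fb, fa = ssig.butter(3, wn)
        low = ssig.filtfilt(fb, fa, signal, padlen=0)
    else:
        low = signal.copy()
    high = signal - low

    deriv = np.diff(low)
    w = np.ones_like(deriv)
    mu = 0.0
    for _ in range(cfg.max_iter):
        mu = np.sum(w * deriv) / np.sum(w)
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * np.median(dev)
        if sigma == 0:
            break
        r = dev / (cfg.biweight_c * sigma)
        w_new = np.where(r < 1, (1 - r**2) ** 2, 0.0)
        done = np.max(np.abs(w_new - w)) < cfg.tol
        w = w_new
        if done:
            break
    corrected_deriv = w * (deriv - mu)
    low_corrected = np.concatenate([[0.0], np.cumsum(corrected_deriv)])
    low_corrected -= low_corrected.mean()
    return low_corrected + high + mean


def _dct_keep_mask(n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    # DCT-II basis k has frequency k*fs/(2n)
    freqs = np.arange(n) * fs / (2 * n)
    return freqs >= cutoff_hz


def dct_highpass(series: np.ndarray, fs: float, cutoff_hz: float = 0.0078) -> np.ndarray:
    """Project out discrete-cosine components below ``cutoff_hz``.

    Removes the span of DCT-II basis functions (including the constant)
    whose frequency k*fs/(2N) lies below the cutoff. Linear and idempotent.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2} Hz")
    coef = sfft.dct(x, type=2, norm="ortho", axis=0)
    keep = _dct_keep_mask(n, fs, cutoff_hz)
    coef[~keep] = 0.0
    return sfft.idct(coef, type=2, norm="ortho", axis=0)


def hrf_lowpass(
    series: np.ndarray, fs: float, params: HRFParams | None = None
) -> np.ndarray:
    """Causal convolution with the unit-sum canonical-HRF kernel.

    The input is edge-padded at the start with its first sample so the
    output has the input's length; a constant series passes unchanged.
    """
    x = np.asarray(series, dtype=float)
    kernel = canonical_hrf(fs, params, norm="sum")
    if x.ndim == 2:
        out = np.empty_like(x)
        for c in range(x.shape[1]):
            out[:, c] = hrf_lowpass(x[:, c], fs, params)
        return out
    pad = np.full(kernel.size - 1, x[0])
    return np.convolve(np.concatenate([pad, x]), kernel, mode="valid")


def preprocess_recording(
    rec: RawRecording, cfg: PreprocessConfig | None = None
) -> tuple[HbSeries, QCReport]:
    """Full chain: MBLL -> QC -> TDDR -> DCT high-pass -> HRF low-pass.

    QC runs on HbO immediately after the Beer-Lambert step (before motion
    correction and filtering); excluded channels are reported but their
    series are still carried through so downstream code can mask them.
    """
    cfg = cfg or PreprocessConfig()
    od = intensity_to_od(rec, cfg.baseline_window_s)
    hb = mbll(od, rec.wavelengths, fs=rec.fs, channel_ids=rec.channel_ids)

    qc = sliding_window_qc(hb.hbo, rec.fs, cfg.qc)
    qc.excluded_channels = {
        rec.channel_ids[i - 1] for i in qc.excluded_channels
    } | set(cfg.manual_exclusions)
    qc.artifact_fraction = {
        rec.channel_ids[i - 1]: f for i, f in qc.artifact_fraction.items()
    }

    hbo, hbr = hb.hbo, hb.hbr
    if cfg.run_tddr:
        hbo = tddr(hbo, rec.fs, cfg.tddr)
        hbr = tddr(hbr, rec.fs, cfg.tddr)
    if cfg.run_highpass:
        hbo = dct_highpass(hbo, rec.fs, cfg.filters.highpass_cutoff_hz)
        hbr = dct_highpass(hbr, rec.fs, cfg.filters.highpass_cutoff_hz)
    if cfg.run_lowpass:
        hbo = hrf_lowpass(hbo, rec.fs, cfg.filters.hrf_params)
        hbr = hrf_lowpass(hbr, rec.fs, cfg.filters.hrf_params)
    out = HbSeries(
        hbo=hbo,
        hbr=hbr,
        fs=rec.fs,
        channel_ids=list(rec.channel_ids),
        participant_id=rec.participant_id,
        block_id=rec.block_id,
    )
    return out, qc
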