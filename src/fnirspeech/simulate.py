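"""Synthetic participants with known ground truth for every pipeline stage.

The generator emulates the block-design acquisition: per block, a rest
phase, a preparation phase containing annotated private-speech intervals
(the remainder being inner speech), and an execution (outer speech) phase.
Channel HbO is built generatively as

    hbo = sum_cond beta[ch, cond] * (boxcar_cond * HRF)
        + per-condition latent-factor mixtures (inducing target
          channel-pair correlations)
        + physiological sinusoids (Mayer waves ~0.1 Hz, respiration
          ~0.3 Hz, cardiac ~1.2 Hz, random phase per channel)
        + white noise,

HbR as -HbO/3 plus independent noise, and both are projected forward
through the Beer-Lambert extinction matrix to two-wavelength intensities.
Motion artifacts (1-3 sample spikes, persistent baseline shifts) are
injected in optical-density space — i.e. multiplicatively in intensity —
with their indices logged in the ground truth.

Default magnitudes are desk-realistic for continuous-wave fNIRS expressed
in mM*mm: task betas of a few hundredths, white noise SD 0.05 per sample
at 10 Hz, physiological amplitudes 0.01-0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hrf import HRFParams, canonical_hrf
from .io import (
    EventAnnotation,
    RawRecording,
    Token,
    write_events,
    write_json,
    write_raw,
    write_transcript,
)
from .montage import paper_montage
from .preprocess import EXTINCTION_COEFFS
from .segmentation import build_condition_timeline

__all__ = [
    "BlockTiming",
    "PhysioSpec",
    "MotionSpec",
    "PrivateSegmentSpec",
    "SimulationConfig",
    "GroundTruth",
    "ParticipantSim",
    "mini_config",
    "full_config",
    "pair_loading_for_r",
    "simulate_participant",
    "simulate_group",
]


@dataclass(frozen=True)
class BlockTiming:
    """Phase durations of one task block, seconds."""

    rest_s: float = 180.0
    prep_s: float = 600.0
    exec_s: float = 300.0

    @property
    def total_s(self) -> float:
        return self.rest_s + self.prep_s + self.exec_s


@dataclass(frozen=True)
class PhysioSpec:
    """Physiological oscillations: amplitude (mM*mm) per frequency (Hz)."""

    freqs_hz: tuple[float, ...] = (0.1, 0.3, 1.2)
    amplitudes: tuple[float, ...] = (0.02, 0.01, 0.015)


@dataclass(frozen=True)
class MotionSpec:
    """Motion artifacts injected in optical-density space."""

    spike_rate_per_min: float = 2.0
    spike_od_amplitude: float = 0.2
    spike_len_samples: tuple[int, int] = (1, 3)
    shift_rate_per_min: float = 0.2
    shift_od_amplitude: float = 0.05


@dataclass(frozen=True)
class PrivateSegmentSpec:
    """Distribution of private-speech intervals within preparation."""

    n_intervals: int = 8
    min_len_s: float = 10.0
    max_len_s: float = 30.0
    min_gap_s: float = 2.0


@dataclass
class SimulationConfig:
    n_channels: int = 44
    fs: float = 10.0
    timing: BlockTiming = field(default_factory=BlockTiming)
    n_blocks: int = 2
    true_betas: np.ndarray | None = None  # (C, 3): private, inner, outer
    white_sd: float = 0.05
    hbr_noise_sd: float = 0.017
    physio: PhysioSpec = field(default_factory=PhysioSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    ps_segments: PrivateSegmentSpec = field(default_factory=PrivateSegmentSpec)
    #: per-condition latent-factor loadings, condition -> (C, K)
    connectivity_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    hrf_params: HRFParams = field(default_factory=HRFParams)
    wavelengths: tuple[float, float] = (695.0, 830.0)
    baseline_intensity: float = 1000.0

    def betas(self) -> np.ndarray:
        if self.true_betas is None:
            return np.zeros((self.n_channels, 3))
        b = np.asarray(self.true_betas, dtype=float)
        if b.shape != (self.n_channels, 3):
            raise ValueError(f"true_betas must be ({self.n_channels}, 3)")
        return b


def full_config(**kw) -> SimulationConfig:
    """Study-scale configuration: 3 min rest, 10 min preparation, 5 min
    execution, two blocks, 44 channels at 10 Hz."""
    return SimulationConfig(**kw)


def mini_config(**kw) -> SimulationConfig:
    """Scaled-down profile (1 min rest, 3 min preparation, 1.5 min
    execution) preserving all structural features; suited to fast tests."""
    kw.setdefault("timing", BlockTiming(rest_s=60.0, prep_s=180.0, exec_s=90.0))
    kw.setdefault(
        "ps_segments", PrivateSegmentSpec(n_intervals=3, min_len_s=8.0, max_len_s=15.0)
    )
    return SimulationConfig(**kw)


def pair_loading_for_r(r_target: float, noise_sd: float) -> float:
    """Loading a for a single shared unit-variance factor on two channels
    with independent noise SD sigma, so that corr = a^2/(a^2+sigma^2) hits
    ``r_target``."""
    if not 0 < r_target < 1:
        raise ValueError("target correlation must lie in (0, 1)")
    return noise_sd * np.sqrt(r_target / (1 - r_target))


@dataclass
class GroundTruth:
    true_betas: np.ndarray  # (C, 3)
    private_intervals: list[list[tuple[float, float]]]  # per block
    artifact_spans: list[list[tuple[int, int, int]]]  # per block: (chan_idx, start, stop)
    connectivity_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def expected_r(self, condition: str, i: int, j: int, noise_var: float) -> float:
        """Model-implied Pearson correlation between channel indices i, j
        during a condition, given total per-channel noise variance."""
        L = self.connectivity_loadings.get(condition)
        if L is None:
            return 0.0
        cov = float(L[i] @ L[j])
        vi = float(L[i] @ L[i]) + noise_var
        vj = float(L[j] @ L[j]) + noise_var
        return cov / np.sqrt(vi * vj)

    def to_dict(self) -> dict:
        return {
            "true_betas": self.true_betas.tolist(),
            "private_intervals": self.private_intervals,
            "artifact_spans": self.artifact_spans,
            "connectivity_loadings": {
                k: v.tolist() for k, v in self.connectivity_loadings.items()
            },
            "seed": self.seed,
        }


@dataclass
class ParticipantSim:
    participant_id: str
    recordings: list[RawRecording]
    events: list[EventAnnotation]
    tokens: list[Token]
    ground_truth: GroundTruth


def _draw_private_intervals(
    rng: np.random.Generator, spec: PrivateSegmentSpec, prep_on: float, prep_off: float, fs: float
) -> list[tuple[float, float]]:
    """Non-overlapping intervals inside [prep_on, prep_off), lengths uniform
    in [min_len, max_len], inter-interval gaps >= min_gap, snapped to the
    sample grid so durations are exact in samples."""
    n = spec.n_intervals
    if n == 0:
        return []
    span = prep_off - prep_on
    lens = rng.uniform(spec.min_len_s, spec.max_len_s, size=n)
    need = lens.sum() + spec.min_gap_s * (n + 1)
    if need > span:
        raise ValueError(
            f"infeasible private-segment spec: {need:.1f} s required, "
            f"{span:.1f} s of preparation available"
        )
    slack = span - need
    gap_extra = rng.dirichlet(np.ones(n + 1)) * slack
    intervals = []
    cursor = prep_on
    for k in range(n):
        cursor += spec.min_gap_s + gap_extra[k]
        onset = round(cursor * fs) / fs
        offset = round((cursor + lens[k]) * fs) / fs
        intervals.append((onset, offset))
        cursor += lens[k]
    return intervals


def _simulate_block(
    cfg: SimulationConfig, rng: np.random.Generator, block_id: int, participant_id: str
) -> tuple[RawRecording, EventAnnotation, list[tuple[int, int, int]], list[tuple[float, float]], list[Token]]:
    fs, C = cfg.fs, cfg.n_channels
    tim = cfg.timing
    rest_off = tim.rest_s
    prep_off = tim.rest_s + tim.prep_s
    exec_off = tim.total_s
    T = int(round(exec_off * fs))

    private = _draw_private_intervals(rng, cfg.ps_segments, rest_off, prep_off, fs)
    intervals = [
        ("rest", 0.0, rest_off),
        ("preparation", rest_off, prep_off),
        ("execution", prep_off, exec_off),
    ] + [("private_speech", on, off) for on, off in private]
    events = EventAnnotation(intervals=intervals, block_id=block_id)
    timeline = build_condition_timeline(events, fs, exec_off, min_segment_s=0.0)

    # neural response: HRF-convolved condition boxcars times per-channel betas
    hrf = canonical_hrf(fs, cfg.hrf_params, norm="peak")
    betas = cfg.betas()
    hbo = np.zeros((T, C))
    for k, cond in enumerate(("private", "inner", "outer")):
        box = timeline.mask(cond).astype(float)
        if box.any():
            reg = np.convolve(box, hrf)[:T]
            hbo += np.outer(reg, betas[:, k])

    # per-condition latent factors inducing channel-pair correlation
    for cond, L in cfg.connectivity_loadings.items():
        L = np.asarray(L, dtype=float)
        mask = timeline.mask(cond)
        if not mask.any():
            continue
        s = rng.standard_normal((T, L.shape[1]))
        hbo[mask] += s[mask] @ L.T

    # physiology: random phase per channel and rhythm
    t = np.arange(T) / fs
    for f, a in zip(cfg.physio.freqs_hz, cfg.physio.amplitudes):
        if a == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=C)
        hbo += a * np.sin(2 * np.pi * f * t[:, None] + phase[None, :])

    if cfg.white_sd > 0:
        hbo += rng.normal(0, cfg.white_sd, size=(T, C))
    hbr = -hbo / 3.0
    if cfg.hbr_noise_sd > 0:
        hbr = hbr + rng.normal(0, cfg.hbr_noise_sd, size=(T, C))

    # forward Beer-Lambert projection to optical density, then intensity
    E = np.asarray([EXTINCTION_COEFFS[w] for w in cfg.wavelengths])  # (2, 2)
    od = np.stack([hbo, hbr], axis=-1) @ E.T  # (T, C, 2)

    # motion artifacts in OD space (multiplicative in intensity)
    spans: list[tuple[int, int, int]] = []
    minutes = exec_off / 60.0
    m = cfg.motion
    for c in range(C):
        for _ in range(rng.poisson(m.spike_rate_per_min * minutes)):
            start = int(rng.integers(0, T - m.spike_len_samples[1]))
            length = int(rng.integers(m.spike_len_samples[0], m.spike_len_samples[1] + 1))
            amp = m.spike_od_amplitude * rng.choice([-1.0, 1.0])
            od[start : start + length, c, :] += amp
            spans.append((c, start, start + length))
        for _ in range(rng.poisson(m.shift_rate_per_min * minutes)):
            start = int(rng.integers(0, T))
            amp = m.shift_od_amplitude * rng.choice([-1.0, 1.0])
            od[start:, c, :] += amp
            spans.append((c, start, T))

    intensity = cfg.baseline_intensity * 10.0 ** (-od)
    rec = RawRecording(
        intensities=intensity,
        wavelengths=cfg.wavelengths,
        fs=fs,
        participant_id=participant_id,
        block_id=block_id,
    )

    # timed transcript: tokens inside private intervals, ~2.5 words/s
    tokens: list[Token] = []
    for on, off in private:
        times = np.arange(on + 0.2, off - 0.1, 0.4)
        for w, tt in enumerate(times):
            lang = "ZH" if rng.random() < 0.3 else "EN"
            tokens.append(Token(f"b{block_id}w{len(tokens)}", lang, round(float(tt), 3)))
    return rec, events, spans, private, tokens


def simulate_participant(
    cfg: SimulationConfig, seed: int | np.random.SeedSequence, participant_id: str = "sub-01"
) -> ParticipantSim:
    """Generate one participant: two-block raw recordings, annotations,
    a timed transcript, and the ground truth that produced them.

    Deterministic: the same seed yields bit-identical output.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    recordings, events, tokens = [], [], []
    spans_all, private_all = [], []
    for b in range(1, cfg.n_blocks + 1):
        rec, ev, spans, private, toks = _simulate_block(cfg, rng, b, participant_id)
        recordings.append(rec)
        events.append(ev)
        spans_all.append(spans)
        private_all.append(private)
        # transcript times on a session clock: blocks follow one another
        offset = (b - 1) * cfg.timing.total_s
        tokens.extend(Token(t.word, t.language, t.time_s + offset) for t in toks)
    gt = GroundTruth(
        true_betas=cfg.betas(),
        private_intervals=private_all,
        artifact_spans=spans_all,
        connectivity_loadings={
            k: np.asarray(v, float) for k, v in cfg.connectivity_loadings.items()
        },
        seed=ss.entropy if isinstance(ss.entropy, int) else None,
    )
    return ParticipantSim(participant_id, recordings, events, tokens, gt)


def simulate_group(
    cfg: SimulationConfig,
    n_per_group: int = 16,
    effect_spec: dict | None = None,
    master_seed: int = 0,
    outdir: str | Path | None = None,
    between_sd: float = 0.02,
) -> list[ParticipantSim]:
    """Generate two proficiency groups of independent participants.

    ``effect_spec`` plants group-level structure:

    - ``{"beta": {(group, condition): {channel_id: effect}}}`` adds a mean
      beta offset (mM*mm) for the named channels;
    - ``{"fc": {(group, condition): [(ch_i, ch_j, r_target)]}}`` installs a
      shared latent factor on a channel pair targeting correlation r.

    Each participant additionally receives i.i.d. normal between-subject
    beta variation with SD ``between_sd``. When ``outdir`` is given, the
    on-disk layout consumed by the CLI is written (per-participant raw
    HDF5 per block, events and transcript TSVs, a participants table, and
    ``ground_truth.json``).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    effect_spec = effect_spec or {}
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * n_per_group + 1)
    meta_rng = np.random.default_rng(children[-1])

    sims: list[ParticipantSim] = []
    rows = []
    base = cfg.betas()
    for gi, group in enumerate(("high", "low")):
        for k in range(n_per_group):
            idx = gi * n_per_group + k
            pid = f"sub-{idx + 1:02d}"
            betas_i = base.copy()
            for (g, cond), chan_effects in effect_spec.get("beta", {}).items():
                if g != group:
                    continue
                ci = {"private": 0, "inner": 1, "outer": 2}[cond]
                for cid, eff in chan_effects.items():
                    betas_i[int(cid) - 1, ci] += eff
            rng_b = np.random.default_rng(children[idx].spawn(1)[0])
            betas_i += rng_b.normal(0, between_sd, size=betas_i.shape)
            loadings = dict(cfg.connectivity_loadings)
            for (g, cond), pairs in effect_spec.get("fc", {}).items():
                if g != group:
                    continue
                cols = []
                for (ci, cj, r_target) in pairs:
                    a = pair_loading_for_r(r_target, cfg.white_sd)
                    v = np.zeros(cfg.n_channels)
                    v[int(ci) - 1] = a
                    v[int(cj) - 1] = a
                    cols.append(v)
                extra = np.column_stack(cols)
                L0 = loadings.get(cond)
                loadings[cond] = (
                    extra if L0 is None else np.column_stack([np.asarray(L0), extra])
                )
            cfg_i = SimulationConfig(
                **{
                    **cfg.__dict__,
                    "true_betas": betas_i,
                    "connectivity_loadings": loadings,
                }
            )
            sims.append(simulate_participant(cfg_i, children[idx], pid))
            rows.append({"participant_id": pid, "group": group})

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "participants.tsv", sep="\t", index=False)
        from .montage import write_montage_yaml

        write_montage_yaml(paper_montage(), outdir / "montage.yaml")
        gt_all = {}
        for sim, row in zip(sims, rows):
            pdir = outdir / sim.participant_id
            pdir.mkdir(exist_ok=True)
            for rec in sim.recordings:
                write_raw(rec, pdir / f"block-{rec.block_id}_raw.h5")
            write_events(sim.events, pdir / "events.tsv")
            write_transcript(sim.tokens, pdir / "transcript.tsv")
            gt_all[sim.participant_id] = sim.ground_truth.to_dict()
        write_json(
            {"master_seed": master_seed, "participants": gt_all},
            outdir / "ground_truth.json",
        )
    return sims
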