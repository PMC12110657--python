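"""Condition timelines and preparation-phase speech coding.

The task block has three annotated phases: rest, preparation and
execution. Within preparation, annotated intervals of overt self-directed
speech define the *private speech* condition; the remaining preparation
time is *inner speech*; the execution phase is *outer speech*.

Behavioral coding of the preparation phase counts utterances (speech
segments separated by a pause exceeding two seconds) and words (English
plus Chinese), and derives utterances per second of cumulative private
speech and words per utterance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import EventAnnotation, Token

__all__ = [
    "CONDITIONS",
    "ConditionTimeline",
    "Utterance",
    "PrivateSpeechMeasures",
    "build_condition_timeline",
    "segment_utterances",
    "private_speech_measures",
]

#: Per-sample label codes, in order.
CONDITIONS = ("unlabeled", "rest", "private", "inner", "outer")
_CODE = {name: i for i, name in enumerate(CONDITIONS)}


@dataclass
class ConditionTimeline:
    """Per-sample condition labels at a fixed sampling rate."""

    labels: np.ndarray  # (T,) int codes into CONDITIONS
    fs: float

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def label_names(self) -> np.ndarray:
        return np.asarray(CONDITIONS)[self.labels]

    def mask(self, condition: str) -> np.ndarray:
        return self.labels == _CODE[condition]

    def segments(self, condition: str) -> list[tuple[int, int]]:
        """Half-open [start, stop) sample-index runs of the condition."""
        m = self.mask(condition)
        if not m.any():
            return []
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]

    def segments_s(self, condition: str) -> list[tuple[float, float]]:
        return [(s / self.fs, e / self.fs) for s, e in self.segments(condition)]

    def duration_s(self, condition: str) -> float:
        return float(self.mask(condition).sum()) / self.fs


def _to_index(t_s: float, fs: float) -> int:
    # sample i covers time i/fs; t in [onset, offset) maps to
    # indices [ceil(onset*fs), ceil(offset*fs)) with an epsilon guard so
    # grid-aligned times land exactly.
    return int(math.ceil(t_s * fs - 1e-9))


def build_condition_timeline(
    events: EventAnnotation,
    fs: float,
    duration_s: float | None = None,
    min_segment_s: float = 1.0,
) -> ConditionTimeline:
    """Per-sample condition labels from one block's annotations.

    Sample i receives the label of the interval containing time i/fs.
    Preparation samples not covered by a private-speech interval are inner
    speech; execution is outer speech. Runs shorter than ``min_segment_s``
    (after labeling) are merged into the preceding run's label — a
    correlation or regressor over an ultra-short fragment is meaningless.
    """
    if duration_s is None:
        duration_s = events.duration_s
    n = _to_index(duration_s, fs)
    labels = np.zeros(n, dtype=np.int8)  # unlabeled

    phase_to_cond = {"rest": "rest", "preparation": "inner", "execution": "outer"}
    for label, onset, offset in events.phases():
        s, e = _to_index(onset, fs), min(_to_index(offset, fs), n)
        labels[s:e] = _CODE[phase_to_cond[label]]
    preps = [iv for iv in events.phases() if iv[0] == "preparation"]
    for onset, offset in events.private_intervals():
        if not any(on <= onset and offset <= off for _, on, off in preps):
            raise ValueError(
                f"private interval [{onset}, {offset}) outside preparation"
            )
        s, e = _to_index(onset, fs), min(_to_index(offset, fs), n)
        labels[s:e] = _CODE["private"]

    if min_segment_s > 0:
        min_len = int(round(min_segment_s * fs))
        labels = _merge_short_runs(labels, min_len)
    return ConditionTimeline(labels=labels, fs=fs)


def _merge_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Relabel runs shorter than ``min_len`` with the preceding run's label
    (the following run's label for a short run at the start)."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        edges = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], edges])
        stops = np.concatenate([edges, [len(labels)]])
        if len(starts) == 1:
            break
        for i, (s, e) in enumerate(zip(starts, stops)):
            if e - s < min_len:
                repl = labels[starts[i - 1]] if i > 0 else labels[stops[i]]
                labels[s:e] = repl
                changed = True
                break
    return labels


@dataclass(frozen=True)
class Utterance:
    """A maximal run of tokens with inter-token gaps <= the pause threshold."""

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("an utterance must contain at least one token")

    @property
    def onset(self) -> float:
        return self.tokens[0].time_s

    @property
    def offset(self) -> float:
        return self.tokens[-1].time_s

    @property
    def n_words(self) -> int:
        return len(self.tokens)


def segment_utterances(tokens: list[Token], pause_s: float = 2.0) -> list[Utterance]:
    """Split a timed token stream into utterances at pauses.

    A new utterance begins whenever the gap to the previous token strictly
    exceeds ``pause_s``; a gap exactly equal to the threshold does not
    split. Tokens must be time-sorted.
    """
    if not tokens:
        return []
    times = [t.time_s for t in tokens]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("tokens must be sorted by time")
    utterances: list[list[Token]] = [[tokens[0]]]
    for prev, cur in zip(tokens, tokens[1:]):
        if cur.time_s - prev.time_s > pause_s:
            utterances.append([cur])
        else:
            utterances[-1].append(cur)
    return [Utterance(tuple(u)) for u in utterances]


@dataclass(frozen=True)
class PrivateSpeechMeasures:
    """U, W_PS, U/S and W/U of one participant's preparation phase."""

    n_utterances: int  # U
    n_words: int  # W_PS, English + Chinese
    utterances_per_second: float | None  # U/S
    words_per_utterance: float | None  # W/U; None when U = 0


def private_speech_measures(
    utterances: list[Utterance], cumulative_ps_seconds: float
) -> PrivateSpeechMeasures:
    """Quantitative private-speech measures.

    ``cumulative_ps_seconds`` is the summed duration of all annotated
    private-speech intervals (the S of U/S).
    """
    u = len(utterances)
    w = sum(utt.n_words for utt in utterances)
    if u > 0 and cumulative_ps_seconds <= 0:
        raise ValueError("cumulative private-speech duration must be positive when U > 0")
    ups = u / cumulative_ps_seconds if cumulative_ps_seconds > 0 else None
    wpu = w / u if u > 0 else None
    return PrivateSpeechMeasures(u, w, ups, wpu)
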