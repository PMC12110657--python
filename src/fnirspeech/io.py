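"""Containers and file formats for raw recordings, events and transcripts.

Raw two-wavelength intensity recordings are stored either as long-format
CSV (``time_s,channel,wavelength_nm,intensity``) or as HDF5 (datasets
``/intensity [T x C x 2]`` and ``/time_s``, attributes ``fs``,
``wavelengths_nm``, ``channel_ids``). Event annotations are TSV
(``label,onset_s,offset_s,block``), timed transcripts are TSV
(``word,language,time_s``). All round trips are lossless up to float
representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "EventAnnotation",
    "Token",
    "SchemaError",
    "read_raw",
    "write_raw",
    "read_events",
    "write_events",
    "read_transcript",
    "write_transcript",
]

PHASE_LABELS = ("rest", "preparation", "execution")
EVENT_LABELS = PHASE_LABELS + ("private_speech",)


class SchemaError(ValueError):
    """Raised for malformed input files (names the offending row/field)."""


@dataclass
class RawRecording:
    """Raw optode intensities, time x channel x wavelength, arbitrary units."""

    intensities: np.ndarray  # (T, C, 2), strictly positive
    wavelengths: tuple[float, float] = (695.0, 830.0)
    fs: float = 10.0
    channel_ids: list[int] = field(default_factory=list)
    participant_id: str = ""
    block_id: int = 1

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[2] != 2:
            raise SchemaError(
                f"intensities must be (T, C, 2), got {self.intensities.shape}"
            )
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise SchemaError("intensities contain non-finite values")
        bad = np.argwhere(self.intensities <= 0)
        if bad.size:
            t, c, w = bad[0]
            raise SchemaError(
                f"non-positive intensity at sample {t}, channel index {c}, "
                f"wavelength {self.wavelengths[w]} nm"
            )
        if not self.channel_ids:
            self.channel_ids = list(range(1, self.intensities.shape[1] + 1))
        if len(self.channel_ids) != self.intensities.shape[1]:
            raise SchemaError("channel_ids length does not match intensity array")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class EventAnnotation:
    """Annotated intervals of one block: phases plus private-speech segments.

    Times are seconds from recording start; intervals are half-open
    [onset, offset). Private-speech intervals must nest inside a
    preparation interval; top-level phases must not overlap.
    """

    intervals: list[tuple[str, float, float]]
    block_id: int = 1

    def __post_init__(self) -> None:
        for label, onset, offset in self.intervals:
            if label not in EVENT_LABELS:
                raise SchemaError(f"unknown event label {label!r}")
            if not onset < offset:
                raise SchemaError(
                    f"interval {label!r} has offset {offset} <= onset {onset}"
                )
        phases = sorted(
            [iv for iv in self.intervals if iv[0] in PHASE_LABELS], key=lambda iv: iv[1]
        )
        for (l1, _, off1), (l2, on2, _) in zip(phases, phases[1:]):
            if on2 < off1:
                raise SchemaError(f"phase intervals {l1!r} and {l2!r} overlap")
        preps = [iv for iv in self.intervals if iv[0] == "preparation"]
        for label, onset, offset in self.intervals:
            if label == "private_speech":
                if not any(on <= onset and offset <= off for _, on, off in preps):
                    raise SchemaError(
                        f"private_speech interval [{onset}, {offset}) lies outside "
                        "every preparation interval"
                    )

    def phases(self) -> list[tuple[str, float, float]]:
        return sorted(
            [iv for iv in self.intervals if iv[0] in PHASE_LABELS], key=lambda iv: iv[1]
        )

    def private_intervals(self) -> list[tuple[float, float]]:
        return sorted(
            (on, off) for lab, on, off in self.intervals if lab == "private_speech"
        )

    @property
    def duration_s(self) -> float:
        return max(off for _, _, off in self.intervals)


@dataclass(frozen=True)
class Token:
    """One transcribed word with its onset time."""

    word: str
    language: str  # "EN" | "ZH"
    time_s: float


# ---------------------------------------------------------------------------
# raw recordings


def write_raw(rec: RawRecording, path) -> None:
    """Write a recording as HDF5 (``.h5``/``.hdf5``) or long-format CSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("intensity", data=rec.intensities)
            fh.create_dataset("time_s", data=rec.time_s)
            fh.attrs["fs"] = rec.fs
            fh.attrs["wavelengths_nm"] = list(rec.wavelengths)
            fh.attrs["channel_ids"] = rec.channel_ids
            fh.attrs["participant_id"] = rec.participant_id
            fh.attrs["block_id"] = rec.block_id
    else:
        T, C, _ = rec.intensities.shape
        t = np.repeat(rec.time_s, C * 2)
        ch = np.tile(np.repeat(rec.channel_ids, 2), T)
        wl = np.tile(list(rec.wavelengths), T * C)
        df = pd.DataFrame(
            {
                "time_s": t,
                "channel": ch,
                "wavelength_nm": wl,
                "intensity": rec.intensities.reshape(-1),
            }
        )
        df.to_csv(path, index=False)


def read_raw(path, fs: float | None = None) -> RawRecording:
    """Read a recording written by :func:`write_raw`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            inten = np.asarray(fh["intensity"])
            wl = tuple(float(w) for w in fh.attrs["wavelengths_nm"])
            return RawRecording(
                intensities=inten,
                wavelengths=wl,  # type: ignore[arg-type]
                fs=float(fh.attrs["fs"]),
                channel_ids=[int(c) for c in fh.attrs["channel_ids"]],
                participant_id=str(fh.attrs.get("participant_id", "")),
                block_id=int(fh.attrs.get("block_id", 1)),
            )
    df = pd.read_csv(path)
    required = {"time_s", "channel", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"raw CSV missing columns: {sorted(missing)}")
    wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
    if len(wavelengths) != 2:
        raise SchemaError(
            f"expected exactly two wavelengths, found {wavelengths}"
        )
    channels = sorted(df["channel"].unique())
    times = np.sort(df["time_s"].unique())
    wide = df.pivot_table(
        index="time_s", columns=["channel", "wavelength_nm"], values="intensity"
    )
    if wide.isna().any().any():
        raise SchemaError("raw CSV is not a complete time x channel x wavelength grid")
    inten = np.empty((len(times), len(channels), 2))
    for ci, c in enumerate(channels):
        for wi, w in enumerate(wavelengths):
            inten[:, ci, wi] = wide[(c, w)].to_numpy()
    if fs is None:
        dt = np.diff(times)
        fs = 1.0 / float(np.median(dt)) if len(dt) else 10.0
    return RawRecording(
        intensities=inten,
        wavelengths=wavelengths,  # type: ignore[arg-type]
        fs=float(round(fs, 9)),
        channel_ids=[int(c) for c in channels],
    )


# ---------------------------------------------------------------------------
# events


def write_events(annotations: list[EventAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        for label, onset, offset in ann.intervals:
            rows.append(
                {"label": label, "onset_s": onset, "offset_s": offset, "block": ann.block_id}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path, max_duration_s: float | None = None) -> list[EventAnnotation]:
    """Read per-block event annotations; optionally validate against duration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"label", "onset_s", "offset_s", "block"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"events TSV missing columns: {sorted(missing)}")
    out = []
    for block, grp in df.groupby("block", sort=True):
        intervals = []
        for i, row in grp.iterrows():
            onset, offset = float(row["onset_s"]), float(row["offset_s"])
            if max_duration_s is not None and offset > max_duration_s + 1e-9:
                raise SchemaError(
                    f"row {i}: offset {offset} s exceeds recording duration "
                    f"{max_duration_s} s"
                )
            intervals.append((str(row["label"]), onset, offset))
        out.append(EventAnnotation(intervals=intervals, block_id=int(block)))
    return out


# ---------------------------------------------------------------------------
# transcripts


def write_transcript(tokens: list[Token], path) -> None:
    pd.DataFrame(
        [{"word": t.word, "language": t.language, "time_s": t.time_s} for t in tokens]
    ).to_csv(path, sep="\t", index=False)


def read_transcript(path) -> list[Token]:
    df = pd.read_csv(path, sep="\t")
    required = {"word", "language", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"transcript TSV missing columns: {sorted(missing)}")
    return [
        Token(str(r["word"]), str(r["language"]), float(r["time_s"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# small JSON helpers used across modules


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
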