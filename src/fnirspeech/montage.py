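"""Probe montage and channel map.

An fNIRS *channel* is an adjacent emitter-detector optode pair. The study
montage consists of two 3x5 probe arrays placed bilaterally, each holding
8 emitters and 7 detectors in an alternating (checkerboard) pattern, which
yields 22 channels per hemisphere and 44 in total.

The geometric rule mapping grid pairs to published channel ids is not part
of the montage contract: region membership is. The module therefore exposes
an explicit region-group table (``PAPER_REGION_GROUPS``) keyed by published
channel ids, and the geometric enumeration is deterministic but
illustrative (row-major, left array first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ProbeArray",
    "Channel",
    "ChannelMap",
    "InvalidMontageError",
    "build_channel_map",
    "apply_exclusions",
    "region_order",
    "paper_montage",
    "PAPER_REGION_GROUPS",
    "PAPER_EXCLUDED_CHANNELS",
    "read_montage_yaml",
    "write_montage_yaml",
]


class InvalidMontageError(ValueError):
    """Raised when a probe array or channel map violates montage invariants."""


#: Region groupings of the study montage, in reporting order. Keys are
#: ``region_hemisphere`` labels; values are published channel ids, in the
#: exact within-group order used for the region-ordered connectivity axes.
PAPER_REGION_GROUPS: dict[str, list[int]] = {
    "frontal_left": [12, 17, 21, 13, 18, 22],
    "motor_left": [11, 16, 20],
    "parietal_left": [5, 10, 15, 14, 19],
    "temporal_left": [2, 6, 7, 1, 3, 8],
    "frontal_right": [37, 42, 36, 41, 32],
    "motor_right": [38, 43],
    "parietal_right": [34, 39, 31, 35, 40, 44],
    "temporal_right": [29, 30, 33, 24, 25, 26, 28],
}

#: Channels excluded from analysis (localized outside the cranial boundary).
PAPER_EXCLUDED_CHANNELS: frozenset[int] = frozenset({4, 9, 23, 27})


@dataclass(frozen=True)
class ProbeArray:
    """A rectangular optode array with alternating emitter/detector roles.

    ``corner_role`` fixes the role at grid position (0, 0); the role at
    (r, c) is then determined by the parity of r + c, so every horizontal
    or vertical grid edge joins one emitter and one detector.
    """

    array_id: str
    hemisphere: str  # "left" | "right"
    n_rows: int = 3
    n_cols: int = 5
    corner_role: str = "E"  # "E" emitter | "D" detector
    #: explicit row-major role assignment; None derives roles from parity
    #: (which always alternates). Supplying non-alternating roles makes
    #: channel enumeration fail with an invalid-montage error.
    roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise InvalidMontageError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if self.corner_role not in ("E", "D"):
            raise InvalidMontageError(f"corner_role must be 'E' or 'D', got {self.corner_role!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidMontageError("array must have at least one row and column")
        if self.roles is not None:
            if len(self.roles) != self.n_rows * self.n_cols:
                raise InvalidMontageError("roles must cover every grid position")
            if set(self.roles) - {"E", "D"}:
                raise InvalidMontageError("roles must be 'E' or 'D'")

    def role_at(self, row: int, col: int) -> str:
        if self.roles is not None:
            return self.roles[row * self.n_cols + col]
        other = "D" if self.corner_role == "E" else "E"
        return self.corner_role if (row + col) % 2 == 0 else other

    @property
    def n_emitters(self) -> int:
        return sum(
            self.role_at(r, c) == "E" for r in range(self.n_rows) for c in range(self.n_cols)
        )

    @property
    def n_detectors(self) -> int:
        return self.n_rows * self.n_cols - self.n_emitters

    def channel_pairs(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Adjacent emitter-detector pairs, row-major.

        For each position, the edge to its right neighbour is enumerated
        before the edge to the neighbour below.
        """
        pairs = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if c + 1 < self.n_cols:
                    pairs.append(((r, c), (r, c + 1)))
                if r + 1 < self.n_rows:
                    pairs.append(((r, c), (r + 1, c)))
        return pairs


@dataclass(frozen=True)
class Channel:
    channel_id: int
    emitter_pos: tuple[str, int, int]  # (array_id, row, col)
    detector_pos: tuple[str, int, int]
    hemisphere: str
    region: str | None = None  # e.g. "frontal_left"
    valid: bool = True


@dataclass(frozen=True)
class ChannelMap:
    """Channels of a montage with validity flags and region labels.

    ``region_groups`` preserves the reporting order of regions and of
    channels within each region; it drives :func:`region_order`.
    """

    channels: tuple[Channel, ...]
    excluded_ids: frozenset[int] = frozenset()
    region_groups: tuple[tuple[str, tuple[int, ...]], ...] = ()

    def __post_init__(self) -> None:
        ids = [ch.channel_id for ch in self.channels]
        if len(set(ids)) != len(ids):
            raise InvalidMontageError("channel ids are not unique")
        if not self.valid_ids:
            raise InvalidMontageError("montage has no valid channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def valid_ids(self) -> list[int]:
        return [ch.channel_id for ch in self.channels if ch.valid]

    @property
    def n_valid(self) -> int:
        return len(self.valid_ids)

    def channel(self, channel_id: int) -> Channel:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(f"no channel with id {channel_id}")

    def with_regions(self, groups: dict[str, list[int]]) -> "ChannelMap":
        """Return a copy with region labels assigned from a group table."""
        label_of: dict[int, str] = {}
        for region, chan_ids in groups.items():
            for cid in chan_ids:
                if cid in label_of:
                    raise InvalidMontageError(f"channel {cid} listed in two region groups")
                label_of[cid] = region
        new = tuple(
            replace(ch, region=label_of.get(ch.channel_id, ch.region)) for ch in self.channels
        )
        frozen_groups = tuple((r, tuple(ids)) for r, ids in groups.items())
        return ChannelMap(new, self.excluded_ids, frozen_groups)


def build_channel_map(arrays: list[ProbeArray]) -> ChannelMap:
    """Enumerate channels of one or more probe arrays.

    One channel per horizontally/vertically adjacent emitter-detector grid
    pair; numbering is deterministic: row-major within each array, arrays in
    the given order (left array first for the study montage), ids 1-based.
    """
    if not arrays:
        raise InvalidMontageError("at least one probe array is required")
    channels: list[Channel] = []
    cid = 1
    for arr in arrays:
        for (p1, p2) in arr.channel_pairs():
            r1, c1 = p1
            r2, c2 = p2
            roles = {arr.role_at(r1, c1), arr.role_at(r2, c2)}
            if roles != {"E", "D"}:
                raise InvalidMontageError(
                    f"array {arr.array_id}: grid edge {p1}-{p2} does not join an "
                    "emitter to a detector (roles do not alternate)"
                )
            if arr.role_at(r1, c1) == "E":
                epos, dpos = (arr.array_id, r1, c1), (arr.array_id, r2, c2)
            else:
                epos, dpos = (arr.array_id, r2, c2), (arr.array_id, r1, c1)
            channels.append(Channel(cid, epos, dpos, arr.hemisphere))
            cid += 1
    return ChannelMap(tuple(channels))


def apply_exclusions(cmap: ChannelMap, excluded: set[int]) -> ChannelMap:
    """Flag the given channel ids invalid and rebuild the valid set."""
    known = {ch.channel_id for ch in cmap.channels}
    unknown = set(excluded) - known
    if unknown:
        raise KeyError(f"unknown channel ids in exclusion set: {sorted(unknown)}")
    all_excluded = set(cmap.excluded_ids) | set(excluded)
    new = tuple(
        replace(ch, valid=ch.channel_id not in all_excluded) for ch in cmap.channels
    )
    if not any(ch.valid for ch in new):
        raise InvalidMontageError("excluding all channels leaves an empty montage")
    return ChannelMap(new, frozenset(all_excluded), cmap.region_groups)


def region_order(cmap: ChannelMap, groups: dict[str, list[int]] | None = None) -> dict[int, int]:
    """Bijection valid-channel-id -> 1..n_valid, grouped by brain region.

    Groups are traversed in table order (left frontal, left motor, left
    parietal, left temporal, then the right-hemisphere homologues for the
    study table); within a group, channels keep the listed order.
    """
    if groups is None:
        if cmap.region_groups:
            groups = {r: list(ids) for r, ids in cmap.region_groups}
        else:
            groups = {}
            for ch in cmap.channels:
                if not ch.valid:
                    continue
                if ch.region is None:
                    raise InvalidMontageError(
                        f"valid channel {ch.channel_id} has no region label"
                    )
                groups.setdefault(ch.region, []).append(ch.channel_id)
    valid = set(cmap.valid_ids)
    order: dict[int, int] = {}
    pos = 1
    for region, chan_ids in groups.items():
        for cid in chan_ids:
            if cid not in valid:
                continue
            if cid in order:
                raise InvalidMontageError(f"channel {cid} appears twice in region groups")
            order[cid] = pos
            pos += 1
    missing = valid - set(order)
    if missing:
        raise InvalidMontageError(
            f"valid channels without a region assignment: {sorted(missing)}"
        )
    return order


def paper_montage(apply_paper_exclusions: bool = True) -> ChannelMap:
    """The study's 44-channel bilateral montage with region labels.

    Two 3x5 arrays (8 emitters + 7 detectors each), left array first;
    channels 4, 9, 23, 27 are excluded by default, leaving 40 valid
    channels grouped into eight regions.
    """
    arrays = [
        ProbeArray("left", "left"),
        ProbeArray("right", "right"),
    ]
    cmap = build_channel_map(arrays).with_regions(PAPER_REGION_GROUPS)
    if apply_paper_exclusions:
        cmap = apply_exclusions(cmap, set(PAPER_EXCLUDED_CHANNELS))
    return cmap


def region_ordered_ids(cmap: ChannelMap, groups: dict[str, list[int]] | None = None) -> list[int]:
    """Valid channel ids sorted into region order (axis labels for FC matrices)."""
    order = region_order(cmap, groups)
    return [cid for cid, _ in sorted(order.items(), key=lambda kv: kv[1])]


def write_montage_yaml(cmap: ChannelMap, path) -> None:
    doc = {
        "channels": [
            {
                "id": ch.channel_id,
                "hemisphere": ch.hemisphere,
                "region": ch.region,
                "valid": bool(ch.valid),
                "emitter": list(ch.emitter_pos),
                "detector": list(ch.detector_pos),
            }
            for ch in cmap.channels
        ],
        "excluded": sorted(cmap.excluded_ids),
        "region_groups": [
            {"region": r, "channels": list(ids)} for r, ids in cmap.region_groups
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_montage_yaml(path) -> ChannelMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    channels = tuple(
        Channel(
            channel_id=int(c["id"]),
            emitter_pos=tuple(c["emitter"]),
            detector_pos=tuple(c["detector"]),
            hemisphere=c["hemisphere"],
            region=c.get("region"),
            valid=bool(c.get("valid", True)),
        )
        for c in doc["channels"]
    )
    groups = tuple(
        (g["region"], tuple(int(c) for c in g["channels"]))
        for g in doc.get("region_groups", [])
    )
    return ChannelMap(channels, frozenset(doc.get("excluded", [])), groups)


def n_channels_for_grid(n_rows: int, n_cols: int) -> int:
    """Channel count of an alternating r x c grid: all grid edges."""
    return n_rows * (n_cols - 1) + (n_rows - 1) * n_cols
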