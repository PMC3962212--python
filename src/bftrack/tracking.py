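"""Linking per-frame detections into trajectories; RMSD track filtering.

Linking is frame-to-frame optimal assignment (Hungarian algorithm on
squared displacement), gated by a maximum per-step displacement, with an
optional memory allowing an object to vanish for a few frames and be
re-linked. Non-motile objects (immobilized or dead cells, debris) are then
removed by thresholding each track's root-mean-square excursion about its
time-averaged position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import Detection

__all__ = [
    "Track",
    "LinkParams",
    "link_detections",
    "track_rmsd",
    "filter_tracks_by_rmsd",
    "round_track_coordinates",
]


@dataclass
class Track:
    """Time-ordered centroid sequence of one tracked object.

    positions are (x, y) in pixels; `frames` strictly increasing. `flags`
    holds per-point exclusion markers set during manual post-processing
    (division, contact, debris intervals); flagged points are skipped by the
    statistics stages.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.frames), dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n, 2) matching frames")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class LinkParams:
    """Linker knobs: max displacement per frame step (px) and gap memory."""

    max_displacement: float = 20.0
    memory: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


def link_detections(
    per_frame_detections: list[list[Detection]], params: LinkParams = LinkParams()
) -> list[Track]:
    """Sort per-frame centroid lists into particle tracks.

    Each frame's detections are assigned to the set of active track ends by
    minimum total squared displacement (Hungarian algorithm), with links
    longer than `max_displacement` per frame step forbidden. Unmatched
    detections open new tracks; a track end stays active for `memory` extra
    frames, allowing gaps. Every detection ends up in exactly one track.
    """
    # active: list of dicts with frames, positions (lists), last seen frame
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0

    for fi, dets in enumerate(per_frame_detections):
        # retire tracks that are out of memory
        still = []
        for tr in active:
            if fi - tr["frames"][-1] > params.memory + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        pts = np.asarray([d.centroid for d in dets], dtype=float).reshape(len(dets), 2)
        assigned = np.full(len(dets), -1, dtype=int)
        if active and len(dets):
            ends = np.asarray([tr["positions"][-1] for tr in active])
            gaps = np.asarray([fi - tr["frames"][-1] for tr in active], dtype=float)
            d2 = ((ends[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            # allow proportionally larger steps across gap frames
            limit2 = (params.max_displacement * gaps) ** 2
            feasible = d2 <= limit2[:, None]
            big = 1e12
            cost = np.where(feasible, d2, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if feasible[r, c]:
                    assigned[c] = r
        for c, det in enumerate(dets):
            r = assigned[c]
            if r >= 0:
                active[r]["frames"].append(fi)
                active[r]["positions"].append(tuple(pts[c]))
            else:
                active.append(
                    {"id": next_id, "frames": [fi], "positions": [tuple(pts[c])]}
                )
                next_id += 1

    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])
    return [
        Track(track_id=tr["id"], frames=np.asarray(tr["frames"]), positions=np.asarray(tr["positions"]))
        for tr in finished
    ]


def track_rmsd(track: Track) -> float:
    """Root-mean-squared excursion of a track about its mean position.

    ``RMSD = sqrt( sum_i |r_i - r_mean|^2 / (N - 1) )`` — note the N−1
    denominator. Small for cells that do not move.
    """
    n = len(track)
    if n < 2:
        raise ValueError("track_rmsd needs at least 2 points")
    dev = track.positions - track.positions.mean(axis=0)
    return float(np.sqrt((dev**2).sum() / (n - 1)))


def filter_tracks_by_rmsd(
    tracks: list[Track], threshold: float = 15.0
) -> tuple[list[Track], list[Track]]:
    """Partition tracks into (kept, discarded) by the RMSD threshold.

    The default of 15 px is about half a typical cell diameter, removing
    objects that never move a full cell diameter over the recording.
    Singleton tracks (N < 2) are always discarded.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept, discarded = [], []
    for tr in tracks:
        if len(tr) >= 2 and track_rmsd(tr) >= threshold:
            kept.append(tr)
        else:
            discarded.append(tr)
    return kept, discarded


def round_track_coordinates(track: Track) -> Track:
    """Round positions to the nearest integer pixel (ties to even).

    Emulates trackers that truncate centroid output to whole pixels, for
    studying the effect of coordinate quantization on motility statistics.
    """
    return Track(
        track_id=track.track_id,
        frames=track.frames.copy(),
        positions=np.rint(track.positions),
        flags=track.flags.copy(),
    )
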