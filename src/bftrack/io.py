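"""File I/O: frame sequences in, track tables and reports out."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "read_frame_sequence",
    "write_tracks",
    "read_tracks",
    "tracks_from_dataframe",
    "tracks_to_dataframe",
    "read_exclusions",
    "apply_exclusions",
]

#: ITU-R 601 luminance weights for RGB -> grayscale reduction
_LUMA = np.array([0.299, 0.587, 0.114])

_TRACK_COLUMNS = ["track_id", "frame", "time_min", "x_px", "y_px", "x_um", "y_um", "flag"]


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        if frame.shape[2] == 4:
            frame = frame[:, :, :3]
        return frame[:, :, :3].astype(float) @ _LUMA
    return frame


def read_frame_sequence(path_or_pattern: str | Path) -> tuple[np.ndarray, dict]:
    """Read a movie as an ordered grayscale stack.

    Accepts a multi-page TIFF path, a directory of frames, or a glob
    pattern. Files are ordered naturally (frame2 before frame10); color
    frames are reduced to luminance; integer bit depth is preserved for
    single-channel input. Returns (stack (n, h, w), metadata dict).
    """
    import imageio.v3 as iio
    import tifffile

    p = Path(path_or_pattern)
    if p.is_file() and p.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # pages with color channels
            stack = np.stack([_to_gray(fr) for fr in stack])
        return stack, {"source": str(p), "n_frames": len(stack), "files": [str(p)]}

    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in
             (".tif", ".tiff", ".png", ".jpg", ".jpeg")),
            key=lambda f: _natural_key(f.name),
        )
    else:
        files = sorted(p.parent.glob(p.name), key=lambda f: _natural_key(f.name))
    if not files:
        raise FileNotFoundError(f"no frames found at {path_or_pattern}")

    frames = []
    shape = None
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:
            raise OSError(f"unreadable frame {f}: {exc}") from exc
        img = _to_gray(img)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"frame {f} has shape {img.shape}, expected {shape} "
                "(mixed dimensions in sequence)"
            )
        frames.append(img)
    stack = np.stack(frames)
    return stack, {
        "source": str(path_or_pattern),
        "n_frames": len(stack),
        "files": [str(f) for f in files],
    }


def tracks_to_dataframe(
    tracks: list[Track], dt: float = 1.0, pixel_size: float = 1.0
) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, (x, y), flag in zip(tr.frames, tr.positions, tr.flags):
            rows.append(
                (tr.track_id, int(frame), frame * dt, x, y,
                 x * pixel_size, y * pixel_size, int(flag))
            )
    return pd.DataFrame(rows, columns=_TRACK_COLUMNS)


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    required = {"track_id", "frame", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing required columns: {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        flags = grp["flag"].to_numpy(dtype=bool) if "flag" in grp else None
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                positions=grp[["x_px", "y_px"]].to_numpy(dtype=float),
                flags=flags,
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path: str | Path, dt: float = 1.0,
                 pixel_size: float = 1.0) -> None:
    """Write the track table CSV (px and µm columns both included)."""
    df = tracks_to_dataframe(tracks, dt=dt, pixel_size=pixel_size)
    # %.17g guarantees float64 round-trips bit-exactly through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
    pixel_size: float = 1.0,
) -> list[Track]:
    """Read a track table CSV, optionally remapping foreign column names.

    `column_map` maps this package's names to the file's names, e.g.
    ``{"track_id": "id", "frame": "t", "x_px": "X", "y_px": "Y"}`` — this is
    how text/Excel-exported tables from other tracking programs are
    ingested. If the file provides only µm columns (`x_um`, `y_um`), pixel
    positions are derived with `pixel_size`. Empty files give an empty list.
    """
    import warnings

    p = Path(path)
    try:
        df = pd.read_csv(p, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{p} is empty: no tracks read", stacklevel=2)
        return []
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if len(df) == 0:
        warnings.warn(f"{p} has no rows: no tracks read", stacklevel=2)
        return []
    if "x_px" not in df.columns and {"x_um", "y_um"} <= set(df.columns):
        df["x_px"] = df["x_um"] / pixel_size
        df["y_px"] = df["y_um"] / pixel_size
    return tracks_from_dataframe(df)


def read_exclusions(path: str | Path) -> list[tuple[int, int | None, int | None, str]]:
    """Parse a manual post-processing exclusion list.

    Line format: ``track_id [frame_start frame_end] reason...``. A line
    without a frame range excludes the whole track. '#' starts a comment.
    """
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        tid = int(toks[0])
        if len(toks) >= 3 and toks[1].lstrip("-").isdigit() and toks[2].lstrip("-").isdigit():
            out.append((tid, int(toks[1]), int(toks[2]), " ".join(toks[3:])))
        else:
            out.append((tid, None, None, " ".join(toks[1:])))
    return out


def apply_exclusions(
    tracks: list[Track], exclusions: list[tuple[int, int | None, int | None, str]]
) -> list[Track]:
    """Flag excluded points; tracks excluded entirely are dropped.

    Flagged intervals are skipped by the statistics stages (they split
    velocity series), implementing manual screening for division, contact
    and debris without automating the judgment itself.
    """
    whole = {tid for tid, a, b, _ in exclusions if a is None}
    ranges: dict[int, list[tuple[int, int]]] = {}
    for tid, a, b, _ in exclusions:
        if a is not None:
            ranges.setdefault(tid, []).append((a, b))
    out = []
    for tr in tracks:
        if tr.track_id in whole:
            continue
        flags = tr.flags.copy()
        for a, b in ranges.get(tr.track_id, []):
            flags |= (tr.frames >= a) & (tr.frames <= b)
        out.append(Track(tr.track_id, tr.frames.copy(), tr.positions.copy(), flags))
    return out
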