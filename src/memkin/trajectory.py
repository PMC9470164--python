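"""Trajectory I/O, filtering, and the two primitive observables.

Consumes spot-tracking exports (TrackMate-style CSV: one row per detection,
grouped by track id) and produces the raw material of the membrane-binding
analyses: per-track dwell times and per-frame step sizes.

Filtering follows the standard single-particle-tracking hygiene rules, in
order: drop tracks that begin in the first frame (arrival time unknown),
tracks present in the last frame (departure unknown), tracks of <= 2
frames, immobile tracks, and tracks near the field edge where TIRF
illumination is uneven.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import TRACK_COLUMNS

__all__ = [
    "Track",
    "FilterReport",
    "read_tracks",
    "tracks_from_frame",
    "filter_tracks",
    "extract_dwells",
    "extract_steps",
    "DEFAULT_IMMOBILE_THRESHOLD",
]

# 2 x default localization sigma (0.02 um): a track whose maximum excursion
# from its start never exceeds twice the localization error is classified
# immobile.
DEFAULT_IMMOBILE_THRESHOLD = 0.04

_REQUIRED = ("TRACK_ID", "FRAME", "POSITION_T", "POSITION_X", "POSITION_Y")

#: generic dialect: map from our canonical names to arbitrary CSV headers
DEFAULT_DIALECT = {c: c for c in TRACK_COLUMNS}


@dataclass(frozen=True)
class Track:
    """One particle's time-ordered positions and intensities."""

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frames)
        if n < 1:
            raise ValueError("track must have >= 1 point")
        for name in ("t", "x", "y", "intensity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name!r}")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(
                f"track {self.track_id}: frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FilterReport:
    """Bookkeeping of how many tracks each rule removed, in applied order."""

    n_input: int = 0
    n_removed_by_rule: dict = field(default_factory=dict)
    n_output: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_output + sum(
            self.n_removed_by_rule.values())

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"n_input": self.n_input,
                        "n_removed_by_rule": self.n_removed_by_rule,
                        "n_output": self.n_output}, indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def _make_track(tid: int, g: pd.DataFrame) -> Track:
    g = g.sort_values("FRAME", kind="stable")
    return Track(
        track_id=int(tid),
        frames=g["FRAME"].to_numpy(dtype=int),
        t=g["POSITION_T"].to_numpy(dtype=float),
        x=g["POSITION_X"].to_numpy(dtype=float),
        y=g["POSITION_Y"].to_numpy(dtype=float),
        intensity=g["INTENSITY"].to_numpy(dtype=float)
        if "INTENSITY" in g else np.full(len(g), np.nan),
    )


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Group a long-format detection table into Track objects."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    tracks = []
    for tid, g in df.groupby("TRACK_ID", sort=True):
        if g["FRAME"].duplicated().any():
            raise ValueError(f"track {tid}: duplicate frames "
                             "(non-monotone after sorting)")
        tracks.append(_make_track(tid, g))
    return tracks


def read_tracks(path: str | Path, dialect: dict | None = None) -> list[Track]:
    """Read a TrackMate-style CSV into Track objects.

    ``dialect`` maps canonical column names (``TRACK_ID`` etc.) to the
    file's actual headers.  Malformed numeric rows are reported in a
    ValueError rather than silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): "
                         f"{', '.join(missing)}")
    numeric = df[list(_REQUIRED)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path.name}: malformed rows (file lines {rows})")
    df[list(_REQUIRED)] = numeric
    return tracks_from_frame(df)


def filter_tracks(
    tracks: Sequence[Track],
    movie_n_frames: int,
    field_bounds: tuple[float, float],
    min_len: int = 3,
    edge_margin: float | None = None,
    immobile_threshold: float = DEFAULT_IMMOBILE_THRESHOLD,
) -> tuple[list[Track], FilterReport]:
    """Apply the tracking hygiene rules, in order; inputs are not mutated.

    Rules: track_start (begins in frame 1), track_end (present in the last
    movie frame), duration (<= 2 frames, i.e. < ``min_len``), immobile
    (maximum excursion from the track's own start below
    ``immobile_threshold``), edge (mean position within ``edge_margin`` of
    the field border; default margin is 5% of the field width).
    """
    if edge_margin is None:
        edge_margin = 0.05 * field_bounds[0]
    report = FilterReport(n_input=len(tracks))
    rules = ["track_start", "track_end", "duration", "immobile", "edge"]
    report.n_removed_by_rule = {r: 0 for r in rules}

    survivors = list(tracks)

    def _apply(rule, pred):
        nonlocal survivors
        kept = [tr for tr in survivors if not pred(tr)]
        report.n_removed_by_rule[rule] = len(survivors) - len(kept)
        survivors = kept

    _apply("track_start", lambda tr: tr.frames[0] == 1)
    _apply("track_end", lambda tr: tr.frames[-1] == movie_n_frames)
    _apply("duration", lambda tr: len(tr) < min_len)

    def _immobile(tr: Track) -> bool:
        d = np.hypot(tr.x - tr.x[0], tr.y - tr.y[0])
        return float(d.max()) < immobile_threshold

    _apply("immobile", _immobile)

    def _edge(tr: Track) -> bool:
        mx, my = float(tr.x.mean()), float(tr.y.mean())
        return (mx < edge_margin or my < edge_margin
                or mx > field_bounds[0] - edge_margin
                or my > field_bounds[1] - edge_margin)

    _apply("edge", _edge)

    report.n_output = len(survivors)
    report.check()
    return survivors, report


def extract_dwells(tracks: Sequence[Track], frame_interval: float) -> np.ndarray:
    """Per-track dwell time: (frame span, inclusive) x frame interval.

    Gapped tracks (missed detections) contribute by frame span, so a track
    observed in frames 3..6 dwells 4 frames regardless of internal gaps.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    return np.array([(tr.frames[-1] - tr.frames[0] + 1) * frame_interval
                     for tr in tracks], dtype=float)


def extract_steps(tracks: Sequence[Track]) -> tuple[np.ndarray, int]:
    """All consecutive-frame 2D displacements r = sqrt(dx^2 + dy^2), in um.

    Frame pairs separated by a detection gap are excluded; the second
    return value counts those skipped pairs.
    """
    steps = []
    n_gapped = 0
    for tr in tracks:
        if len(tr) < 2:
            continue
        dfr = np.diff(tr.frames)
        consec = dfr == 1
        n_gapped += int((~consec).sum())
        dx = np.diff(tr.x)[consec]
        dy = np.diff(tr.y)[consec]
        steps.append(np.hypot(dx, dy))
    if not steps:
        return np.array([]), n_gapped
    return np.concatenate(steps), n_gapped
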