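"""Trajectory linking, lifetime extraction and first-formation time.

Linking is Crocker–Grier style: frame by frame, detections are assigned to
open tracks by minimising the total squared displacement, subject to a hard
search-range cutoff (default 8 px = 0.85 um). A track may vanish for up to
``memory`` frames (default 6, i.e. 60 s at 10 s/frame) and still be continued;
tracks with fewer detections than ``min_length`` (default 2) are discarded.

The per-frame objective solved by the Hungarian algorithm is

    sum of squared link displacements
      + search_range**2 * (number of unlinked tracks + unlinked detections),

i.e. leaving a feasible pair unlinked is never cheaper than linking it. When
two assignments tie, the link that continues the longer existing track wins
(implemented as an infinitesimal cost bonus), which makes the output
deterministic and independent of detection ordering within a frame.

The lifetime of a track spanning frames [first, last] is
(last - first + 1) * frame_interval, so a minimum-length track of 2 frames at
10 s/frame has a 20 s lifetime. Tracks already present in frame 0 are
"pre-formed": their formation time is unobserved, and they are excluded from
formation-time and lifetime statistics.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "link_trajectories",
    "summarise_tracks",
    "filter_preformed",
    "first_formation_time",
]

_BIG = 1e12
_TIE_EPS = 1e-9


def link_trajectories(detections: pd.DataFrame, search_range: float = 8.0,
                      memory: int = 6, min_length: int = 2) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    ``detections`` needs columns ``frame``, ``x_px``, ``y_px`` (additional
    columns are carried through). Returns the input rows of every retained
    track with a ``track_id`` column added; track ids are assigned by first
    frame, then x of the first detection.
    """
    if search_range <= 0:
        raise ValueError("search_range must be positive")
    if memory < 0 or min_length < 1:
        raise ValueError("memory must be >= 0 and min_length >= 1")
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(required)}")
    det = detections.reset_index(drop=True)
    frames = det["frame"].to_numpy()
    if len(det) and (frames < 0).any():
        raise ValueError("inconsistent frame indexing: negative frame index")

    sr2 = search_range ** 2
    # open track state: per track -> [last_frame, x, y, n_points, row_indices]
    open_tracks: list[dict] = []
    done_tracks: list[list[int]] = []

    if len(det) == 0:
        out = det.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out

    for f in range(int(frames.min()), int(frames.max()) + 1):
        sel = np.flatnonzero(frames == f)
        # deterministic intra-frame order regardless of input ordering
        if len(sel):
            order = np.lexsort((det["y_px"].to_numpy()[sel],
                                det["x_px"].to_numpy()[sel]))
            sel = sel[order]
        # retire tracks whose gap exceeded memory
        still_open = []
        for tr in open_tracks:
            if f - tr["last_frame"] > memory + 1:
                done_tracks.append(tr["rows"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        n_t, n_p = len(open_tracks), len(sel)
        if n_p == 0:
            continue
        px = det["x_px"].to_numpy()[sel]
        py = det["y_px"].to_numpy()[sel]
        if n_t == 0:
            assign = [None] * n_p
        else:
            size = n_t + n_p
            cost = np.full((size, size), _BIG)
            for i, tr in enumerate(open_tracks):
                d2 = (px - tr["x"]) ** 2 + (py - tr["y"]) ** 2
                feasible = d2 <= sr2
                c = np.where(feasible, d2 - _TIE_EPS * min(tr["n"], 10 ** 6), _BIG)
                cost[i, :n_p] = c
                cost[i, n_p + i] = sr2  # track goes unlinked this frame
            for j in range(n_p):
                cost[n_t + j, j] = sr2  # detection starts a new track
            cost[n_t:, n_p:] = 0.0
            rows_idx, cols_idx = linear_sum_assignment(cost)
            assign = [None] * n_p
            for r, c in zip(rows_idx, cols_idx):
                if r < n_t and c < n_p and cost[r, c] < sr2 + 1:
                    assign[c] = r
        linked = set()
        for j, tr_idx in enumerate(assign):
            if tr_idx is not None:
                tr = open_tracks[tr_idx]
                tr["rows"].append(int(sel[j]))
                tr["last_frame"], tr["x"], tr["y"] = f, px[j], py[j]
                tr["n"] += 1
                linked.add(tr_idx)
            else:
                open_tracks.append({"last_frame": f, "x": px[j], "y": py[j],
                                    "n": 1, "rows": [int(sel[j])]})

    done_tracks.extend(tr["rows"] for tr in open_tracks)
    kept = [rows for rows in done_tracks if len(rows) >= min_length]
    # stable ordering: first frame, then x of first point
    kept.sort(key=lambda rows: (frames[rows[0]],
                                float(det["x_px"].iloc[rows[0]]),
                                float(det["y_px"].iloc[rows[0]])))
    pieces = []
    for tid, rows in enumerate(kept):
        piece = det.iloc[rows].copy()
        piece["track_id"] = tid
        pieces.append(piece)
    if not pieces:
        out = det.iloc[:0].copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)


def summarise_tracks(points: pd.DataFrame, frame_interval: float,
                     n_frames: Optional[int] = None) -> pd.DataFrame:
    """Per-track summary: start/end frame, lifetime, pre-formed/censored flags.

    ``censored`` marks tracks still present in the last movie frame (their
    true lifetime is right-censored); it is only filled when ``n_frames`` is
    given.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    cols = ["track_id", "first_frame", "last_frame", "n_points",
            "start_s", "lifetime_s", "preformed", "censored"]
    if len(points) == 0:
        dtypes = [int, int, int, int, float, float, bool, bool]
        return pd.DataFrame({c: pd.Series(dtype=t)
                             for c, t in zip(cols, dtypes)})
    g = points.groupby("track_id")["frame"]
    summary = pd.DataFrame({
        "track_id": g.min().index,
        "first_frame": g.min().to_numpy(),
        "last_frame": g.max().to_numpy(),
        "n_points": g.size().to_numpy(),
    })
    summary["start_s"] = summary["first_frame"] * frame_interval
    summary["lifetime_s"] = (summary["last_frame"] - summary["first_frame"]
                             + 1) * frame_interval
    summary["preformed"] = summary["first_frame"] == 0
    summary["censored"] = (summary["last_frame"] == n_frames - 1
                           if n_frames is not None else False)
    return summary[cols]


def filter_preformed(summary: pd.DataFrame,
                     points: pd.DataFrame | None = None):
    """Drop trajectories already present in frame 0 (formation unobserved)."""
    kept = summary[~summary["preformed"]].reset_index(drop=True)
    if points is None:
        return kept
    pts = points[points["track_id"].isin(set(kept["track_id"]))]
    return kept, pts.reset_index(drop=True)


def first_formation_time(summary: pd.DataFrame,
                         frame_interval: float) -> Optional[float]:
    """Time of the earliest (non-pre-formed) trajectory start, in seconds.

    Returns ``None`` when no formation was observed (no eligible tracks).
    """
    eligible = summary[~summary["preformed"]]
    if len(eligible) == 0:
        return None
    return float(eligible["first_frame"].min() * frame_interval)
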