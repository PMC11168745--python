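"""Brute-force linking oracle: exhaustive enumeration of per-frame assignments.

Independent of the production tracker: at every frame it enumerates ALL
injective partial assignments of detections to open tracks (respecting the
search range and the gap memory) and keeps the one minimising

    sum of squared link displacements
      + search_range**2 * (unlinked tracks + unlinked detections),

the same objective the Hungarian-based tracker optimises. Feasible only for
tiny instances (<= ~6 detections per frame).
"""

from itertools import permutations

import numpy as np


def link_bruteforce(detections, search_range=8.0, memory=6, min_length=2):
    """Return the set of tracks as frozensets of ``det_id`` values."""
    sr2 = search_range ** 2
    frames = detections["frame"].to_numpy()
    done = []
    open_tracks = []  # dicts: last_frame, x, y, rows
    for f in range(int(frames.min()), int(frames.max()) + 1):
        sub = detections[detections["frame"] == f]
        sub = sub.sort_values(["x_px", "y_px"])
        pts = sub[["x_px", "y_px"]].to_numpy()
        ids = sub["det_id"].to_list()
        still = []
        for tr in open_tracks:
            if f - tr["last_frame"] > memory + 1:
                done.append(tr["rows"])
            else:
                still.append(tr)
        open_tracks = still
        n_p = len(pts)
        if n_p == 0:
            continue
        n_t = len(open_tracks)
        best_cost, best_assign = None, None
        # assignment: tuple giving, for each point, a track index or None
        slots = list(range(n_t)) + [None] * n_p
        for perm in set(permutations(slots, n_p)):
            used = [s for s in perm if s is not None]
            if len(used) != len(set(used)):
                continue
            cost = 0.0
            ok = True
            for j, s in enumerate(perm):
                if s is None:
                    cost += sr2  # new track
                    continue
                tr = open_tracks[s]
                d2 = (pts[j, 0] - tr["x"]) ** 2 + (pts[j, 1] - tr["y"]) ** 2
                if d2 > sr2:
                    ok = False
                    break
                cost += d2
            if not ok:
                continue
            cost += sr2 * (n_t - len(used))  # unlinked open tracks
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_assign = cost, perm
        for j, s in enumerate(best_assign):
            if s is None:
                open_tracks.append({"last_frame": f, "x": pts[j, 0],
                                    "y": pts[j, 1], "rows": [ids[j]]})
            else:
                tr = open_tracks[s]
                tr["rows"].append(ids[j])
                tr["last_frame"], tr["x"], tr["y"] = f, pts[j, 0], pts[j, 1]
    done.extend(tr["rows"] for tr in open_tracks)
    return {frozenset(rows) for rows in done if len(rows) >= min_length}


def random_instance(seed, n_frames=10, max_per_frame=5):
    """A small random tracking instance: wandering particles + clutter."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    n_tracks = rng.integers(2, 5)
    for _ in range(n_tracks):
        f0 = int(rng.integers(0, 3))
        length = int(rng.integers(3, n_frames - f0 + 1))
        x, y = rng.uniform(10, 60, 2)
        for f in range(f0, f0 + length):
            x += rng.uniform(-2.5, 2.5)
            y += rng.uniform(-2.5, 2.5)
            if rng.random() < 0.15:
                continue  # missed detection (gap)
            rows.append((f, x, y))
    for f in range(n_frames):  # clutter
        for _ in range(int(rng.integers(0, 2))):
            rows.append((f, *rng.uniform(0, 70, 2)))
    rng.shuffle(rows)
    df = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
    # cap detections per frame so exhaustive enumeration stays tractable
    df = df.groupby("frame").head(max_per_frame).reset_index(drop=True)
    df["det_id"] = np.arange(len(df))
    return df
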