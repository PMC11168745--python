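"""Cell segmentation, drift correction and membrane/cytoplasm classification.

The cell footprint is segmented from the brightest-point projection of the raw
stack (Otsu threshold on the time-median image, refined per frame). Every
punctum localisation is then expressed relative to the frame-matched cell
centroid (drift correction) and assigned the Euclidean distance to the nearest
point of the frame-matched cell boundary. Localisations within 1.4 um of the
boundary are classified as membrane, the rest as cytoplasm; trajectories whose
first localisation is cytoplasmic are excluded from downstream kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage

__all__ = [
    "CellGeometry",
    "segment_cell",
    "correct_drift",
    "boundary_distance",
    "annotate_distances",
    "classify_compartment",
    "filter_membrane_initiated",
    "counts_over_time",
    "MEMBRANE_THRESHOLD_UM",
]

#: default membrane/cytoplasm separation threshold (um).
MEMBRANE_THRESHOLD_UM = 1.4


@dataclass
class CellGeometry:
    """Per-frame cell mask, outer boundary point set and centroid.

    Coordinates are (x, y) pairs in micrometres; ``boundaries[f]`` is an
    (N, 2) array of boundary points for frame ``f`` and ``centroids`` is a
    (T, 2) array.
    """

    centroids: np.ndarray
    boundaries: List[np.ndarray]
    pixel_size: float
    masks: Optional[np.ndarray] = None
    _trees: dict = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.boundaries)

    def boundary_tree(self, frame: int) -> cKDTree:
        if frame not in self._trees:
            self._trees[frame] = cKDTree(self.boundaries[frame])
        return self._trees[frame]

    def translated(self, offset_um) -> "CellGeometry":
        """Rigidly translated copy (masks are dropped)."""
        off = np.asarray(offset_um, dtype=float)
        return CellGeometry(
            centroids=self.centroids + off,
            boundaries=[b + off for b in self.boundaries],
            pixel_size=self.pixel_size,
        )


def segment_cell(projection: np.ndarray, pixel_size: float) -> CellGeometry:
    """Segment the cell footprint from a (t, y, x) raw projection stack.

    The intensity threshold is Otsu's, computed on the time-median image so a
    transiently bright punctum cannot skew it; each frame is then thresholded,
    morphologically closed, hole-filled, and reduced to its largest connected
    component. The boundary is the sub-pixel 0.5-level contour of the mask.

    Raises ``ValueError`` when no foreground is found.
    """
    proj = np.asarray(projection)
    if proj.dtype.kind != "f":
        proj = proj.astype(np.float32)
    if proj.ndim == 2:
        proj = proj[None]
    if proj.ndim != 3:
        raise ValueError("projection must be (t, y, x) or (y, x)")
    median_img = np.median(proj, axis=0)
    if np.ptp(median_img) == 0:
        raise ValueError("no foreground found: image is constant")
    # smooth before thresholding: single noise pixels in a max-projection
    # otherwise seed speckles that survive the morphological cleanup
    smooth_sigma = 2.0
    thr = threshold_otsu(ndimage.gaussian_filter(median_img, smooth_sigma))

    centroids = np.zeros((proj.shape[0], 2))
    boundaries: List[np.ndarray] = []
    masks = np.zeros(proj.shape, dtype=bool)
    footprint = morphology.disk(2)
    for f, frame in enumerate(proj):
        mask = ndimage.gaussian_filter(frame, smooth_sigma) > thr
        mask = ndimage.binary_closing(mask, structure=footprint)
        mask = ndimage.binary_fill_holes(mask)
        labels, n = ndimage.label(mask)
        if n == 0:
            raise ValueError(f"no foreground found in frame {f}")
        largest = np.argmax(ndimage.sum(mask, labels, range(1, n + 1))) + 1
        mask = labels == largest
        masks[f] = mask
        rows, cols = np.nonzero(mask)
        centroids[f] = (cols.mean() * pixel_size, rows.mean() * pixel_size)
        contours = measure.find_contours(mask.astype(float), 0.5)
        contour = max(contours, key=len)  # outer boundary
        # find_contours returns (row, col); convert to (x, y) um
        boundaries.append(np.column_stack(
            (contour[:, 1] * pixel_size, contour[:, 0] * pixel_size)))
    return CellGeometry(centroids=centroids, boundaries=boundaries,
                        pixel_size=pixel_size, masks=masks)


def correct_drift(points: pd.DataFrame, geometry: CellGeometry) -> pd.DataFrame:
    """Re-express localisations relative to the frame-matched cell centroid.

    Adds ``x_rel_um``/``y_rel_um`` columns; requires ``frame``, ``x_um``,
    ``y_um``. Raises ``KeyError`` if a trajectory frame is missing from the
    geometry.
    """
    out = points.copy()
    frames = out["frame"].to_numpy(dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= geometry.n_frames):
        missing = frames[(frames < 0) | (frames >= geometry.n_frames)]
        raise KeyError(f"geometry has no frame(s) {sorted(set(missing))}")
    cents = geometry.centroids[frames] if frames.size else np.zeros((0, 2))
    out["x_rel_um"] = out["x_um"].to_numpy() - (cents[:, 0] if frames.size else 0)
    out["y_rel_um"] = out["y_um"].to_numpy() - (cents[:, 1] if frames.size else 0)
    return out


def boundary_distance(point_um, geometry: CellGeometry, frame: int) -> float:
    """Euclidean distance (um) from ``point_um = (x, y)`` to the nearest
    boundary point of ``frame``."""
    d, _ = geometry.boundary_tree(frame).query(np.asarray(point_um, float))
    return float(d)


def annotate_distances(points: pd.DataFrame, geometry: CellGeometry,
                       threshold: float = MEMBRANE_THRESHOLD_UM) -> pd.DataFrame:
    """Add ``distance_um`` and ``compartment`` columns to a localisation table."""
    out = points.copy()
    dist = np.empty(len(out))
    xy = out[["x_um", "y_um"]].to_numpy()
    frames = out["frame"].to_numpy(dtype=int)
    for f in np.unique(frames):
        sel = frames == f
        dist[sel], _ = geometry.boundary_tree(int(f)).query(xy[sel])
    out["distance_um"] = dist
    out["compartment"] = classify_compartment(dist, threshold)
    return out


def classify_compartment(distance, threshold: float = MEMBRANE_THRESHOLD_UM):
    """'membrane' iff distance <= threshold (inclusive), else 'cytoplasm'.

    Accepts a scalar or an array; negative distances are rejected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    labels = np.where(d <= threshold, "membrane", "cytoplasm")
    if np.isscalar(distance) or d.ndim == 0:
        return str(labels)
    return labels


def filter_membrane_initiated(points: pd.DataFrame,
                              summary: pd.DataFrame | None = None):
    """Keep only trajectories whose first localisation is at the membrane.

    ``points`` must carry ``track_id``, ``frame`` and ``compartment``. Returns
    the filtered points table (and the filtered summary when one is given).
    """
    if len(points) == 0:
        return (points, summary) if summary is not None else points
    first = points.sort_values("frame").groupby("track_id").first()
    keep = set(first.index[first["compartment"] == "membrane"])
    pts = points[points["track_id"].isin(keep)].reset_index(drop=True)
    if summary is not None:
        summ = summary[summary["track_id"].isin(keep)].reset_index(drop=True)
        return pts, summ
    return pts


def counts_over_time(points: pd.DataFrame, n_frames: int,
                     frame_interval: float, n_cells: int = 1) -> pd.DataFrame:
    """Per-frame membrane and cytoplasm punctum counts, normalised per cell.

    ``points`` should already be restricted to membrane-initiated
    trajectories and carry a ``compartment`` column; each localisation is
    re-classified per frame, so a punctum that internalises after assembly
    moves from the membrane count to the cytoplasm count.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t_s = np.arange(n_frames) * frame_interval
    mem = np.zeros(n_frames)
    cyt = np.zeros(n_frames)
    if len(points):
        grouped = points.groupby(["frame", "compartment"]).size()
        for (f, comp), count in grouped.items():
            if 0 <= f < n_frames:
                (mem if comp == "membrane" else cyt)[int(f)] = count
    return pd.DataFrame({
        "t_s": t_s,
        "membrane_per_cell": mem / n_cells,
        "cytoplasm_per_cell": cyt / n_cells,
    })
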