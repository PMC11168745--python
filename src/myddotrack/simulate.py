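"""Ground-truthed synthetic data for both pipeline branches.

Live branch: a single adherent cell is modelled as a circular footprint
(optionally drifting rigidly) extruded into a fluorescent slab. Diffraction-
limited puncta nucleate as a Poisson process after a stimulus-dependent delay,
predominantly within a band at the cell boundary, and persist for lifetimes
drawn from the two-step degradation model (the hypoexponential distribution,
sampled exactly as the sum of two independent exponential waiting times).
Stacks are rendered punctum-by-punctum as 3D Gaussians on the cell background,
with Poisson shot noise on the photon expectation plus Gaussian read noise.

Fixed branch: binary cluster masks spanning ~50-500 nm, a mixture of
rasterised disks (shape factor exactly 1 by construction) and perturbed
polygons whose true area/perimeter are computed analytically before
rasterisation.

All randomness flows from a single seeded generator per simulation call, so an
identical config (including seed) reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .config import SimulationConfig
from .geometry import CellGeometry

__all__ = [
    "GroundTruthEvent",
    "SyntheticClusterSet",
    "simulate_lifetimes",
    "simulate_cell",
    "simulate_events",
    "render_stack",
    "simulate_dataset",
    "simulate_cluster_masks",
    "simulate_cluster_scene",
    "events_to_frame",
    "alive_at_frame",
]


# --------------------------------------------------------------------------
# lifetimes
# --------------------------------------------------------------------------

def simulate_lifetimes(n: int, k1: float, k2: float,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` lifetimes from the two-step degradation model.

    The lifetime of a complex that must pass through two sequential
    first-order steps with rates ``k1`` and ``k2`` is the sum of two
    independent exponential waiting times — the hypoexponential construction,
    which samples the target density P(tau) exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / k1, n) + rng.exponential(1.0 / k2, n)


# --------------------------------------------------------------------------
# cell geometry
# --------------------------------------------------------------------------

def simulate_cell(config: SimulationConfig) -> CellGeometry:
    """Ground-truth cell geometry: circular footprint, optional rigid drift.

    Returns a :class:`CellGeometry` with per-frame masks, dense boundary point
    sets and centroids (all in um). Raises ``ValueError`` when the cell (plus
    its total drift) does not fit inside the field of view.
    """
    n_frames = config.image_shape[0]
    fx, fy = config.field_size_um
    vx, vy = config.drift_velocity
    t_end = (n_frames - 1) * config.frame_interval
    c0 = np.array([fx / 2.0, fy / 2.0])
    times = np.arange(n_frames) * config.frame_interval
    centroids = c0[None, :] + np.outer(times, [vx, vy])
    r = config.cell_radius
    margin = config.pixel_size_xy
    lo = centroids.min(axis=0) - r
    hi = centroids.max(axis=0) + r
    if lo[0] < -margin or lo[1] < -margin or hi[0] > fx + margin or hi[1] > fy + margin:
        raise ValueError("cell (including drift) does not fit inside the field of view")

    theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    circle = np.column_stack((np.cos(theta), np.sin(theta))) * r
    boundaries = [c + circle for c in centroids]

    ny, nx = config.image_shape[2], config.image_shape[3]
    xs = np.arange(nx) * config.pixel_size_xy
    ys = np.arange(ny) * config.pixel_size_xy
    gx, gy = np.meshgrid(xs, ys)
    masks = np.zeros((n_frames, ny, nx), dtype=bool)
    for f, c in enumerate(centroids):
        masks[f] = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 <= r * r
    return CellGeometry(centroids=centroids, boundaries=boundaries,
                        pixel_size=config.pixel_size_xy, masks=masks)


# --------------------------------------------------------------------------
# nucleation events
# --------------------------------------------------------------------------

@dataclass
class GroundTruthEvent:
    """One simulated punctum: birth/death, lifetime and per-frame positions."""

    event_id: int
    birth_time: float
    death_time: float
    x: float  # initial absolute position, um
    y: float
    z: float
    compartment: str  # membrane | cytoplasm
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def lifetime(self) -> float:
        return self.death_time - self.birth_time


def simulate_events(config: SimulationConfig, geometry: CellGeometry,
                    rng: np.random.Generator | None = None
                    ) -> List[GroundTruthEvent]:
    """Nucleation events: Poisson births after the delay, placed by compartment.

    A fraction ``membrane_fraction`` of events is placed within the membrane
    band (distance to the boundary <= ``membrane_band`` um, itself inside the
    1.4 um classification band); the rest are placed in the interior at least
    ``cytoplasm_margin`` um from the boundary, uniformly by area. Lifetimes
    come from :func:`simulate_lifetimes`. Events co-move rigidly with the
    drifting cell; optional Brownian motion is added when
    ``diffusion_coefficient`` > 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    t_total = config.movie_duration
    window = t_total - config.formation_delay
    if config.nucleation_duration is not None:
        window = min(window, config.nucleation_duration)
    if window <= 0:
        return []
    n = int(rng.poisson(config.nucleation_rate * window))
    births = config.formation_delay + np.sort(rng.uniform(0.0, window, n))
    lifetimes = simulate_lifetimes(max(n, 1), config.k1, config.k2, rng=rng)[:n]
    is_membrane = rng.random(n) < config.membrane_fraction
    r_cell = config.cell_radius
    # dart-throwing placement with a minimum separation between nucleation
    # sites (relative to the cell centre; rigid drift preserves separations)
    rel_positions = np.empty((n, 2))
    for i in range(n):
        best, best_d = None, -1.0
        for _attempt in range(500):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            u = rng.random()
            if is_membrane[i]:
                rad = r_cell - u * config.membrane_band
            else:
                rad = (r_cell - config.cytoplasm_margin) * math.sqrt(u)
            cand = np.array([rad * math.cos(ang), rad * math.sin(ang)])
            if config.min_separation <= 0 or i == 0:
                best = cand
                break
            d = float(np.min(np.hypot(*(rel_positions[:i] - cand).T)))
            if d >= config.min_separation:
                best = cand
                break
            if d > best_d:  # keep the most isolated candidate as fallback
                best, best_d = cand, d
        rel_positions[i] = best
    zs = config.cell_z_offset + (0.25 + 0.5 * rng.random(n)) * config.cell_height
    step_sigma = math.sqrt(2.0 * config.diffusion_coefficient
                           * config.frame_interval)

    n_frames = config.image_shape[0]
    dt = config.frame_interval
    events: List[GroundTruthEvent] = []
    for i in range(n):
        birth, death = births[i], births[i] + lifetimes[i]
        rel = rel_positions[i]
        first = int(math.ceil(birth / dt))
        last = min(int(math.floor(death / dt - 1e-12)), n_frames - 1)
        if death / dt - math.floor(death / dt) == 0.0:
            last = min(last, int(death / dt) - 1)  # alive on [birth, death)
        frames = np.arange(first, last + 1) if last >= first else np.empty(0, int)
        if step_sigma > 0 and len(frames):
            walk = np.cumsum(rng.normal(0.0, step_sigma, (len(frames), 2)), axis=0)
            walk -= walk[0]
        else:
            walk = np.zeros((len(frames), 2))
        positions = geometry.centroids[frames] + rel[None, :] + walk \
            if len(frames) else np.empty((0, 2))
        birth_frame = min(max(first, 0), n_frames - 1)
        abs0 = geometry.centroids[birth_frame] + rel
        events.append(GroundTruthEvent(
            event_id=i, birth_time=float(birth), death_time=float(death),
            x=float(abs0[0]), y=float(abs0[1]), z=float(zs[i]),
            compartment="membrane" if is_membrane[i] else "cytoplasm",
            frames=frames, positions=positions))
    return events


def alive_at_frame(events: Sequence[GroundTruthEvent], frame: int) -> List[GroundTruthEvent]:
    """Events alive at (rendered in) a given frame index."""
    return [e for e in events if frame in set(e.frames.tolist())]


def events_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    """Tabulate events: one row per event with birth/death/lifetime/position."""
    rows = [{
        "event_id": e.event_id,
        "birth_s": e.birth_time,
        "death_s": e.death_time,
        "lifetime_s": e.lifetime,
        "x_um": e.x,
        "y_um": e.y,
        "z_um": e.z,
        "compartment": e.compartment,
    } for e in events]
    return pd.DataFrame(rows, columns=[
        "event_id", "birth_s", "death_s", "lifetime_s",
        "x_um", "y_um", "z_um", "compartment"])


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_stack(events: Sequence[GroundTruthEvent], geometry: CellGeometry,
                 config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 noise: bool = True) -> np.ndarray:
    """Render the 4D stack: cell slab + 3D Gaussian puncta + camera noise.

    The photon expectation is ``outside_level`` everywhere, ``background_level``
    inside the cell footprint within the cell slab, plus a 3D Gaussian of peak
    ``photon_amplitude`` per live punctum. With ``noise=True`` the returned
    stack is Poisson(expectation) + N(0, read_noise_sigma) rounded to uint16;
    with ``noise=False`` the float expectation itself is returned.
    """
    if config.photon_amplitude <= 0:
        raise ValueError("photon_amplitude must be positive")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_frames, nz, ny, nx = config.image_shape
    px, dz = config.pixel_size_xy, config.z_spacing
    sx = config.psf_sigma_xy / px
    sz = config.psf_sigma_z / dz
    z_lo = config.cell_z_offset
    z_hi = config.cell_z_offset + config.cell_height
    z_coords = np.arange(nz) * dz
    slab = (z_coords >= z_lo) & (z_coords <= z_hi)

    win_xy = int(math.ceil(4 * sx))
    win_z = int(math.ceil(4 * sz))
    off = np.arange(-win_xy, win_xy + 1, dtype=float)
    off_z = np.arange(-win_z, win_z + 1, dtype=float)

    out = np.empty((n_frames, nz, ny, nx),
                   dtype=np.uint16 if noise else np.float32)
    frame_events: List[List[Tuple[float, float]]] = [[] for _ in range(n_frames)]
    for e in events:
        for j, f in enumerate(e.frames):
            frame_events[int(f)].append((e.positions[j, 0], e.positions[j, 1], e.z))

    for f in range(n_frames):
        exp = np.full((nz, ny, nx), config.outside_level, dtype=np.float64)
        cell = geometry.masks[f] if geometry.masks is not None else None
        if cell is not None:
            exp[slab] = np.where(cell, config.background_level,
                                 config.outside_level)
        for (x_um, y_um, z_um) in frame_events[f]:
            cx, cy, cz = x_um / px, y_um / px, z_um / dz
            ix, iy, iz = int(round(cx)), int(round(cy)), int(round(cz))
            gx = np.exp(-((ix + off - cx) ** 2) / (2 * sx * sx))
            gy = np.exp(-((iy + off - cy) ** 2) / (2 * sx * sx))
            gz = np.exp(-((iz + off_z - cz) ** 2) / (2 * sz * sz))
            kernel = config.photon_amplitude * gz[:, None, None] \
                * gy[None, :, None] * gx[None, None, :]
            zs0, zs1 = max(0, iz - win_z), min(nz, iz + win_z + 1)
            ys0, ys1 = max(0, iy - win_xy), min(ny, iy + win_xy + 1)
            xs0, xs1 = max(0, ix - win_xy), min(nx, ix + win_xy + 1)
            kz0, ky0, kx0 = zs0 - (iz - win_z), ys0 - (iy - win_xy), xs0 - (ix - win_xy)
            exp[zs0:zs1, ys0:ys1, xs0:xs1] += kernel[
                kz0:kz0 + (zs1 - zs0), ky0:ky0 + (ys1 - ys0), kx0:kx0 + (xs1 - xs0)]
        if noise:
            counts = rng.poisson(exp).astype(np.float64)
            if config.read_noise_sigma > 0:
                counts += rng.normal(0.0, config.read_noise_sigma, exp.shape)
            out[f] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
        else:
            out[f] = exp.astype(np.float32)
    return out


def simulate_dataset(config: SimulationConfig, noise: bool = True):
    """Full simulation: (stack array, events, geometry), one seeded rng."""
    rng = np.random.default_rng(config.rng_seed)
    geometry = simulate_cell(config)
    events = simulate_events(config, geometry, rng=rng)
    stack = render_stack(events, geometry, config, rng=rng, noise=noise)
    return stack, events, geometry


# --------------------------------------------------------------------------
# cluster masks (fixed branch)
# --------------------------------------------------------------------------

@dataclass
class SyntheticClusterSet:
    """Binary cluster masks with analytically known morphometry."""

    masks: List[np.ndarray]
    pixel_size_nm: float
    table: pd.DataFrame  # true area/perimeter/shape factor/diameter per mask


def _irregular_polygon(rng: np.random.Generator, r0_nm: float,
                       amp_range: Tuple[float, float], n_vertices: int = 256):
    """Perturbed-circle polygon with analytic area/perimeter; resampled until
    its true shape factor is <= 0.85 so it is unambiguously non-spherical."""
    for _ in range(100):
        n_harm = rng.integers(2, 6)
        amps = rng.uniform(*amp_range, n_harm) / np.arange(1, n_harm + 1)
        phases = rng.uniform(0, 2 * math.pi, n_harm)
        theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
        radial = np.ones_like(theta)
        for k, (a, ph) in enumerate(zip(amps, phases), start=2):
            radial += a * np.cos(k * theta + ph)
        if radial.min() <= 0.15:
            continue
        r = r0_nm * radial
        x, y = r * np.cos(theta), r * np.sin(theta)
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        perim = float(np.sum(np.hypot(np.diff(np.append(x, x[0])),
                                      np.diff(np.append(y, y[0])))))
        sf = 4 * math.pi * area / perim ** 2
        if sf <= 0.85:
            return x, y, float(area), perim, float(sf)
    raise RuntimeError("failed to generate an irregular polygon")


def simulate_cluster_masks(n: int, pixel_size_nm: float = 10.0,
                           circular_fraction: float = 0.5,
                           size_range: Tuple[float, float] = (50.0, 500.0),
                           seed: int | None = None,
                           colocalised_fraction: float = 1.0,
                           irregularity: Tuple[float, float] = (0.10, 0.35),
                           ) -> SyntheticClusterSet:
    """Generate ``n`` binary cluster masks with known true morphometry.

    ``round(circular_fraction * n)`` members are rasterised disks (true shape
    factor exactly 1); the rest are perturbed polygons whose area and
    perimeter are computed analytically from the polygon before rasterisation.
    ``size_range`` is the diameter range in nm.
    """
    if not 0.0 <= circular_fraction <= 1.0:
        raise ValueError("circular_fraction must lie in [0, 1]")
    if not 0.0 <= colocalised_fraction <= 1.0:
        raise ValueError("colocalised_fraction must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    rng = np.random.default_rng(seed)
    n_circ = int(round(circular_fraction * n))
    masks: List[np.ndarray] = []
    rows = []
    for i in range(n):
        circular = i < n_circ
        diam = rng.uniform(*size_range)
        cx_off, cy_off = rng.uniform(0.0, 1.0, 2)  # sub-pixel centre offset
        if circular:
            r_nm = diam / 2.0
            r_px = r_nm / pixel_size_nm
            half = int(math.ceil(r_px)) + 3
            size = 2 * half + 1
            yy, xx = np.mgrid[0:size, 0:size].astype(float)
            cx, cy = half + cx_off, half + cy_off
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
            area = math.pi * r_nm ** 2
            perim = 2 * math.pi * r_nm
            sf = 1.0
        else:
            x_nm, y_nm, area, perim, sf = _irregular_polygon(
                rng, diam / 2.0, irregularity)
            x_px = x_nm / pixel_size_nm
            y_px = y_nm / pixel_size_nm
            half = int(math.ceil(max(np.abs(x_px).max(), np.abs(y_px).max()))) + 3
            size = 2 * half + 1
            rr, cc = draw_polygon(y_px + half + cy_off, x_px + half + cx_off,
                                  (size, size))
            mask = np.zeros((size, size), dtype=bool)
            mask[rr, cc] = True
        masks.append(mask)
        rows.append({
            "cluster_id": i,
            "circular": circular,
            "true_area_nm2": area,
            "true_perimeter_nm": perim,
            "true_shape_factor": sf,
            "true_diameter_nm": diam,
            "colocalised": bool(rng.random() < colocalised_fraction),
        })
    return SyntheticClusterSet(masks=masks, pixel_size_nm=pixel_size_nm,
                               table=pd.DataFrame(rows))


def simulate_cluster_scene(cluster_set: SyntheticClusterSet,
                           seed: int | None = None,
                           amplitude: float = 1000.0,
                           ref_sigma_nm: float = 150.0,
                           noise_sigma: float = 5.0,
                           blur_sigma_px: float = 1.5):
    """Place cluster masks on a shared canvas and render the two channels.

    Returns ``(sr_image, reference_image, placements)``: a super-resolved
    intensity image (cluster masks at ``amplitude`` counts, blurred by the
    reconstruction's effective localisation precision and with Gaussian
    noise added — thresholding at half-amplitude recovers the mask), a
    widefield-like reference channel with a Gaussian blob over every
    colocalised cluster (non-colocalised clusters get no reference signal and
    must be rejected by the colocalisation filter), and a table of
    ground-truth canvas centroids.
    """
    from scipy import ndimage as _ndi
    rng = np.random.default_rng(seed)
    masks = cluster_set.masks
    px_nm = cluster_set.pixel_size_nm
    cell = max(m.shape[0] for m in masks) + 16
    n = len(masks)
    grid = int(math.ceil(math.sqrt(n)))
    canvas = np.zeros((grid * cell, grid * cell), dtype=float)
    order = rng.permutation(n)
    rows = []
    for slot, idx in enumerate(order):
        m = masks[idx]
        gy, gx = divmod(slot, grid)
        oy = gy * cell + (cell - m.shape[0]) // 2
        ox = gx * cell + (cell - m.shape[1]) // 2
        canvas[oy:oy + m.shape[0], ox:ox + m.shape[1]] += m
        ys, xs = np.nonzero(m)
        rows.append({"cluster_id": int(idx),
                     "row_px": oy + ys.mean(), "col_px": ox + xs.mean()})
    placements = pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)

    sr = canvas * amplitude
    if blur_sigma_px > 0:
        sr = _ndi.gaussian_filter(sr, blur_sigma_px)
    sr = sr + rng.normal(0.0, noise_sigma, canvas.shape)
    ref = np.zeros_like(canvas)
    sig = ref_sigma_nm / px_nm
    half = int(math.ceil(4 * sig))
    off = np.arange(-half, half + 1, dtype=float)
    coloc = cluster_set.table.set_index("cluster_id")["colocalised"]
    for _, p in placements.iterrows():
        if not coloc.loc[int(p["cluster_id"])]:
            continue
        iy, ix = int(round(p["row_px"])), int(round(p["col_px"]))
        gy = np.exp(-((iy + off - p["row_px"]) ** 2) / (2 * sig * sig))
        gx = np.exp(-((ix + off - p["col_px"]) ** 2) / (2 * sig * sig))
        blob = 500.0 * np.outer(gy, gx)
        y0, y1 = max(0, iy - half), min(ref.shape[0], iy + half + 1)
        x0, x1 = max(0, ix - half), min(ref.shape[1], ix + half + 1)
        ref[y0:y1, x0:x1] += blob[y0 - (iy - half):y1 - (iy - half),
                                  x0 - (ix - half):x1 - (ix - half)]
    ref += rng.normal(0.0, 1.0, ref.shape)
    return sr, ref, placements
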