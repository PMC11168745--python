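"""Configuration objects for the simulation and the analysis pipelines.

Two dataclasses hold every tunable parameter:

* :class:`SimulationConfig` — the synthetic-imaging model (field of view,
  calibration, cell geometry, nucleation kinetics, degradation rates, optics
  and camera noise).
* :class:`PipelineConfig` — the analysis parameters. The defaults are the
  values used throughout the analysis: rolling-ball radius 80 px, 3D Gaussian
  blur sigma 1 px, detection prominence 20 counts, linking search range 8 px
  (0.85 um), memory 6 frames, minimum track length 2 frames, membrane
  threshold 1.4 um, frame interval 10 s, z step 0.2 um.

Configs round-trip losslessly through YAML/JSON; unknown keys are rejected so
that a typo in a threshold name fails loudly instead of being ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 4D acquisition.

    Spatial units are micrometres, time is seconds, intensities are camera
    counts. The defaults emulate the study conditions: z-stacks of 100 slices
    at 200 nm spacing acquired every 10 s, a single adherent cell roughly
    16 um across, diffraction-limited puncta nucleating predominantly at the
    cell boundary after a stimulus-dependent delay, with lifetimes drawn from
    the two-step degradation model.
    """

    #: (t, z, y, x) voxel counts of the rendered stack.
    image_shape: Tuple[int, int, int, int] = (180, 100, 256, 256)
    #: xy pixel size in um/px (0.85 um == 8 px).
    pixel_size_xy: float = 0.10625
    #: z slice spacing in um.
    z_spacing: float = 0.2
    #: time between consecutive z-scans in s.
    frame_interval: float = 10.0

    #: radius of the (circular) adherent cell footprint, um.
    cell_radius: float = 8.0
    #: height of the fluorescent cell slab, um.
    cell_height: float = 2.0
    #: z offset of the bottom of the cell slab above the first slice, um.
    cell_z_offset: float = 0.2
    #: rigid drift velocity of the cell, (vx, vy) um/s.
    drift_velocity: Tuple[float, float] = (0.0, 0.0)

    #: punctum nucleation rate after the delay, events/s.
    nucleation_rate: float = 0.02
    #: stimulus-to-first-possible-nucleation delay, s.
    formation_delay: float = 80.0
    #: duration of the nucleation window after the delay, s; None = until the
    #: end of the movie.
    nucleation_duration: float | None = None
    #: degradation rate constants of the two-step model, 1/s.
    k1: float = 0.005
    k2: float = 0.02
    #: fraction of events nucleating in the membrane band.
    membrane_fraction: float = 0.9
    #: width of the membrane placement band (distance from the boundary within
    #: which membrane events are placed), um. Kept well inside the 1.4 um
    #: classification threshold.
    membrane_band: float = 0.7
    #: minimum distance from the boundary for cytoplasmic events, um.
    cytoplasm_margin: float = 2.0
    #: punctum diffusion coefficient, um^2/s (0 = static puncta).
    diffusion_coefficient: float = 0.0
    #: minimum distance between nucleation sites, um. Two puncta closer than
    #: the linking search range (0.85 um) are unresolvable by construction, so
    #: ground-truth trajectories would be ill-defined; 0 disables the check.
    min_separation: float = 1.0

    #: PSF Gaussian sigmas, um.
    psf_sigma_xy: float = 0.15
    psf_sigma_z: float = 0.4
    #: peak expected photon count of a punctum above local background.
    photon_amplitude: float = 50.0
    #: expected counts inside the cell (camera offset + autofluorescence +
    #: diffuse cytosolic signal).
    background_level: float = 100.0
    #: expected counts outside the cell (camera offset + stray light). Kept
    #: close to background_level: a diffuse cytosolic excess much larger than
    #: the rolling ball can sag under a cell-sized plateau would leave a dome
    #: after background subtraction, which real cytosolic MyD88-YFP does not.
    outside_level: float = 85.0
    #: Gaussian camera read noise sigma, counts.
    read_noise_sigma: float = 2.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        t, z, y, x = self.image_shape
        if min(t, z, y, x) < 1:
            raise ValueError("all image dimensions must be >= 1")
        for name in (
            "pixel_size_xy",
            "z_spacing",
            "frame_interval",
            "cell_radius",
            "cell_height",
            "nucleation_rate",
            "k1",
            "k2",
            "membrane_band",
            "psf_sigma_xy",
            "psf_sigma_z",
            "photon_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("formation_delay", "cytoplasm_margin", "background_level",
                     "outside_level", "read_noise_sigma", "cell_z_offset",
                     "diffusion_coefficient", "min_separation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if self.nucleation_duration is not None and self.nucleation_duration <= 0:
            raise ValueError("nucleation_duration must be positive or None")
        if self.cytoplasm_margin >= self.cell_radius:
            raise ValueError("cytoplasm_margin must be smaller than cell_radius")
        if self.membrane_band > self.cell_radius:
            raise ValueError("membrane_band must not exceed cell_radius")

    @property
    def field_size_um(self) -> Tuple[float, float]:
        """(width_x, height_y) of the field of view in um."""
        _, _, ny, nx = self.image_shape
        return nx * self.pixel_size_xy, ny * self.pixel_size_xy

    @property
    def movie_duration(self) -> float:
        return self.image_shape[0] * self.frame_interval


@dataclass
class PipelineConfig:
    """Analysis parameters with the standard defaults (see module docstring)."""

    branch: str = "live"  # live | fixed | simulate

    # calibration (used when the input TIFF carries none)
    pixel_size_xy: float = 0.10625
    z_spacing: float = 0.2
    frame_interval: float = 10.0

    # preprocessing + detection
    ball_radius: int = 80
    blur_sigma: float = 1.0
    prominence: float = 20.0
    #: apply the rolling-ball per z-slice ("slice") or once on the brightest-
    #: point projection ("projection").
    background_mode: str = "slice"
    subpixel: bool = True

    # linking
    search_range: float = 8.0
    memory: int = 6
    min_track_length: int = 2

    # spatial classification
    membrane_threshold: float = 1.4
    distance_mode: str = "2d"

    # lifetime fitting
    fit_method: str = "mle"  # mle | histogram_lsq
    histogram_bin_width: float = 10.0
    interval_censored: bool = False
    n_bootstrap: int = 1000
    min_fit_n: int = 10

    # fixed (morphometry) branch
    spherical_tolerance: float = 0.05
    roi_expand_px: int = 2
    min_cluster_px: int = 4

    n_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch not in ("live", "fixed", "simulate"):
            raise ValueError("branch must be live, fixed or simulate")
        if self.background_mode not in ("slice", "projection"):
            raise ValueError("background_mode must be 'slice' or 'projection'")
        if self.distance_mode not in ("2d", "3d"):
            raise ValueError("distance_mode must be '2d' or '3d'")
        if self.fit_method not in ("mle", "histogram_lsq"):
            raise ValueError("fit_method must be 'mle' or 'histogram_lsq'")
        if self.ball_radius < 1:
            raise ValueError("ball_radius must be >= 1")
        for name in ("blur_sigma", "prominence", "search_range",
                     "membrane_threshold", "frame_interval", "pixel_size_xy",
                     "z_spacing", "histogram_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"valid keys are {sorted(names)}"
        )
    # YAML/JSON lists -> tuples for tuple-typed fields
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path: str | Path, kind: str = "pipeline"):
    """Load a YAML/JSON config file. ``kind`` is 'pipeline' or 'simulation'."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cls = PipelineConfig if kind == "pipeline" else SimulationConfig
    return _from_mapping(cls, data)


def save_config(config, path: str | Path) -> None:
    """Serialise a config dataclass to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)
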