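"""Validated run configuration for the correlative pipeline.

All physical sizes are nanometres, all times are frame indices, and pixel
indices are 0-based.  The pixel-centre convention ``nm = (index + 0.5) *
pixel_size`` is used everywhere a pixel grid meets physical coordinates, so
that rendering and registration share the same origin without half-pixel
bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ContractError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every fixed parameter of the pipeline, with acquisition defaults.

    Parameters
    ----------
    live_pixel_size : float
        Camera pixel size of the live movies after 4x4 binning, nm.
    live_frame_rate : float
        Effective per-channel acquisition rate, Hz (channels alternate).
    stim_frame : int
        Frame index (per channel, 0-based) at which the stimulus arrives.
    roi_size : int
        Side of the square bouton ROI in live pixels.
    bg_size : int
        Side of the square background ROI in live pixels.
    smooth_window : int
        Length of the trailing moving-average window applied to traces.
    baseline_frames : int
        Number of pre-stimulus frames averaged for the baseline.
    peak_window : int
        Number of frames from the stimulus (inclusive) searched for the peak.
    response_sd_factor : float
        A bouton responds when its peak change exceeds this multiple of the
        baseline standard deviation.
    storm_camera_pixel : float
        dSTORM camera pixel size, nm (sets the default pairing tolerance).
    render_pixel : float
        Pixel size of rendered super-resolution images, nm.
    density_factor : float
        Voronoi density threshold as a multiple of the dataset mean density.
    max_neighbour_dist : tuple of float
        Cluster linkage distance per colour (colour 1, colour 2), nm.
    min_molecules : tuple of int
        Minimum detections for a cluster per colour (colour 1, colour 2).
    match_dist : float
        Maximum live-to-dSTORM synapse matching distance, nm (also the
        default orphan-assignment distance).
    seed : int
        Seed for every stochastic component.
    baseline_sd_on_smoothed : bool
        Whether the baseline s.d. used by the responder threshold is taken
        on the smoothed trace or (default) the raw background-subtracted
        trace.  The raw trace gives an unbiased noise scale: smoothing
        correlates neighbouring baseline samples, which biases the
        15-sample s.d. estimate downward and inflates the false-positive
        rate of the responder test.
    """

    live_pixel_size: float = 433.0
    live_frame_rate: float = 12.5
    stim_frame: int = 30
    roi_size: int = 5
    bg_size: int = 15
    smooth_window: int = 4
    baseline_frames: int = 15
    peak_window: int = 15
    response_sd_factor: float = 3.0
    storm_camera_pixel: float = 97.0
    render_pixel: float = 10.0
    density_factor: float = 1.0
    max_neighbour_dist: tuple[float, float] = (200.0, 100.0)
    min_molecules: tuple[int, int] = (200, 20)
    match_dist: float = 500.0
    seed: int = 0
    baseline_sd_on_smoothed: bool = False

    def __post_init__(self) -> None:
        self.max_neighbour_dist = tuple(float(v) for v in self.max_neighbour_dist)
        self.min_molecules = tuple(int(v) for v in self.min_molecules)
        positive = {
            "live_pixel_size": self.live_pixel_size,
            "live_frame_rate": self.live_frame_rate,
            "roi_size": self.roi_size,
            "bg_size": self.bg_size,
            "smooth_window": self.smooth_window,
            "baseline_frames": self.baseline_frames,
            "peak_window": self.peak_window,
            "response_sd_factor": self.response_sd_factor,
            "storm_camera_pixel": self.storm_camera_pixel,
            "render_pixel": self.render_pixel,
            "density_factor": self.density_factor,
            "match_dist": self.match_dist,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ContractError(f"{name} must be strictly positive, got {value!r}")
        if self.stim_frame < 0:
            raise ContractError(f"stim_frame must be >= 0, got {self.stim_frame}")
        if self.roi_size >= self.bg_size:
            raise ContractError(
                f"roi_size ({self.roi_size}) must be smaller than bg_size ({self.bg_size})"
            )
        for name, pair in (
            ("max_neighbour_dist", self.max_neighbour_dist),
            ("min_molecules", self.min_molecules),
        ):
            if len(pair) != 2:
                raise ContractError(f"{name} must list one value per colour (length 2)")
            if not all(v > 0 for v in pair):
                raise ContractError(f"{name} entries must be strictly positive")

    # -- colour-indexed access (colours are 1-based, matching the field's usage)

    def neighbour_dist(self, colour: int) -> float:
        return self.max_neighbour_dist[_colour_index(colour)]

    def min_mol(self, colour: int) -> int:
        return self.min_molecules[_colour_index(colour)]

    # -- YAML round trip

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["max_neighbour_dist"] = list(self.max_neighbour_dist)
        data["min_molecules"] = list(self.min_molecules)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _colour_index(colour: int) -> int:
    if colour not in (1, 2):
        raise ContractError(f"colour must be 1 or 2, got {colour!r}")
    return colour - 1
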