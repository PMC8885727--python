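"""Live-imaging trace analysis: from two-channel movies to per-bouton
response measures and responder classification.

The measurement chain per bouton: mean over a square ROI centred on the
punctum, minus the mean over a single larger background ROI, per channel;
trailing moving-average smoothing; baseline = mean of the pre-stimulus
frames; peak change = max over a fixed post-stimulus window.  A bouton is a
calcium responder when its peak red change exceeds ``response_sd_factor``
baseline standard deviations, and analogously for release on the green
channel.  Responses are normalised to the red baseline R0, which reports
the reporter amount at the synapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .config import PipelineConfig
from .errors import ContractError, PlacementError
from .io import FluorescenceMovie

__all__ = [
    "TraceSet",
    "SynapseResponse",
    "extract_traces",
    "smooth_trace",
    "analyse_response",
    "auto_background_centre",
]

log = logging.getLogger(__name__)


@dataclass
class TraceSet:
    """Per-bouton raw and background-subtracted traces for both channels."""

    g_raw: np.ndarray            # (n_boutons, n_frames) ROI means, green
    r_raw: np.ndarray            # (n_boutons, n_frames) ROI means, red
    bg_g: np.ndarray             # (n_frames,) background ROI mean, green
    bg_r: np.ndarray             # (n_frames,) background ROI mean, red
    centres: np.ndarray          # (n_boutons, 2) ROI centres, live px (row, col)
    bg_centre: tuple[int, int]
    stim_frame: int

    @property
    def g(self) -> np.ndarray:
        """Background-subtracted green traces."""
        return self.g_raw - self.bg_g[None, :]

    @property
    def r(self) -> np.ndarray:
        """Background-subtracted red traces."""
        return self.r_raw - self.bg_r[None, :]

    @property
    def n_boutons(self) -> int:
        return self.g_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.g_raw.shape[1]


@dataclass
class SynapseResponse:
    """Derived response measures for one bouton.

    ``dG_over_dR`` is reported only for calcium responders with a positive
    red change; otherwise it is NaN.  ``valid`` is False when the red
    baseline is non-positive, in which case the record is excluded from all
    downstream analysis.
    """

    bouton_id: int
    G0: float
    R0: float
    baseline_sd_G: float
    baseline_sd_R: float
    dG: float
    dR: float
    dG_over_R: float
    dR_over_R: float
    dG_over_dR: float
    calcium_responder: bool
    release_detected: bool
    valid: bool = True
    reason: str = ""


def _roi_mean_trace(data: np.ndarray, centre, size: int, what: str) -> np.ndarray:
    half = size // 2
    r, c = int(centre[0]), int(centre[1])
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    if r0 < 0 or c0 < 0 or r1 > data.shape[1] or c1 > data.shape[2]:
        raise PlacementError(
            f"{what}: {size}x{size} ROI at ({r}, {c}) is clipped by the frame edge"
        )
    return data[:, r0:r1, c0:c1].mean(axis=(1, 2))


def auto_background_centre(movie: FluorescenceMovie, cfg: PipelineConfig) -> tuple[int, int]:
    """Default background ROI: centre of the minimum-mean bg_size square of
    the time-averaged image (darkest region of the field)."""
    mean_img = movie.data.mean(axis=0)
    half = cfg.bg_size // 2
    # zero padding is irrelevant: only fully interior windows are considered
    local = uniform_filter(mean_img, size=cfg.bg_size, mode="constant", cval=0.0)
    interior = np.full(mean_img.shape, np.inf)
    interior[half : mean_img.shape[0] - half, half : mean_img.shape[1] - half] = local[
        half : mean_img.shape[0] - half, half : mean_img.shape[1] - half
    ]
    r, c = np.unravel_index(np.argmin(interior), interior.shape)
    return int(r), int(c)


def extract_traces(
    g_movie: FluorescenceMovie,
    r_movie: FluorescenceMovie,
    centres: np.ndarray,
    cfg: PipelineConfig,
    bg_centre: tuple[int, int] | None = None,
) -> TraceSet:
    """Extract background-subtracted ROI traces for each bouton.

    ``centres`` are (row, col) live-pixel positions of the bouton ROIs; a
    single ``bg_size`` background ROI serves the whole field (chosen
    automatically as the darkest region if not given).
    """
    if g_movie.data.shape != r_movie.data.shape:
        raise ContractError("G and R movies must have identical shapes")
    centres = np.atleast_2d(np.asarray(centres))
    if bg_centre is None:
        bg_centre = auto_background_centre(g_movie, cfg)

    g_tr = np.empty((len(centres), g_movie.n_frames))
    r_tr = np.empty_like(g_tr)
    for i, ctr in enumerate(centres):
        g_tr[i] = _roi_mean_trace(g_movie.data, ctr, cfg.roi_size, f"bouton {i}")
        r_tr[i] = _roi_mean_trace(r_movie.data, ctr, cfg.roi_size, f"bouton {i}")
    bg_g = _roi_mean_trace(g_movie.data, bg_centre, cfg.bg_size, "background")
    bg_r = _roi_mean_trace(r_movie.data, bg_centre, cfg.bg_size, "background")
    stim = g_movie.stim_frame if g_movie.stim_frame is not None else cfg.stim_frame
    return TraceSet(
        g_raw=g_tr,
        r_raw=r_tr,
        bg_g=bg_g,
        bg_r=bg_r,
        centres=centres,
        bg_centre=tuple(int(v) for v in bg_centre),
        stim_frame=int(stim),
    )


def smooth_trace(trace: np.ndarray, window: int) -> np.ndarray:
    """Trailing (causal) moving average over ``window`` frames.

    ``out[t] = mean(trace[max(0, t - window + 1) .. t])`` — partial windows
    at the start average what is available, so no post-stimulus signal can
    leak backwards into the baseline.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if window < 1:
        raise ContractError(f"window must be >= 1, got {window}")
    if window > n:
        raise ContractError(f"window ({window}) exceeds trace length ({n})")
    if window == 1:
        return trace.copy()
    # direct windowed sums (not cumsum differences) so constant traces stay
    # exactly constant and window = 1 is the exact identity
    kernel = np.ones(window)
    counts = np.minimum(np.arange(1, n + 1), window)
    sums = np.apply_along_axis(lambda v: np.convolve(v, kernel)[:n], -1, trace)
    return sums / counts


def analyse_response(traces: TraceSet, cfg: PipelineConfig) -> list[SynapseResponse]:
    """Compute per-bouton response measures on the smoothed traces.

    Baseline = mean of the ``baseline_frames`` frames ending at
    ``stim_frame - 1``; peak change = max over the ``peak_window`` frames
    starting at ``stim_frame`` (inclusive), relative to baseline.  Responder
    thresholds use strict inequality so that a flat zero-variance trace
    never classifies as responding.
    """
    stim = traces.stim_frame
    if stim - cfg.baseline_frames < 0 or stim + cfg.peak_window > traces.n_frames:
        raise ContractError(
            f"stim_frame {stim} leaves no room for baseline "
            f"({cfg.baseline_frames}) or peak window ({cfg.peak_window})"
        )
    base_sl = slice(stim - cfg.baseline_frames, stim)
    peak_sl = slice(stim, stim + cfg.peak_window)

    out: list[SynapseResponse] = []
    for i in range(traces.n_boutons):
        sm_g = smooth_trace(traces.g[i], cfg.smooth_window)
        sm_r = smooth_trace(traces.r[i], cfg.smooth_window)
        G0 = float(sm_g[base_sl].mean())
        R0 = float(sm_r[base_sl].mean())
        if cfg.baseline_sd_on_smoothed:
            sd_g = float(sm_g[base_sl].std(ddof=1))
            sd_r = float(sm_r[base_sl].std(ddof=1))
        else:
            sd_g = float(traces.g[i][base_sl].std(ddof=1))
            sd_r = float(traces.r[i][base_sl].std(ddof=1))
        dG = float(sm_g[peak_sl].max() - G0)
        dR = float(sm_r[peak_sl].max() - R0)
        calcium = dR > cfg.response_sd_factor * sd_r
        release = dG > cfg.response_sd_factor * sd_g
        if R0 <= 0:
            log.warning("bouton %d excluded: non-positive red baseline R0=%.3g", i, R0)
            out.append(
                SynapseResponse(
                    i, G0, R0, sd_g, sd_r, dG, dR,
                    np.nan, np.nan, np.nan, False, False,
                    valid=False, reason="non-positive R0",
                )
            )
            continue
        dG_over_R = dG / R0
        dR_over_R = dR / R0
        dG_over_dR = dG / dR if (calcium and dR > 0) else np.nan
        out.append(
            SynapseResponse(
                i, G0, R0, sd_g, sd_r, dG, dR,
                dG_over_R, dR_over_R, dG_over_dR, calcium, release,
            )
        )
    return out
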