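"""Synthetic ground-truth generators for every input the pipeline consumes.

These emulate, at a controllable scale, the three experimental layers:

* stimulus-locked two-channel bouton movies (green SypHy reporting vesicle
  release, red RGECO reporting calcium influx) with additive Gaussian noise;
* two-camera single-emitter tables for spectral demixing, where each
  emitter's photons split between cameras with a fluorophore-specific ratio;
* clustered 3D localisation scenes — one diffuse colour-1 (vesicle pool)
  cluster per synapse plus 1-6 compact colour-2 subsynaptic domains (SSDs)
  on its periphery, over uniform Poisson background;

plus a known affine map between the live and dSTORM coordinate frames and a
programmable coupling between structure (SSD point count) and function
(green response amplitude).  Every generator is deterministic under a fixed
seed and returns the ground truth needed to score the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import ContractError, PlacementError
from .io import FluorescenceMovie, make_localizations

__all__ = [
    "SceneGroundTruth",
    "simulate_functional_movie",
    "simulate_two_camera_emitters",
    "simulate_synapse_scene",
    "simulate_correlative_dataset",
]

#: Spatial sigma of a simulated bouton spot, live pixels.
SPOT_SIGMA_PX = 1.5
#: Decay time constants of the green / red response kernels, frames.
TAU_G, TAU_R = 40.0, 8.0
#: Default baselines (arbitrary camera units): green low, red high.
G0_DEFAULT, R0_DEFAULT = 10.0, 100.0
#: Log-sigma of the emitter total-photon distribution.
PHOTON_SIGMA_LOG = 0.5


@dataclass
class SceneGroundTruth:
    """Everything a scorer needs to check pipeline output against truth.

    Only the fields relevant to the generator that produced it are filled.
    """

    # functional side
    centres_px: np.ndarray | None = None          # (n, 2) live-pixel bouton centres
    amplitudes: np.ndarray | None = None          # (n, 2) programmed (dG, dR)
    baselines: tuple[float, float] = (G0_DEFAULT, R0_DEFAULT)
    responder: np.ndarray | None = None           # programmed dR > 0
    bg_centre: tuple[int, int] | None = None
    # structural side
    centres_nm: np.ndarray | None = None          # (n, 3) synapse centres, nm
    colour1_labels: np.ndarray | None = None      # per colour-1 point: synapse id, -1 bg
    colour2_labels: np.ndarray | None = None      # per colour-2 point: synapse id, -1 bg
    colour2_ssd: np.ndarray | None = None         # per colour-2 point: SSD id within synapse
    ssd_counts: np.ndarray | None = None          # programmed SSDs per synapse
    ssd_points: np.ndarray | None = None          # total colour-2 points per synapse
    # registration / coupling
    affine: tuple[np.ndarray, np.ndarray] | None = None   # (A 2x2, t 2)
    drift: np.ndarray | None = None               # (n_bins, 3): frame, dx, dy
    coupling: str | None = None                   # "positive" | "null"
    coupling_coeff: float | None = None


# ---------------------------------------------------------------------------
# functional movies


def _response_kernel(
    n_frames: int, stim: int, amplitude: float, tau: float, plateau: int
) -> np.ndarray:
    """Step at ``stim``, flat for ``plateau`` frames, then exponential decay.

    The plateau is at least as long as the smoothing window so that a
    trailing moving average recovers the programmed amplitude exactly on
    noiseless data.
    """
    t = np.arange(n_frames, dtype=float)
    out = np.zeros(n_frames)
    on = t >= stim
    out[on] = amplitude
    decay = t >= stim + plateau
    out[decay] = amplitude * np.exp(-(t[decay] - (stim + plateau - 1)) / tau)
    return out


def default_bouton_grid(n: int, spacing: int, margin: int) -> np.ndarray:
    """Integer (row, col) centres on a square grid with the given spacing."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centres = np.stack([rr.ravel(), cc.ravel()], axis=1)[:n]
    return centres * spacing + margin


def simulate_functional_movie(
    cfg: PipelineConfig,
    n_synapses: int,
    amplitudes: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    baselines: tuple[float, float] = (G0_DEFAULT, R0_DEFAULT),
    centres: np.ndarray | None = None,
    n_frames: int | None = None,
    plateau: int | None = None,
) -> tuple[FluorescenceMovie, FluorescenceMovie, SceneGroundTruth]:
    """Simulate matched green/red movies of responding boutons.

    Each bouton is a Gaussian spot (sigma 1.5 px) whose ROI-mean time course
    is ``baseline + kernel``: a step of the programmed amplitude at
    ``cfg.stim_frame``, a plateau of at least ``cfg.smooth_window`` frames,
    then exponential decay (tau 40 frames green, 8 frames red).  The spot
    profile is normalised so the mean over the central ``roi_size`` square
    equals 1 — the extracted background-subtracted ROI trace therefore
    equals the programmed time course exactly in the noiseless case.
    I.i.d. Gaussian noise of ``noise_sd`` is added per pixel.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if amplitudes.shape != (n_synapses, 2):
        raise ContractError(
            f"amplitudes must be (n_synapses, 2) = ({n_synapses}, 2), "
            f"got {amplitudes.shape}"
        )
    spacing = cfg.bg_size + 2
    margin = cfg.bg_size
    if centres is None:
        centres = default_bouton_grid(n_synapses, spacing, margin)
    centres = np.asarray(centres, dtype=int)
    if len(centres) != n_synapses:
        raise ContractError("centres must have one row per synapse")
    if n_synapses > 1:
        from scipy.spatial.distance import pdist

        if pdist(centres.astype(float), metric="chebyshev").min() <= cfg.bg_size:
            raise PlacementError(
                f"bouton centres must be separated by more than bg_size "
                f"({cfg.bg_size}) pixels"
            )
    if n_frames is None:
        n_frames = cfg.stim_frame + cfg.peak_window + 25
    if plateau is None:
        plateau = cfg.smooth_window + 2
    if plateau < cfg.smooth_window:
        raise ContractError("plateau must cover the smoothing window")

    half = cfg.roi_size // 2
    kernel_half = 3 * int(np.ceil(SPOT_SIGMA_PX)) + half
    # frame extends past the spots, leaving a strictly dark band at the
    # bottom for the background ROI (spot kernels are finite)
    content = tuple(int(centres[:, k].max()) + kernel_half for k in (0, 1))
    shape = (
        content[0] + cfg.bg_size + 4,
        max(content[1] + kernel_half + 1, cfg.bg_size + 2),
    )
    ax = np.arange(-kernel_half, kernel_half + 1, dtype=float)
    spot = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * SPOT_SIGMA_PX**2))
    core = spot[
        kernel_half - half : kernel_half + half + 1,
        kernel_half - half : kernel_half + half + 1,
    ]
    spot = spot / core.mean()  # ROI-mean of the spot is exactly 1

    rng = np.random.default_rng(seed)
    movies = []
    for ch, (base, tau) in enumerate(((baselines[0], TAU_G), (baselines[1], TAU_R))):
        frames = np.zeros((n_frames,) + shape)
        for i, (r, c) in enumerate(centres):
            kern = _response_kernel(
                n_frames, cfg.stim_frame, amplitudes[i, ch], tau, plateau
            )
            trace = base + kern
            r0, r1 = r - kernel_half, r + kernel_half + 1
            c0, c1 = c - kernel_half, c + kernel_half + 1
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise PlacementError(f"bouton {i} spot extends beyond the frame")
            frames[:, r0:r1, c0:c1] += trace[:, None, None] * spot
        if noise_sd > 0:
            frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        movies.append(frames)

    dR = amplitudes[:, 1]
    truth = SceneGroundTruth(
        centres_px=centres,
        amplitudes=amplitudes,
        baselines=tuple(baselines),
        responder=dR > 0,
        bg_centre=(shape[0] - cfg.bg_size // 2 - 1, cfg.bg_size // 2 + 1),
    )
    g = FluorescenceMovie(
        movies[0], "G", cfg.live_pixel_size, cfg.live_frame_rate, cfg.stim_frame
    )
    r = FluorescenceMovie(
        movies[1], "R", cfg.live_pixel_size, cfg.live_frame_rate, cfg.stim_frame
    )
    return g, r, truth


# ---------------------------------------------------------------------------
# two-camera emitters (spectral demixing input)


def simulate_two_camera_emitters(
    n_per_fluor: tuple[int, int],
    ratio_means: tuple[float, float] = (0.75, 0.30),
    ratio_sd: float = 0.05,
    photon_budget: float = 2000.0,
    seed: int = 0,
    *,
    box_nm: float = 10_000.0,
    n_frames: int = 1000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate single emitters whose photons split between two cameras.

    Each emitter's total photon count is lognormal with mean
    ``photon_budget``; its photon ratio rho = I_cam1/(I_cam1+I_cam2) is
    normal around the fluorophore mean (0.75 for the camera-1-favouring
    fluorophore A, 0.30 for B), truncated to [0, 1].  Positions are uniform
    in a square field; frames are uniform.  Returns the table (intensities
    filled, ratio and labels left for the pipeline) and the true labels.
    """
    if ratio_sd <= 0:
        raise ContractError(f"ratio_sd must be > 0, got {ratio_sd}")
    mu_a, mu_b = ratio_means
    if not (0 < mu_b < mu_a < 1):
        raise ContractError(
            f"ratio means must satisfy 0 < mu_B < mu_A < 1, got {ratio_means}"
        )
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for n, mu, name in ((n_per_fluor[0], mu_a, "fluorA"), (n_per_fluor[1], mu_b, "fluorB")):
        if n == 0:
            continue
        a, b = (0.0 - mu) / ratio_sd, (1.0 - mu) / ratio_sd
        rho = stats.truncnorm.rvs(a, b, loc=mu, scale=ratio_sd, size=n, random_state=rng)
        mu_log = np.log(photon_budget) - PHOTON_SIGMA_LOG**2 / 2
        total = rng.lognormal(mu_log, PHOTON_SIGMA_LOG, size=n)
        df = make_localizations(
            x=rng.uniform(0, box_nm, n),
            y=rng.uniform(0, box_nm, n),
            z=np.zeros(n),
            frame=rng.integers(0, n_frames, n),
            I_cam1=rho * total,
            I_cam2=(1.0 - rho) * total,
        )
        rows.append(df)
        labels.append(np.full(n, name, dtype=object))
    if not rows:
        return make_localizations(x=np.empty(0), y=np.empty(0)), np.empty(0, dtype=object)
    table = pd.concat(rows, ignore_index=True)
    return table, np.concatenate(labels)


# ---------------------------------------------------------------------------
# clustered 3D scenes


def _grid_centres_nm(
    n: int, spacing: float, margin: float, z_span: float, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[float, float, float]]:
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xx, yy = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
    xy = np.stack([xx.ravel(), yy.ravel()], axis=1)[:n] * spacing + margin
    z = rng.uniform(-z_span / 6, z_span / 6, size=n)
    centres = np.column_stack([xy, z])
    box = (cols * spacing + margin, rows * spacing + margin, z_span)
    return centres, box


def simulate_synapse_scene(
    n_synapses: int,
    ssd_count_range: tuple[int, int] = (1, 6),
    colour1_n: tuple[int, int] = (400, 2000),
    colour1_sigma: float = 150.0,
    ssd_n: tuple[int, int] = (20, 200),
    ssd_sigma: float = 40.0,
    ssd_offset: float = 150.0,
    background_density: float = 2.0,
    z_span: float = 1000.0,
    seed: int = 0,
    *,
    centres_nm: np.ndarray | None = None,
    box_nm: tuple[float, float, float] | None = None,
    min_separation: float = 2000.0,
) -> tuple[dict[int, np.ndarray], SceneGroundTruth]:
    """Simulate a two-colour 3D localisation scene.

    Per synapse: ``colour1_n`` (drawn uniformly from the range) colour-1
    points Gaussian around the synapse centre (lateral sigma
    ``colour1_sigma``, axial sigma capped to respect the ~1 um usable z
    range), and 1-6 colour-2 SSDs, each a compact Gaussian subcluster
    (sigma ``ssd_sigma``) offset ``ssd_offset`` nm from the colour-1
    centroid — emulating active-zone protein nanodomains sitting on the
    vesicle-cloud periphery.  Uniform Poisson background is added to both
    colours at ``background_density`` points/um^3.
    """
    rng = np.random.default_rng(seed)
    if centres_nm is None:
        centres_nm, box = _grid_centres_nm(
            n_synapses, max(min_separation, 3000.0), 1500.0, z_span, rng
        )
    else:
        centres_nm = np.asarray(centres_nm, dtype=float)
        if centres_nm.shape != (n_synapses, 3):
            raise ContractError("centres_nm must be (n_synapses, 3)")
        if box_nm is None:
            span = centres_nm.max(axis=0) - centres_nm.min(axis=0)
            box = tuple(span + 3000.0)
        else:
            box = box_nm
    if n_synapses > 1:
        from scipy.spatial.distance import pdist

        if pdist(centres_nm[:, :2]).min() < min_separation:
            raise PlacementError(
                f"synapse centres must be >= {min_separation} nm apart"
            )
    if box_nm is not None:
        area_needed = n_synapses * min_separation**2
        if box[0] * box[1] < area_needed:
            raise PlacementError("box too small for the requested synapse count")

    z_sigma1 = min(colour1_sigma, z_span / 10)
    lo, hi = ssd_count_range
    pts1, lab1 = [], []
    pts2, lab2, ssd_lab = [], [], []
    ssd_counts = np.zeros(n_synapses, dtype=int)
    ssd_points = np.zeros(n_synapses, dtype=int)
    for s, centre in enumerate(centres_nm):
        n1 = int(rng.integers(colour1_n[0], colour1_n[1] + 1))
        sigma = np.array([colour1_sigma, colour1_sigma, z_sigma1])
        pts1.append(centre + rng.normal(0, 1, (n1, 3)) * sigma)
        lab1.append(np.full(n1, s))
        k = int(rng.integers(lo, hi + 1))
        ssd_counts[s] = k
        # SSDs sit on the active-zone periphery at evenly spaced angles;
        # the ring radius grows with the SSD count so adjacent domains stay
        # separated by more than the colour-2 linkage distance (synapses
        # with more SSDs are bigger)
        # adjacent-domain chord must clear two ~3.5 sigma tails plus the
        # linkage distance: 2 r sin(pi/k) >= 2*3.5*sigma + 100 + slack
        half_gap = 3.5 * ssd_sigma + 60.0
        radius = ssd_offset if k == 1 else max(ssd_offset, half_gap / np.sin(np.pi / k))
        phase = rng.uniform(0, 2 * np.pi)
        for j in range(k):
            theta = phase + 2 * np.pi * (j + rng.uniform(-0.05, 0.05)) / k
            direction = np.array(
                [np.cos(theta), np.sin(theta), rng.uniform(-0.1, 0.1)]
            )
            direction /= np.linalg.norm(direction)
            sc = centre + direction * radius
            n2 = int(rng.integers(ssd_n[0], ssd_n[1] + 1))
            sig2 = np.array([ssd_sigma, ssd_sigma, ssd_sigma])
            pts2.append(sc + rng.normal(0, 1, (n2, 3)) * sig2)
            lab2.append(np.full(n2, s))
            ssd_lab.append(np.full(n2, j))
            ssd_points[s] += n2

    # uniform Poisson background over the box, both colours
    vol_um3 = box[0] * box[1] * box[2] * 1e-9
    origin = centres_nm.min(axis=0) - 1500.0
    for pts, lab, extra in ((pts1, lab1, None), (pts2, lab2, ssd_lab)):
        n_bg = rng.poisson(background_density * vol_um3)
        if n_bg > 0:
            bg = origin + rng.uniform(0, 1, (n_bg, 3)) * np.asarray(box)
            pts.append(bg)
            lab.append(np.full(n_bg, -1))
            if extra is not None:
                extra.append(np.full(n_bg, -1))

    points = {1: np.vstack(pts1), 2: np.vstack(pts2)}
    truth = SceneGroundTruth(
        centres_nm=centres_nm,
        colour1_labels=np.concatenate(lab1).astype(int),
        colour2_labels=np.concatenate(lab2).astype(int),
        colour2_ssd=np.concatenate(ssd_lab).astype(int),
        ssd_counts=ssd_counts,
        ssd_points=ssd_points,
    )
    return points, truth


# ---------------------------------------------------------------------------
# end-to-end correlative dataset


def _draw_affine(
    cfg: PipelineConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """An invertible live-px -> nm map: scale near the live pixel size with
    a small rotation and shear, plus a translation of a few hundred nm."""
    scale = cfg.live_pixel_size * (1.0 + rng.uniform(-0.02, 0.02))
    theta = rng.uniform(-np.deg2rad(3), np.deg2rad(3))
    shear = rng.uniform(-0.02, 0.02)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    A = scale * rot @ sh
    t = rng.uniform(-500.0, 500.0, size=2)
    return A, t


def simulate_correlative_dataset(
    cfg: PipelineConfig,
    n_synapses: int = 20,
    coupling: str = "positive",
    coupling_coeff: float = 0.02,
    seed: int = 0,
    *,
    noise_sd: float = 0.5,
    sigma_log: float = 0.3,
    n_landmarks: int = 6,
    background_density: float = 2.0,
    ssd_count_range: tuple[int, int] = (1, 6),
    colour1_n: tuple[int, int] = (400, 900),
    ssd_n: tuple[int, int] = (40, 150),
) -> tuple[
    FluorescenceMovie, FluorescenceMovie, dict[int, np.ndarray],
    np.ndarray, np.ndarray, SceneGroundTruth,
]:
    """Simulate a full correlative experiment with known coupling.

    Bouton centres are laid out in live pixel space, mapped through a random
    invertible affine into nm space where the point-cloud scene is placed.
    Under ``positive`` coupling the green amplitude is
    ``coupling_coeff * (total SSD points) * exp(N(0, sigma_log))``; under
    ``null`` it is drawn independently.  Returns ``(G movie, R movie,
    points-per-colour, src landmarks (live px), dst landmarks (nm), truth)``.
    """
    if coupling not in ("positive", "null"):
        raise ContractError(f"coupling must be 'positive' or 'null', got {coupling!r}")
    if coupling == "positive" and n_synapses < 3:
        warnings.warn(
            "fewer than 3 synapses with positive coupling: correlation is underpowered",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    A, t = _draw_affine(cfg, rng)

    spacing = cfg.bg_size + 2
    centres_px = default_bouton_grid(n_synapses, spacing, cfg.bg_size)
    # spec/pixel convention: (row, col) indexes -> (x, y) = (col, row)
    src_xy = centres_px[:, ::-1].astype(float)
    centres_nm_xy = src_xy @ A.T + t
    z = rng.uniform(-100.0, 100.0, n_synapses)
    centres_nm = np.column_stack([centres_nm_xy, z])

    points, scene = simulate_synapse_scene(
        n_synapses,
        ssd_count_range=ssd_count_range,
        colour1_n=colour1_n,
        ssd_n=ssd_n,
        background_density=background_density,
        seed=int(rng.integers(0, 2**31 - 1)),
        centres_nm=centres_nm,
        min_separation=min(2000.0, spacing * cfg.live_pixel_size * 0.9),
    )

    dR = rng.uniform(40.0, 80.0, n_synapses)
    if coupling == "positive":
        noise = np.exp(rng.normal(0.0, sigma_log, n_synapses)) if sigma_log > 0 else 1.0
        dG = coupling_coeff * scene.ssd_points * noise
    else:
        dG = np.exp(rng.normal(np.log(3.0), 0.5, n_synapses))
    amplitudes = np.column_stack([dG, dR])

    g, r, func_truth = simulate_functional_movie(
        cfg,
        n_synapses,
        amplitudes,
        noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        centres=centres_px,
    )

    lm_src = rng.uniform(0, centres_px.max(), (n_landmarks, 2))
    lm_dst = lm_src @ A.T + t

    truth = SceneGroundTruth(
        centres_px=centres_px,
        amplitudes=amplitudes,
        baselines=func_truth.baselines,
        responder=dR > 0,
        bg_centre=func_truth.bg_centre,
        centres_nm=centres_nm,
        colour1_labels=scene.colour1_labels,
        colour2_labels=scene.colour2_labels,
        colour2_ssd=scene.colour2_ssd,
        ssd_counts=scene.ssd_counts,
        ssd_points=scene.ssd_points,
        affine=(A, t),
        coupling=coupling,
        coupling_coeff=coupling_coeff,
    )
    return g, r, points, lm_src, lm_dst, truth
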