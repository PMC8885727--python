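"""Localisation post-processing: two-camera pairing, photon-ratio spectral
demixing, lateral drift correction by cross-correlation, and 2D rendering.

Spectral demixing assigns each single emitter to one of two spectrally
close fluorophores from the ratio rho = I_cam1/(I_cam1 + I_cam2) of its
intensities on the two cameras behind a long-pass dichroic.  The ratio
histogram is bimodal; a two-component Gaussian mixture with a posterior
rejection band converts it into per-record labels with an explicit bound on
crosstalk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture
from skimage.registration import phase_cross_correlation

from .errors import (
    ContractError,
    DemixingError,
    DriftEstimationError,
    EmptyResultError,
)

__all__ = [
    "DemixModel",
    "DriftTrajectory",
    "pair_detections",
    "compute_photon_ratio",
    "fit_demix_model",
    "classify",
    "estimate_drift",
    "apply_drift",
    "render",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# two-camera pairing


def pair_detections(
    cam1: pd.DataFrame,
    cam2: pd.DataFrame,
    tol: float = 97.0,
    frame_match: bool = True,
) -> pd.DataFrame:
    """Merge mutual nearest-neighbour detections from the two cameras.

    Both tables must be in a common coordinate frame (nm).  Records are
    paired when each is the other's nearest neighbour within ``tol`` nm
    (on the same frame when ``frame_match``); the pair inherits camera-1
    coordinates with both intensities filled.  Unpaired records are dropped
    and their counts logged.
    """
    if tol <= 0:
        raise ContractError(f"pairing tolerance must be > 0, got {tol}")
    if len(cam1) == 0 or len(cam2) == 0:
        log.info("pairing dropped %d cam1 and %d cam2 records (one table empty)",
                 len(cam1), len(cam2))
        from .io import empty_localizations

        return empty_localizations()

    groups1 = cam1.groupby("frame").indices if frame_match else {0: np.arange(len(cam1))}
    groups2 = cam2.groupby("frame").indices if frame_match else {0: np.arange(len(cam2))}
    pairs: list[tuple[int, int]] = []
    for key, idx1 in groups1.items():
        idx2 = groups2.get(key)
        if idx2 is None:
            continue
        p1 = cam1.iloc[idx1][["x", "y"]].to_numpy()
        p2 = cam2.iloc[idx2][["x", "y"]].to_numpy()
        t1, t2 = cKDTree(p1), cKDTree(p2)
        d12, j12 = t2.query(p1, distance_upper_bound=tol)
        d21, j21 = t1.query(p2, distance_upper_bound=tol)
        for a, (d, b) in enumerate(zip(d12, j12)):
            if np.isfinite(d) and b < len(p2) and j21[b] == a:
                pairs.append((idx1[a], idx2[b]))
    n_drop1 = len(cam1) - len(pairs)
    n_drop2 = len(cam2) - len(pairs)
    log.info("paired %d detections (dropped %d cam1, %d cam2)",
             len(pairs), n_drop1, n_drop2)
    if not pairs:
        from .io import empty_localizations

        return empty_localizations()
    i1 = [a for a, _ in pairs]
    i2 = [b for _, b in pairs]
    out = cam1.iloc[i1].reset_index(drop=True).copy()
    out["I_cam1"] = cam1["I_cam1"].to_numpy()[i1]
    out["I_cam2"] = cam2["I_cam2"].to_numpy()[i2]
    return out


# ---------------------------------------------------------------------------
# photon ratio and demixing


def compute_photon_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``ratio = I_cam1 / (I_cam1 + I_cam2)`` per record.

    Records with zero total intensity (or missing intensities) are flagged
    ``rejected`` with an undefined ratio.
    """
    out = table.copy()
    i1 = out["I_cam1"].to_numpy(dtype=float)
    i2 = out["I_cam2"].to_numpy(dtype=float)
    if np.isnan(i1).all() or np.isnan(i2).all():
        raise DemixingError(
            "camera intensities are absent: demixing requires I_cam1 and I_cam2"
        )
    if ((i1 < 0) | (i2 < 0)).any():
        raise ContractError("camera intensities must be non-negative")
    total = i1 + i2
    bad = ~(total > 0)
    ratio = np.full(len(out), np.nan)
    ratio[~bad] = i1[~bad] / total[~bad]
    out["ratio"] = ratio
    out.loc[bad, "fluor"] = "rejected"
    return out


@dataclass
class DemixModel:
    """Two-component 1D Gaussian mixture over the photon ratio.

    Component A is the high-ratio (camera-1-favouring) fluorophore.  A
    record is assigned only when its posterior exceeds ``threshold``;
    anything in between is rejected, bounding crosstalk explicitly.
    """

    mu_a: float
    mu_b: float
    sd_a: float
    sd_b: float
    weight_a: float
    threshold: float = 0.99

    def __post_init__(self) -> None:
        if not self.mu_b < self.mu_a:
            raise ContractError("component means must satisfy mu_B < mu_A")
        if not 0 < self.weight_a < 1:
            raise ContractError("mixing weight must be in (0, 1)")

    @property
    def weight_b(self) -> float:
        return 1.0 - self.weight_a

    def posterior_a(self, rho: np.ndarray) -> np.ndarray:
        """Posterior probability that each ratio came from component A."""
        rho = np.asarray(rho, dtype=float)
        pa = self.weight_a * _normal_pdf(rho, self.mu_a, self.sd_a)
        pb = self.weight_b * _normal_pdf(rho, self.mu_b, self.sd_b)
        with np.errstate(invalid="ignore"):
            return pa / (pa + pb)


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def fit_demix_model(ratios: np.ndarray, threshold: float = 0.99) -> DemixModel:
    """Fit the two-component ratio mixture.

    Raises :class:`DemixingError` when the fitted components are closer
    than twice their pooled standard deviation — a unimodal histogram
    cannot be demixed.
    """
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 100:
        raise ContractError(
            f"demixing needs >= 100 finite ratios, got {ratios.size}"
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=0,
        n_init=3,
        means_init=np.array([[0.3], [0.7]]),
    ).fit(ratios[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)[::-1]  # A = high ratio
    mu_a, mu_b = means[order]
    sd_a, sd_b = sds[order]
    w_a = weights[order][0]
    # a unimodal sample fitted with two components splits into means about
    # 1.5 pooled s.d. apart; genuine two-fluorophore data sits at >= 4.
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2)
    if mu_a - mu_b < 2.0 * pooled:
        raise DemixingError(
            f"degenerate mixture: component separation {mu_a - mu_b:.4f} is "
            f"below 2x the pooled s.d. {pooled:.4f} (unimodal ratio histogram)"
        )
    return DemixModel(mu_a, mu_b, sd_a, sd_b, w_a, threshold)


def classify(table: pd.DataFrame, model: DemixModel) -> pd.DataFrame:
    """Assign each record to fluorA/fluorB by mixture posterior.

    Records whose posterior for neither component reaches the model
    threshold are rejected (the crosstalk guard), as are records without a
    defined ratio.
    """
    out = table.copy()
    rho = out["ratio"].to_numpy(dtype=float)
    labels = np.full(len(out), "rejected", dtype=object)
    finite = np.isfinite(rho)
    post_a = model.posterior_a(rho[finite])
    lab = np.full(post_a.shape, "rejected", dtype=object)
    lab[post_a >= model.threshold] = "fluorA"
    lab[(1.0 - post_a) >= model.threshold] = "fluorB"
    labels[finite] = lab
    out["fluor"] = labels
    return out


# ---------------------------------------------------------------------------
# drift correction


@dataclass
class DriftTrajectory:
    """Lateral drift per frame bin, relative to the first bin.

    Interpolation between bin centres is linear; beyond the first/last
    centre the end segments are extended linearly, so a steady drift is
    corrected without leaving an uncompensated ramp in the edge bins.
    """

    bin_centres: np.ndarray   # frame of each bin centre
    dx: np.ndarray            # nm
    dy: np.ndarray            # nm

    def at(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        frames = np.asarray(frames, dtype=float)
        return (
            _interp_extrap(frames, self.bin_centres, self.dx),
            _interp_extrap(frames, self.bin_centres, self.dy),
        )


def _interp_extrap(t: np.ndarray, tp: np.ndarray, vp: np.ndarray) -> np.ndarray:
    out = np.interp(t, tp, vp)
    if len(tp) >= 2:
        lo = t < tp[0]
        hi = t > tp[-1]
        if lo.any():
            slope = (vp[1] - vp[0]) / (tp[1] - tp[0])
            out[lo] = vp[0] + slope * (t[lo] - tp[0])
        if hi.any():
            slope = (vp[-1] - vp[-2]) / (tp[-1] - tp[-2])
            out[hi] = vp[-1] + slope * (t[hi] - tp[-1])
    return out


def estimate_drift(
    table: pd.DataFrame,
    bin_frames: int = 2000,
    grid: float = 20.0,
    min_locs: int = 50,
    upsample: int = 10,
) -> DriftTrajectory:
    """Estimate lateral drift by phase cross-correlation of binned renders.

    The table is split into ``bin_frames``-frame bins; each bin is rendered
    as a 2D histogram on a ``grid`` nm grid and registered against the
    first bin with sub-pixel (x ``upsample``) phase correlation.  Bins with
    fewer than ``min_locs`` localisations are skipped and interpolated
    over.  Drift of the first bin is (0, 0) by convention.
    """
    frames = table["frame"].to_numpy()
    if len(table) == 0:
        raise ContractError("cannot estimate drift from an empty table")
    f0 = int(frames.min())
    n_bins = int((frames.max() - f0) // bin_frames) + 1
    if n_bins < 2:
        raise DriftEstimationError(
            f"table spans only {n_bins} bin(s) of {bin_frames} frames; "
            "drift estimation needs at least 2"
        )
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    # common render extent so every bin shares the same pixel grid
    pad = grid
    xe = np.arange(x.min() - pad, x.max() + pad + grid, grid)
    ye = np.arange(y.min() - pad, y.max() + pad + grid, grid)

    bin_idx = ((frames - f0) // bin_frames).astype(int)
    centres, dxs, dys = [], [], []
    ref = None
    for b in range(n_bins):
        sel = bin_idx == b
        centre = f0 + (b + 0.5) * bin_frames
        if sel.sum() < min_locs:
            log.warning("drift bin %d has %d < %d localisations; skipped",
                        b, int(sel.sum()), min_locs)
            continue
        img, _, _ = np.histogram2d(x[sel], y[sel], bins=(xe, ye))
        if ref is None:
            ref = img
            centres.append(centre)
            dxs.append(0.0)
            dys.append(0.0)
            continue
        shift, _, _ = phase_cross_correlation(
            ref, img, upsample_factor=upsample, normalization=None
        )
        # shift registers `img` onto `ref`; the drift is the opposite move
        dxs.append(-shift[0] * grid)
        dys.append(-shift[1] * grid)
        centres.append(centre)
    if len(centres) < 2:
        raise DriftEstimationError("fewer than 2 usable bins after skipping")
    return DriftTrajectory(np.asarray(centres), np.asarray(dxs), np.asarray(dys))


def apply_drift(table: pd.DataFrame, drift: DriftTrajectory) -> pd.DataFrame:
    """Shift x, y by the interpolated drift at each record's frame (z is
    untouched; only lateral drift is corrected)."""
    out = table.copy()
    dx, dy = drift.at(out["frame"].to_numpy())
    out["x"] = out["x"].to_numpy(dtype=float) - dx
    out["y"] = out["y"].to_numpy(dtype=float) - dy
    return out


# ---------------------------------------------------------------------------
# rendering


def render(
    table: pd.DataFrame,
    pixel: float = 10.0,
    fluor: str | None = None,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render localisations as a 2D count histogram.

    Returns ``(image, origin)`` in image convention — ``image[row, col]``
    counts localisations with ``origin[1] + row*pixel <= y`` and
    ``origin[0] + col*pixel <= x`` (origin is the (x, y) min corner).  The
    total count is conserved exactly.
    """
    if pixel <= 0:
        raise ContractError(f"pixel size must be > 0, got {pixel}")
    sel = table
    if fluor is not None:
        sel = table[table["fluor"] == fluor]
    if len(sel) == 0:
        raise EmptyResultError(
            "no localisations to render"
            + (f" after filtering for {fluor!r}" if fluor else "")
        )
    x = sel["x"].to_numpy(dtype=float)
    y = sel["y"].to_numpy(dtype=float)
    if origin is None:
        origin = (np.floor(x.min() / pixel) * pixel, np.floor(y.min() / pixel) * pixel)
    if shape is None:
        n_rows = int(np.floor((y.max() - origin[1]) / pixel)) + 1
        n_cols = int(np.floor((x.max() - origin[0]) / pixel)) + 1
        shape = (n_rows, n_cols)
    ye = origin[1] + np.arange(shape[0] + 1) * pixel
    xe = origin[0] + np.arange(shape[1] + 1) * pixel
    img, _, _ = np.histogram2d(y, x, bins=(ye, xe))
    return img, (float(origin[0]), float(origin[1]))
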