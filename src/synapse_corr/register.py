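"""Landmark affine registration between the live and dSTORM coordinate
frames, cross-modality synapse matching, and the correlation statistics
relating per-synapse structure to function.

Registration is 2D: the live movie's maximum projection and the rendered
super-resolution image share an image plane, and the dSTORM z coordinate is
used only for clustering.  The "manual selection of well-aligned synapses"
of interactive workflows is replaced by a deterministic ambiguity rule:
a live bouton whose second-nearest candidate cluster lies within 10% of
the nearest one's distance is excluded from matching.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .clusters import SynapseStructure
from .errors import ContractError, DegenerateGeometryError
from .io import FluorescenceMovie
from .traces import SynapseResponse

__all__ = [
    "AffineTransform2D",
    "CorrelatedSynapse",
    "StatResult",
    "max_projection",
    "fit_affine",
    "match_synapses",
    "spearman",
    "ks_two_sample",
    "summarise",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# registration


def max_projection(movie: FluorescenceMovie) -> np.ndarray:
    """Per-pixel maximum over frames."""
    if movie.n_frames < 1:
        raise ContractError("movie has no frames")
    return movie.data.max(axis=0)


@dataclass
class AffineTransform2D:
    """The live -> dSTORM map ``x -> A x + t`` estimated from landmarks."""

    A: np.ndarray                 # (2, 2)
    t: np.ndarray                 # (2,)
    rmse: float = 0.0             # nm, over the fitting landmarks
    n_landmarks: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.t = np.asarray(self.t, dtype=float).reshape(2)
        if np.linalg.det(self.A) == 0:
            raise ContractError("affine matrix must be invertible (det != 0)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.A.T + self.t

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.t, self.rmse, self.n_landmarks)


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform2D:
    """Least-squares affine fit from >= 3 non-collinear landmark pairs."""
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape:
        raise ContractError(
            f"landmark count mismatch: src {src.shape} vs dst {dst.shape}"
        )
    n = len(src)
    if n < 3:
        raise ContractError(f"affine fit needs >= 3 landmark pairs, got {n}")
    design = np.column_stack([src, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError(
            "landmarks are collinear or coincident; the affine fit is rank-deficient"
        )
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    A = coef[:2].T
    t = coef[2]
    resid = src @ A.T + t - dst
    # per-coordinate RMSE over the 2n residual components
    rmse = float(np.sqrt((resid**2).mean()))
    return AffineTransform2D(A, t, rmse, n)


# ---------------------------------------------------------------------------
# synapse matching


@dataclass
class CorrelatedSynapse:
    """A functional record joined to its structural record — the unit of
    every downstream statistic.  Only calcium responders are matched."""

    response: SynapseResponse
    structure: SynapseStructure
    match_distance: float
    live_index: int
    structure_index: int


def match_synapses(
    responses: list[SynapseResponse],
    live_xy: np.ndarray,
    structures: list[SynapseStructure],
    transform: AffineTransform2D,
    max_dist: float = 500.0,
    ambiguity: float = 0.1,
) -> list[CorrelatedSynapse]:
    """Greedy one-to-one matching of responder boutons to colour-1 clusters.

    ``live_xy`` holds each bouton's (x, y) position in live coordinates;
    it is mapped through ``transform`` and matched to the nearest colour-1
    cluster centroid within ``max_dist`` nm.  A bouton with two candidates
    within ``ambiguity`` (fractional) distance of each other is excluded and
    logged; matches are assigned greedily in order of increasing distance.
    """
    live_xy = np.atleast_2d(np.asarray(live_xy, dtype=float))
    if len(live_xy) != len(responses):
        raise ContractError("one live position per response is required")
    if not structures:
        return []
    centroids = np.array([s.cluster1.centroid[:2] for s in structures])

    candidates = []
    for i, resp in enumerate(responses):
        if not (resp.valid and resp.calcium_responder):
            continue
        mapped = transform.apply(live_xy[i])[0]
        d = np.linalg.norm(centroids - mapped, axis=1)
        order = np.argsort(d)
        if d[order[0]] > max_dist:
            continue
        if len(d) > 1 and d[order[1]] <= (1.0 + ambiguity) * d[order[0]]:
            log.info(
                "bouton %d excluded as ambiguous (candidates at %.0f and %.0f nm)",
                i, d[order[0]], d[order[1]],
            )
            continue
        candidates.append((float(d[order[0]]), i, int(order[0])))

    candidates.sort()
    used_live: set[int] = set()
    used_struct: set[int] = set()
    out: list[CorrelatedSynapse] = []
    for dist, i, j in candidates:
        if i in used_live or j in used_struct:
            continue
        used_live.add(i)
        used_struct.add(j)
        out.append(CorrelatedSynapse(responses[i], structures[j], dist, i, j))
    return out


# ---------------------------------------------------------------------------
# statistics


@dataclass
class StatResult:
    """A test statistic with its p-value and sample size(s)."""

    statistic: float
    p: float
    n: int | tuple[int, int]
    method: str


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks handle ties; r is the Pearson correlation of the ranks.  For
    n <= 10 the p-value is computed by exact enumeration of all n!
    permutations of one rank vector; above that, by the usual
    t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ContractError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ContractError(f"spearman needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("correlation undefined for a constant input")
    rx, ry = _rank(x), _rank(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, r)
        method = "spearman-exact"
    else:
        with np.errstate(divide="ignore"):
            t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        method = "spearman-t"
    return StatResult(r, p, n, method)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p: fraction of permutations of the y
    ranks with |r| >= |r_obs| (within numerical tolerance)."""
    n = rx.size
    mx, sx = rx.mean(), rx.std()
    my, sy = ry.mean(), ry.std()
    thresh = abs(r_obs) - 1e-12
    total = math.factorial(n)
    count = 0
    chunk: list[tuple] = []
    chunk_size = 100_000

    def flush(ch):
        perm = np.asarray(ch)
        rs = (perm @ rx / n - mx * my) / (sx * sy)
        return int((np.abs(rs) >= thresh).sum())

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def ks_two_sample(x, y) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test, asymptotic two-sided p-value.

    D is the supremum difference of the two empirical CDFs, evaluated over
    the pooled sample values.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ContractError("KS test needs at least 2 observations per sample")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = math.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return StatResult(d, p, (n, m), "ks-asymptotic")


# ---------------------------------------------------------------------------
# report


def summarise(
    correlated: list[CorrelatedSynapse],
    min_group: int = 3,
    include_empty_synapses: bool = False,
) -> dict:
    """Correlation/comparison report over matched synapses.

    Produces (i) Spearman of dG/R vs dR/R overall and within the single-
    vs multiple-SSD groups, (ii) a KS comparison of dG/dR between those
    groups, (iii) KS comparisons of total SSD detections and mean SSD
    density between releasing and non-releasing synapses, (iv) the SSD
    count distribution, and structure-function Spearman correlations of
    dG/R and dR/R against total SSD detections.  Groups below ``min_group``
    skip their comparison with a logged reason.  Synapses with no SSD are
    excluded unless ``include_empty_synapses``.

    No multiple-testing correction is applied; p-values are
    per-comparison.
    """
    recs = [c for c in correlated if include_empty_synapses or c.structure.n_ssd > 0]
    report: dict = {
        "n_matched": len(correlated),
        "n_analysed": len(recs),
        "comparisons": {},
        "skipped": {},
        "ssd_count_distribution": {},
        "footer": "p-values are per-comparison; no multiple-testing correction",
    }
    if not recs:
        return report

    dg_r = np.array([c.response.dG_over_R for c in recs])
    dr_r = np.array([c.response.dR_over_R for c in recs])
    dg_dr = np.array([c.response.dG_over_dR for c in recs])
    n_ssd = np.array([c.structure.n_ssd for c in recs])
    total_det = np.array([c.structure.total_ssd_detections for c in recs], dtype=float)
    mean_dens = np.array([c.structure.mean_ssd_density for c in recs])
    release = np.array([c.response.release_detected for c in recs])

    vals, counts = np.unique(n_ssd, return_counts=True)
    report["ssd_count_distribution"] = {int(v): int(c) for v, c in zip(vals, counts)}

    def add(name, fn, *arrays):
        ns = [len(a) for a in arrays]
        if any(v < min_group for v in ns):
            report["skipped"][name] = f"group sizes {ns} below minimum {min_group}"
            log.info("comparison %s skipped: %s", name, report["skipped"][name])
            return
        try:
            report["comparisons"][name] = fn(*arrays)
        except ContractError as exc:
            report["skipped"][name] = str(exc)
            log.info("comparison %s skipped: %s", name, exc)

    single = n_ssd == 1
    multi = n_ssd >= 2

    add("dG_R_vs_dR_R_all", spearman, dg_r, dr_r)
    add("dG_R_vs_dR_R_single_ssd", spearman, dg_r[single], dr_r[single])
    add("dG_R_vs_dR_R_multi_ssd", spearman, dg_r[multi], dr_r[multi])

    ok = np.isfinite(dg_dr)
    add("dG_dR_single_vs_multi_ssd", ks_two_sample,
        dg_dr[ok & single], dg_dr[ok & multi])

    add("ssd_detections_release_vs_none", ks_two_sample,
        total_det[release], total_det[~release])
    fin = np.isfinite(mean_dens)
    add("ssd_density_release_vs_none", ks_two_sample,
        mean_dens[fin & release], mean_dens[fin & ~release])

    add("dG_R_vs_ssd_detections", spearman, dg_r, total_det)
    add("dR_R_vs_ssd_detections", spearman, dr_r, total_det)
    return report
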