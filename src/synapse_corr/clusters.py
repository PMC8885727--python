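"""Voronoi density-based cluster segmentation and two-colour
colocalisation of 3D localisation point clouds.

Per-point density is the inverse volume of the point's 3D Voronoi cell
(points with unbounded cells get zero density and are excluded from the
dataset mean).  Segmentation keeps points whose density reaches a multiple
of the dataset mean, links kept points within a colour-specific neighbour
distance, and accepts connected components above a colour-specific minimum
size.  Colocalisation associates each colour-2 cluster (a subsynaptic
domain, SSD) with a colour-1 cluster (the vesicle-pool bouton marker) by
point-in-hull overlap, with a distance-bounded orphan-assignment fallback
replacing the manual curation step of interactive workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi, cKDTree

from .config import PipelineConfig
from .errors import ContractError, DegenerateGeometryError

__all__ = [
    "VoronoiDensityMap",
    "Cluster",
    "SynapseStructure",
    "voronoi_density",
    "segment_clusters",
    "cluster_metrics",
    "colocalise",
]

log = logging.getLogger(__name__)


@dataclass
class VoronoiDensityMap:
    """Per-point Voronoi densities (nm^-3) and the dataset average.

    ``mean_density`` (delta_d) is the global density of the dataset —
    point count divided by the volume of the data's convex hull — which is
    what cluster segmentation thresholds against: cluster points sit far
    above it, diffuse background far below.
    ``mean_cell_density`` is the arithmetic mean of the per-point densities
    (a much larger number, dominated by cluster cores), reported for
    diagnostics.  Points whose Voronoi cell is unbounded carry density 0
    and are excluded from both averages.
    """

    density: np.ndarray       # delta_i per point, 0 for unbounded cells
    finite: np.ndarray        # bool mask of bounded cells
    mean_density: float       # delta_d: n_finite / sum of finite cell volumes
    mean_cell_density: float  # arithmetic mean of delta_i over finite cells

    @property
    def n_points(self) -> int:
        return self.density.size


@dataclass
class Cluster:
    """A segmented cluster of one colour."""

    colour: int
    members: np.ndarray       # indices into the colour's point array
    n_detections: int = 0
    volume: float = float("nan")     # convex hull, nm^3
    density: float = float("nan")    # n_detections / volume, nm^-3
    centroid: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        self.n_detections = int(self.members.size)


@dataclass
class SynapseStructure:
    """A colour-1 cluster with its associated colour-2 SSDs."""

    synapse_id: int
    cluster1: Cluster
    ssds: list[Cluster] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)   # "overlap" | "orphan-assigned"

    @property
    def n_ssd(self) -> int:
        return len(self.ssds)

    @property
    def total_ssd_detections(self) -> int:
        return int(sum(c.n_detections for c in self.ssds))

    @property
    def mean_ssd_density(self) -> float:
        dens = [c.density for c in self.ssds if np.isfinite(c.density)]
        return float(np.mean(dens)) if dens else float("nan")


# ---------------------------------------------------------------------------
# Voronoi density


def voronoi_density(
    points: np.ndarray, first_rank_average: bool = True
) -> VoronoiDensityMap:
    """Per-point first-rank Voronoi density.

    The raw density of a point is the inverse volume of its 3D Voronoi
    cell (0 for unbounded cells).  By default the reported density is the
    first-rank average — the mean of the raw density over the point and
    its natural (Delaunay) neighbours with bounded cells — which gives
    boundary-shell points of a cluster a meaningful density instead of 0
    and damps single-cell volume noise.  Pass ``first_rank_average=False``
    for the raw inverse cell volume.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ContractError(f"points must be (n, 3), got shape {points.shape}")
    n = len(points)
    if n < 5:
        raise ContractError(f"Voronoi density needs >= 5 points, got {n}")
    try:
        vor = Voronoi(points)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"degenerate point configuration (coplanar or coincident): {exc}"
        ) from exc

    # cells reaching beyond the data's convex hull (or to infinity) are
    # boundary cells: their size is an artefact of where the data stops,
    # not a density estimate, so they get zero density and are excluded
    # from the dataset average.  The hull test keeps everything invariant
    # under rigid motions.
    try:
        data_hull = Delaunay(points)
        coverage_volume = float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"degenerate point configuration: {exc}"
        ) from exc
    vertex_inside = data_hull.find_simplex(vor.vertices) >= 0
    density = np.zeros(n)
    volumes = np.zeros(n)
    finite = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region or not vertex_inside[region].all():
            continue
        verts = vor.vertices[region]
        try:
            vol = ConvexHull(verts).volume
        except QhullError:
            continue
        if vol > 0:
            density[i] = 1.0 / vol
            volumes[i] = vol
            finite[i] = True
    if not finite.any():
        raise DegenerateGeometryError("no bounded Voronoi cells")

    if first_rank_average:
        neigh: list[list[int]] = [[] for _ in range(n)]
        for a, b in vor.ridge_points:
            neigh[a].append(b)
            neigh[b].append(a)
        averaged = np.zeros(n)
        for i in range(n):
            vals = [density[j] for j in ([i] + neigh[i]) if finite[j]]
            if vals:
                averaged[i] = float(np.mean(vals))
        density = averaged

    return VoronoiDensityMap(
        density=density,
        finite=finite,
        mean_density=float(n / coverage_volume),
        mean_cell_density=float(density[finite].mean()),
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_clusters(
    points: np.ndarray,
    density_map: VoronoiDensityMap,
    colour: int,
    cfg: PipelineConfig,
) -> list[Cluster]:
    """Density-threshold + neighbour-linkage segmentation for one colour.

    Keeps points with ``delta_i >= density_factor * delta_d``, links kept
    points within the colour's maximum neighbour distance, and returns
    connected components with at least the colour's minimum number of
    molecules, with metrics computed.  An empty result is valid.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return []
    if density_map.n_points != len(points):
        raise ContractError("density map was computed on a different point set")
    keep = np.flatnonzero(
        density_map.density >= cfg.density_factor * density_map.mean_density
    )
    if keep.size == 0:
        return []
    kept = points[keep]
    tree = cKDTree(kept)
    pairs = tree.query_pairs(r=cfg.neighbour_dist(colour), output_type="ndarray")
    m = keep.size
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = keep[labels == comp]
        if members.size >= cfg.min_mol(colour):
            clusters.append(cluster_metrics(Cluster(colour, members), points))
    # deterministic order: by first member index
    clusters.sort(key=lambda c: int(c.members.min()))
    return clusters


def cluster_metrics(cluster: Cluster, points: np.ndarray) -> Cluster:
    """Fill convex-hull volume, density and centroid for a cluster.

    Fewer than 4 points, or any coplanar/collinear configuration, marks the
    cluster degenerate with undefined volume and density.
    """
    points = np.asarray(points, dtype=float)
    if cluster.members.size and (
        cluster.members.min() < 0 or cluster.members.max() >= len(points)
    ):
        raise ContractError("cluster membership indices out of range")
    pts = points[cluster.members]
    cluster.centroid = pts.mean(axis=0) if len(pts) else None
    if len(pts) < 4:
        cluster.degenerate = True
        cluster.volume = float("nan")
        cluster.density = float("nan")
        return cluster
    try:
        hull = ConvexHull(pts)
    except QhullError:
        cluster.degenerate = True
        cluster.volume = float("nan")
        cluster.density = float("nan")
        return cluster
    cluster.degenerate = False
    cluster.volume = float(hull.volume)
    cluster.density = cluster.n_detections / cluster.volume
    return cluster


# ---------------------------------------------------------------------------
# colocalisation


def colocalise(
    clusters1: list[Cluster],
    clusters2: list[Cluster],
    points1: np.ndarray,
    points2: np.ndarray,
    orphan_dist: float = 500.0,
) -> tuple[list[SynapseStructure], list[Cluster]]:
    """Associate colour-2 SSDs with colour-1 synapse clusters.

    An SSD overlaps a synapse when any of its points lies inside the
    colour-1 cluster's convex hull (provenance ``overlap``).  SSDs that
    overlap nothing are assigned to the nearest colour-1 centroid within
    ``orphan_dist`` nm (provenance ``orphan-assigned``) — the automated
    stand-in for manual curation of missed colocalisations.  SSDs farther
    than that are returned unassigned.  Synapses with zero SSDs are kept
    (downstream analyses may exclude them).
    """
    points1 = np.asarray(points1, dtype=float)
    points2 = np.asarray(points2, dtype=float)
    structures = [SynapseStructure(i, c1) for i, c1 in enumerate(clusters1)]
    if not clusters1:
        return [], list(clusters2)

    hulls = []
    for c1 in clusters1:
        try:
            hulls.append(Delaunay(points1[c1.members]))
        except QhullError:
            hulls.append(None)
    centroids = np.array([c.centroid[:3] for c in clusters1])

    unassigned: list[Cluster] = []
    for ssd in clusters2:
        pts = points2[ssd.members]
        target, prov = None, None
        for i, tri in enumerate(hulls):
            if tri is not None and (tri.find_simplex(pts) >= 0).any():
                target, prov = i, "overlap"
                break
        if target is None:
            d = np.linalg.norm(centroids - ssd.centroid, axis=1)
            j = int(np.argmin(d))
            if d[j] <= orphan_dist:
                target, prov = j, "orphan-assigned"
        if target is None:
            unassigned.append(ssd)
            log.info(
                "SSD with %d detections unassigned (nearest synapse %.0f nm away)",
                ssd.n_detections,
                float(np.linalg.norm(centroids - ssd.centroid, axis=1).min()),
            )
        else:
            structures[target].ssds.append(ssd)
            structures[target].provenance.append(prov)
    return structures, unassigned
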