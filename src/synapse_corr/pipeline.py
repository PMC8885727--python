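"""End-to-end orchestration: run the full correlative chain on in-memory
inputs.  Thin glue over the stage modules, used by the CLI and by
whole-pipeline evaluations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clusters import (
    SynapseStructure,
    colocalise,
    segment_clusters,
    voronoi_density,
)
from .config import PipelineConfig
from .io import FluorescenceMovie
from .register import (
    AffineTransform2D,
    CorrelatedSynapse,
    fit_affine,
    match_synapses,
    summarise,
)
from .traces import SynapseResponse, analyse_response, extract_traces

__all__ = ["segment_scene", "run_correlative_pipeline", "PipelineResult"]


def segment_scene(
    points: dict[int, np.ndarray], cfg: PipelineConfig
) -> tuple[list[SynapseStructure], list]:
    """Voronoi-density segmentation of both colours plus colocalisation.

    Returns the per-synapse structures and the unassigned colour-2
    clusters.
    """
    clusters = {}
    for colour in (1, 2):
        dmap = voronoi_density(points[colour])
        clusters[colour] = segment_clusters(points[colour], dmap, colour, cfg)
    return colocalise(
        clusters[1], clusters[2], points[1], points[2], orphan_dist=cfg.match_dist
    )


@dataclass
class PipelineResult:
    responses: list[SynapseResponse]
    structures: list[SynapseStructure]
    transform: AffineTransform2D
    correlated: list[CorrelatedSynapse]
    report: dict


def run_correlative_pipeline(
    g_movie: FluorescenceMovie,
    r_movie: FluorescenceMovie,
    points: dict[int, np.ndarray],
    landmarks_src: np.ndarray,
    landmarks_dst: np.ndarray,
    roi_centres: np.ndarray,
    cfg: PipelineConfig,
    bg_centre: tuple[int, int] | None = None,
) -> PipelineResult:
    """Traces -> responses, scene -> structures, registration -> matching
    -> statistics report.

    ``roi_centres`` are (row, col) live-pixel bouton positions; matching
    maps their (x, y) = (col, row) coordinates through the fitted
    transform.
    """
    traces = extract_traces(g_movie, r_movie, roi_centres, cfg, bg_centre=bg_centre)
    responses = analyse_response(traces, cfg)
    structures, _ = segment_scene(points, cfg)
    transform = fit_affine(landmarks_src, landmarks_dst)
    live_xy = np.asarray(roi_centres, dtype=float)[:, ::-1]
    correlated = match_synapses(
        responses, live_xy, structures, transform, max_dist=cfg.match_dist
    )
    report = summarise(correlated)
    return PipelineResult(responses, structures, transform, correlated, report)
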