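"""Reading and writing the formats the pipeline touches.

Localisation tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``x, y, z`` (nm), ``frame`` (0-based index), ``I_cam1,
I_cam2`` (photons), ``ratio`` (the demixing statistic) and ``fluor`` (one of
``unassigned``, ``fluorA``, ``fluorB``, ``rejected``).  Movies are thin
dataclasses around a ``frame x row x col`` array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig
from .errors import ContractError, FormatError, ParseError

__all__ = [
    "LOC_COLUMNS",
    "FLUOR_LABELS",
    "FluorescenceMovie",
    "empty_localizations",
    "make_localizations",
    "read_localizations",
    "write_localizations",
    "read_image_stack",
    "write_image",
    "read_image",
]

#: Canonical localisation-table columns, in storage order.
LOC_COLUMNS = ("x", "y", "z", "frame", "I_cam1", "I_cam2", "ratio", "fluor")

#: Valid fluorophore assignment labels.
FLUOR_LABELS = ("unassigned", "fluorA", "fluorB", "rejected")

#: Default mapping from canonical column names to CSV header names.
DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in LOC_COLUMNS}

_NUMERIC_COLUMNS = ("x", "y", "z", "frame", "I_cam1", "I_cam2", "ratio")
_MANDATORY = ("x", "y", "frame")


@dataclass
class FluorescenceMovie:
    """A single-channel fluorescence time-lapse.

    ``data`` is a ``(n_frames, n_rows, n_cols)`` array in arbitrary camera
    units; ``channel`` is ``"G"`` (SypHy) or ``"R"`` (RGECO).
    """

    data: np.ndarray
    channel: str = "G"
    pixel_size: float = 433.0
    frame_rate: float = 12.5
    stim_frame: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ContractError(
                f"movie data must be frame x row x col, got shape {self.data.shape}"
            )
        if self.channel not in ("G", "R"):
            raise ContractError(f"channel must be 'G' or 'R', got {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def validate_time_series(self, cfg: PipelineConfig) -> None:
        """Check the movie can carry a stimulus-locked analysis."""
        if self.n_frames < 2:
            raise ContractError("time-series analysis needs at least 2 frames")
        stim = self.stim_frame
        if stim is None:
            raise ContractError("movie has no stimulus frame set")
        if not (cfg.baseline_frames <= stim < self.n_frames - cfg.peak_window):
            raise ContractError(
                f"stim_frame {stim} must lie in [{cfg.baseline_frames}, "
                f"{self.n_frames - cfg.peak_window})"
            )


# ---------------------------------------------------------------------------
# localisation tables


def empty_localizations() -> pd.DataFrame:
    """An empty table with the canonical columns and dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in _NUMERIC_COLUMNS})
    df["frame"] = df["frame"].astype(int)
    df["fluor"] = pd.Series(dtype=object)
    return df[list(LOC_COLUMNS)]


def make_localizations(
    x,
    y,
    z=None,
    frame=None,
    I_cam1=None,
    I_cam2=None,
) -> pd.DataFrame:
    """Build a canonical table from coordinate arrays (nm)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    def _col(v, fill):
        if v is None:
            return np.full(n, fill, dtype=float)
        v = np.asarray(v, dtype=float)
        if v.size != n:
            raise ContractError("all localisation columns must have equal length")
        return v

    df = pd.DataFrame(
        {
            "x": x,
            "y": _col(y, 0.0),
            "z": _col(z, 0.0),
            "frame": _col(frame, 0.0).astype(int),
            "I_cam1": _col(I_cam1, np.nan),
            "I_cam2": _col(I_cam2, np.nan),
            "ratio": np.full(n, np.nan),
            "fluor": np.full(n, "unassigned", dtype=object),
        }
    )
    return df


def read_localizations(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a localisation CSV into the canonical table.

    ``dialect`` maps canonical column names to the file's header names; any
    canonical column not mentioned falls back to its own name.  ``x``, ``y``
    and ``frame`` must be resolvable; ``z`` defaults to 0 and missing camera
    intensities leave ``ratio`` undefined and ``fluor`` unassigned.

    Row order is preserved exactly.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for canon in _MANDATORY:
        if names[canon] not in raw.columns:
            raise FormatError(
                f"mandatory column {canon!r} (file column {names[canon]!r}) "
                f"not found in {path}"
            )
    n = len(raw)
    out = empty_localizations() if n == 0 else None
    if out is not None:
        return out

    data = {}
    for canon in _NUMERIC_COLUMNS:
        col = names[canon]
        if col not in raw.columns:
            data[canon] = np.full(n, 0.0 if canon == "z" else np.nan)
            continue
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        data[canon] = parsed.to_numpy(dtype=float)
    df = pd.DataFrame(data)
    df["frame"] = df["frame"].astype(int)
    fluor_col = names["fluor"]
    if fluor_col in raw.columns:
        fluor = raw[fluor_col].fillna("unassigned").astype(str)
        unknown = set(fluor) - set(FLUOR_LABELS)
        if unknown:
            raise FormatError(f"unknown fluorophore labels {sorted(unknown)} in {path}")
        df["fluor"] = fluor.to_numpy(dtype=object)
    else:
        df["fluor"] = "unassigned"
    return df[list(LOC_COLUMNS)]


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical table as CSV (header always present, full precision)."""
    missing = [c for c in LOC_COLUMNS if c not in table.columns]
    if missing:
        raise ContractError(f"table is missing canonical columns {missing}")
    table[list(LOC_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# image stacks

_PIXEL_KEY = "pixel_size_nm"


def read_image_stack(
    path: str | Path,
    channel: str = "G",
    cfg: PipelineConfig | None = None,
    stim_frame: int | None = None,
) -> FluorescenceMovie:
    """Read a multi-page TIFF as a movie, attaching metadata from ``cfg``."""
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent page shapes {sorted(shapes)} in {path}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D page stack, got shape {data.shape}")
    cfg = cfg or PipelineConfig()
    return FluorescenceMovie(
        data=data,
        channel=channel,
        pixel_size=cfg.live_pixel_size,
        frame_rate=cfg.live_frame_rate,
        stim_frame=cfg.stim_frame if stim_frame is None else stim_frame,
    )


def write_image(image: np.ndarray, path: str | Path, pixel_size: float) -> None:
    """Write a 2D image (or frame stack fed page-wise) with its pixel size.

    The physical pixel size is recorded in the TIFF description so that a
    rendered super-resolution image is self-describing.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ContractError(f"write_image expects a 2D array, got shape {image.shape}")
    tifffile.imwrite(path, image, description=json.dumps({_PIXEL_KEY: pixel_size}))


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a single 2D TIFF, returning the array and recorded pixel size."""
    with tifffile.TiffFile(path) as tif:
        data = tif.pages[0].asarray()
        pixel = None
        desc = tif.pages[0].description
        if desc:
            try:
                pixel = json.loads(desc).get(_PIXEL_KEY)
            except (json.JSONDecodeError, AttributeError):
                pixel = None
    return data, pixel


def write_movie(movie: FluorescenceMovie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF."""
    tifffile.imwrite(path, movie.data)
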