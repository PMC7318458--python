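"""Raster and table I/O plus validated run configuration.

Rasters are stored single-band float32 with nodata -9999, either as ESRI
ASCII grids (the default, human-readable) or TIFF. Indexing is 0-based,
row-major, with row 0 the top row; in memory nodata cells are NaN.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "NODATA",
    "read_raster",
    "write_raster",
    "RunConfig",
    "load_config",
    "dump_config",
]

NODATA = -9999.0
_GDAL_NODATA_TAG = 42113


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    if path.suffix.lower() in (".tif", ".tiff"):
        return "geotiff"
    return "ascii"


def write_raster(
    raster: np.ndarray,
    path: str | Path,
    grid: GridSpec | None = None,
    dialect: str | None = None,
) -> Path:
    """Write a raster as float32 with nodata -9999.

    NaN cells become nodata; NaN on a cell marked valid in ``grid`` is an
    error. The ASCII dialect uses a canonical header and ``%.9g`` value
    formatting, so rewriting the same raster gives byte-identical files.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    arr = np.asarray(raster, dtype=np.float64)
    if grid is not None:
        if arr.shape != grid.shape:
            raise ValueError("raster shape does not match grid")
        bad = grid.valid_mask & ~np.isfinite(arr)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} valid cells hold non-finite values")
    out = np.where(np.isfinite(arr), arr, NODATA).astype(np.float32)
    cell = grid.cell_size if grid is not None else 1.0
    if dialect == "ascii":
        lines = [
            f"ncols {arr.shape[1]}",
            f"nrows {arr.shape[0]}",
            "xllcorner 0",
            "yllcorner 0",
            f"cellsize {cell:g}",
            f"NODATA_value {NODATA:g}",
        ]
        for row in out:
            lines.append(" ".join(f"{v:.9g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "geotiff":
        import tifffile

        tifffile.imwrite(
            path,
            out,
            extratags=[(_GDAL_NODATA_TAG, "s", 0, f"{NODATA:g}", True)],
        )
    else:
        raise ValueError(f"unknown raster dialect {dialect!r}")
    return path


def read_raster(
    path: str | Path, dialect: str | None = None
) -> tuple[np.ndarray, GridSpec]:
    """Read a raster; nodata cells become NaN and define the invalid mask."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "ascii":
        with open(path) as fh:
            header: dict[str, float] = {}
            pos = fh.tell()
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
                pos = fh.tell()
            fh.seek(pos)
            data = np.loadtxt(fh, dtype=np.float64)
        # disk format is float32: quantise so round-trips are exact
        data = np.atleast_2d(data).astype(np.float32).astype(np.float64)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"{path}: data shape does not match header")
        nodata = header.get("nodata_value", NODATA)
        cell = header.get("cellsize", 1.0)
    elif dialect == "geotiff":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(np.float64)
            tag = page.tags.get(_GDAL_NODATA_TAG)
            nodata = float(tag.value) if tag is not None else NODATA
        cell = 1.0
    else:
        raise ValueError(f"unknown raster dialect {dialect!r}")
    mask = ~np.isclose(data, nodata)
    data = np.where(mask, data, np.nan)
    grid = GridSpec(data.shape[0], data.shape[1], cell_size=cell, valid_mask=mask)
    return data, grid


def read_raster_dir(
    directory: str | Path, dialect: str | None = None
) -> tuple[dict[str, np.ndarray], GridSpec]:
    """Read every raster in a directory, keyed by file stem, on one grid."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".asc", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no rasters in {directory}")
    rasters: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    for p in paths:
        arr, g = read_raster(p, dialect)
        if grid is None:
            grid = g
        elif g.shape != grid.shape:
            raise ValueError(f"{p}: raster dimensions differ from the first raster")
        rasters[p.stem] = arr
    return rasters, grid


# --------------------------------------------------------------------------
# run configuration


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_StrictModel):
    nrows: int = Field(40, ge=2)
    ncols: int = Field(40, ge=2)
    cell_size: float = Field(1.0, gt=0)


class SimulateConfig(_StrictModel):
    n_env: int = Field(3, ge=1)
    smoothness: float = Field(5.0, ge=0)
    n_roads: int = Field(3, ge=0)
    n_cities: int = Field(5, ge=0)
    n_pas: int = Field(4, ge=0)
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"butterfly": 8, "reptile": 8, "mammal": 8}
    )
    effect_sd: float = Field(0.8, ge=0)
    bias_strength: float = Field(0.3, ge=0)
    n_records: int | None = Field(None, ge=1)
    pa_fraction: float = Field(0.146, ge=0, lt=1)
    urban_fraction: float = Field(0.05, ge=0, lt=1)

    @model_validator(mode="after")
    def _fractions(self) -> "SimulateConfig":
        if self.pa_fraction + self.urban_fraction >= 1:
            raise ValueError("pa_fraction + urban_fraction must be < 1")
        return self


class SdmConfig(_StrictModel):
    block_size: int = Field(5, ge=1)
    k: int = Field(5, ge=2)
    algorithm: str = Field("A", pattern="^[AB]$")
    bias_correct: bool = True
    min_pixels: int = Field(8, ge=1)
    min_blocks: int = Field(5, ge=1)


class PrioritiseConfig(_StrictModel):
    rule: str = Field("caz", pattern="^(caz|abf)$")
    curve: str = Field("none", pattern="^(none|low|medium|high)$")
    radius: int = Field(0, ge=0, le=3)
    weighting: str = Field("none", pattern="^(none|redlist|consistency|both)$")
    warp: int = Field(1, ge=1)
    z: float = Field(0.25, gt=0, le=1)


class GapConfig(_StrictModel):
    bin_width: float = Field(0.01, gt=0, le=0.5)
    target_fraction: float = Field(0.17, gt=0, le=1)


class SensitivityConfig(_StrictModel):
    scale: str = Field("toy", pattern="^(toy|small|paper)$")
    warp: int = Field(10, ge=1)
    top_fractions: list[float] = Field(default_factory=lambda: [0.10, 0.17, 0.25])
    n_trees: int = Field(500, ge=10)
    n_perm: int = Field(10, ge=2)


class RunConfig(_StrictModel):
    """Validated parameters for every pipeline stage plus globals."""

    seed: int = 0
    out_dir: str = "out"
    dialect: str = Field("ascii", pattern="^(ascii|geotiff)$")
    grid: GridConfig = Field(default_factory=GridConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    sdm: SdmConfig = Field(default_factory=SdmConfig)
    prioritise: PrioritiseConfig = Field(default_factory=PrioritiseConfig)
    gap: GapConfig = Field(default_factory=GapConfig)
    sensitivity: SensitivityConfig = Field(default_factory=SensitivityConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)
    logger.info("effective configuration: %s", cfg.model_dump())
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the effective (defaults-filled) configuration next to outputs."""
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
    return path


def write_presences(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records[["species_id", "row", "col"]].to_csv(path, index=False)
    return path


def read_presences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species_id", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"presence table must have columns {sorted(required)}")
    return df
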