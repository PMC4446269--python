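"""On-disk artifacts: multi-page TIFF volumes with JSON sidecar metadata,
CSV tables, and JSON/YAML configs, with round-trip guarantees.

Volumes are stored page-per-z-slice in a 16-bit (or 8-bit) container; the
voxel size travels in a ``<stem>.meta.json`` sidecar because plain TIFF tags
for z-spacing are unreliable across dialects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, FormatError, SchemaError

__all__ = [
    "VolumeMeta",
    "config_hash",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "load_config",
    "validate_physical_sizes",
    "TRUTH_COLUMNS",
    "write_cohort",
]

TRUTH_COLUMNS = ["animal", "group", "x_um", "y_um", "z_um", "diameter_um",
                 "object_type", "cube_id"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class VolumeMeta:
    """Sidecar metadata for a stored volume."""

    voxel_size_um: tuple = (2.0, 2.0, 2.0)
    bit_depth: int = 12
    axis_order: str = "zyx"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel sizes must be positive")
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ConfigurationError("axis_order must be a permutation of zyx")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMeta":
        return cls(voxel_size_um=tuple(d["voxel_size_um"]),
                   bit_depth=int(d["bit_depth"]),
                   axis_order=d.get("axis_order", "zyx"),
                   provenance=d.get("provenance", {}))


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_volume(grid: np.ndarray, meta: VolumeMeta, path) -> None:
    """Write a (z, y, x) integer volume as a multi-page TIFF plus sidecar."""
    path = Path(path)
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise FormatError("volume must be 3-dimensional (z, y, x)")
    tifffile.imwrite(path, grid, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(meta.to_dict(), indent=2, sort_keys=True))


def read_volume(path):
    """Read a multi-page TIFF volume and its sidecar metadata.

    Raises :class:`FormatError` when the stack's pages disagree in shape or
    the ``<stem>.meta.json`` sidecar (voxel size metadata) is missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise FormatError(
                f"{path.name}: pages have inconsistent shapes {sorted(shapes)}")
        grid = tif.asarray()
    if grid.ndim == 2:
        grid = grid[None, ...]
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(
            f"{path.name}: missing voxel-size metadata; provide a sidecar "
            f"config at {side.name} with voxel_size_um and bit_depth")
    meta = VolumeMeta.from_dict(json.loads(side.read_text()))
    return grid, meta


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as RFC 4180 CSV (header row, UTF-8, '.' decimal)."""
    pd.DataFrame(df).to_csv(path, index=False, encoding="utf-8")


def read_table(path, expected_columns: Optional[Sequence[str]] = None
               ) -> pd.DataFrame:
    """Read a CSV table, optionally validating its column set.

    Unknown or missing columns raise :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    if expected_columns is not None:
        expected = list(expected_columns)
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        if unknown or missing:
            raise SchemaError(
                f"{path.name}: unknown columns {unknown}, missing {missing}")
        df = df[expected]
    return df


def validate_physical_sizes(config: dict, _path="") -> None:
    """Reject any negative physical size anywhere in a (nested) config."""
    for key, value in config.items():
        where = f"{_path}.{key}" if _path else key
        if isinstance(value, dict):
            validate_physical_sizes(value, where)
        elif any(key.endswith(suf) for suf in ("_um", "_mm", "_um3", "_mm3",
                                               "_per_mm", "size_um")):
            vals = value if isinstance(value, (list, tuple)) else [value]
            for v in vals:
                if v is not None and float(v) < 0:
                    raise ConfigurationError(f"negative physical size at {where}: {v}")


def load_config(path) -> dict:
    """Load and validate a JSON or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path.name}: config must be a mapping")
    validate_physical_sizes(cfg)
    return cfg


def write_cohort(scenes, outdir, config_echo: Optional[dict] = None) -> dict:
    """Write a generated cohort: one TIFF stack and cortex mask per animal,
    a combined truth.csv and cubes.csv, and the config echoed as JSON.

    Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"volumes": {}, "cortex": {}}
    truths = []
    cube_rows = []
    for scene in scenes:
        meta = VolumeMeta(
            voxel_size_um=tuple(scene.config.voxel_size_um),
            bit_depth=scene.config.bit_depth,
            provenance={"config_hash": config_hash(config_echo or {}),
                        "seed": scene.truth.rng_seed})
        vol_path = outdir / f"{scene.animal_id}.tif"
        write_volume(scene.volume, meta, vol_path)
        manifest["volumes"][scene.animal_id] = str(vol_path)
        cortex_path = outdir / f"cortex_{scene.animal_id}.tif"
        write_volume(scene.cortex_mask.astype(np.uint8), meta, cortex_path)
        manifest["cortex"][scene.animal_id] = str(cortex_path)
        truths.append(scene.truth.plaques)
        if scene.cubes is not None:
            for cube in scene.cubes:
                cube_rows.append({
                    "animal": scene.animal_id, "group": scene.group,
                    "cube_id": cube.id, "hemisphere": cube.hemisphere,
                    "origin_z_um": cube.origin_um[0],
                    "origin_y_um": cube.origin_um[1],
                    "origin_x_um": cube.origin_um[2],
                    "edge_um": cube.edge_um})
    truths = [t for t in truths if not t.empty]
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=TRUTH_COLUMNS))
    write_table(truth[TRUTH_COLUMNS], outdir / "truth.csv")
    manifest["truth"] = str(outdir / "truth.csv")
    if cube_rows:
        write_table(pd.DataFrame(cube_rows), outdir / "cubes.csv")
        manifest["cubes"] = str(outdir / "cubes.csv")
    if config_echo is not None:
        (outdir / "config.json").write_text(
            json.dumps(config_echo, indent=2, sort_keys=True, default=str))
        manifest["config"] = str(outdir / "config.json")
    return manifest
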