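"""File round-tripping: multi-page TIFF stacks/volumes with YAML sidecars,
run configuration parsing, and the metric report table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .atv import ATVParams
from .backprojector import Volume
from .geometry import ConeBeamGeometry
from .nltv import NLTVParams
from .projections import ProjectionStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "load_config",
    "nltv_params_from_config",
    "atv_params_from_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(path, stack: ProjectionStack) -> None:
    """Projection stack as 32-bit float multi-page TIFF + YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(stack.values, dtype=np.float32), photometric="minisblack")
    meta = {
        "kind": "projection_stack",
        "domain": stack.domain,
        "filtered": bool(stack.filtered),
        "geometry": stack.geometry.to_dict(),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stack(path) -> ProjectionStack:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(_sidecar(path).read_text())
    geom = ConeBeamGeometry.from_dict(meta["geometry"])
    if values.ndim == 2:
        values = values[None]
    return ProjectionStack(values, geom, domain=meta["domain"], filtered=meta.get("filtered", False))


def write_volume(path, vol: Volume) -> None:
    """Volume as 32-bit float multi-page TIFF + YAML sidecar with voxel size."""
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(vol.values, dtype=np.float32), photometric="minisblack")
    meta = {
        "kind": "volume",
        "shape_zyx": list(vol.shape),
        "voxel_size_mm_zyx": [float(v) for v in vol.voxel_size],
        "units": "mm^-1",
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_volume(path) -> Volume:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(_sidecar(path).read_text())
    return Volume(values, tuple(meta["voxel_size_mm_zyx"]))


def load_config(path) -> dict:
    """Single YAML config file driving all subcommands."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def nltv_params_from_config(block: dict | None) -> NLTVParams:
    return NLTVParams(**(block or {}))


def atv_params_from_config(block: dict | None) -> ATVParams:
    return ATVParams(**(block or {}))
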