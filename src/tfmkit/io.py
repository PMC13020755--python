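"""File formats and run configuration.

Images, masks and field rasters travel as TIFF (vector fields as
2-channel float32 with a JSON description carrying spacing/units);
tabular outputs as CSV with a provenance header line; configuration as
YAML that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .displacement import FlowParams
from .fields import ElasticSubstrate, VectorField2D

__all__ = [
    "load_stack",
    "save_stack",
    "load_field",
    "save_field",
    "write_csv",
    "RunConfig",
]

_SUPPORTED_DTYPES = (
    np.uint8,
    np.uint16,
    np.int16,
    np.int32,
    np.float32,
    np.float64,
)


def load_stack(path: str | Path) -> list[np.ndarray]:
    """Load a single- or multi-page grayscale TIFF as a list of frames.

    Page order is preserved and dtype is kept; pages of mixed shape or
    unsupported dtype raise.
    """
    with tifffile.TiffFile(str(path)) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shape = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape:
            raise ValueError(f"{path}: page {i} shape {p.shape} != {shape}")
        if not any(p.dtype.type is t for t in _SUPPORTED_DTYPES):
            raise ValueError(f"{path}: unsupported dtype {p.dtype}")
        if p.ndim != 2:
            raise ValueError(f"{path}: pages must be 2D grayscale")
    return pages


def save_stack(path: str | Path, images: list[np.ndarray] | np.ndarray) -> None:
    arr = np.asarray(images)
    tifffile.imwrite(str(path), arr)


def save_field(path: str | Path, fld: VectorField2D, extra_meta: dict | None = None) -> None:
    """Save a vector field as a 2-channel float32 TIFF (channels u, v)."""
    meta = {"spacing": fld.spacing, "units": fld.units}
    if extra_meta:
        meta.update(extra_meta)
    data = np.stack([fld.u, fld.v]).astype(np.float32)
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def load_field(path: str | Path) -> VectorField2D:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel field TIFF")
    return VectorField2D(
        data[0].astype(float),
        data[1].astype(float),
        spacing=float(meta.get("spacing", 1.0)),
        units=str(meta.get("units", "")),
        meta={k: v for k, v in meta.items() if k not in ("spacing", "units")},
    )


def write_csv(path: str | Path, df: pd.DataFrame, config_hash: str | None = None) -> None:
    """Write a CSV with an optional provenance comment header."""
    with open(path, "w") as f:
        if config_hash:
            f.write(f"# config_hash={config_hash}\n")
        df.to_csv(f, index=False)


@dataclass
class RunConfig:
    """Everything needed to (re)run the pipeline on one field of view or
    a time series; serializes to YAML and round-trips losslessly."""

    tensed: str = ""
    relaxed: str = ""
    cell_image: str | None = None
    cell_mask: str | None = None
    out_dir: str = "tfm_out"
    pixel_size: float = 0.108  # µm/px

    flow: FlowParams = field(default_factory=FlowParams)
    median_window: int | None = None
    subsample_step: int = 8

    E_pa: float = 20_000.0
    nu: float = 0.5
    thickness_um: float | None = None
    gcv: bool = True
    lam: float | None = None
    gcv_per_frame: bool = False
    lanczos_exponent: float = 0.0

    mesh_edge_length_um: float = 2.5
    nu_sheet: float = 0.5
    threshold_mode: str = "otsu"

    seed: int = 0
    fail_fast: bool = False

    @property
    def substrate(self) -> ElasticSubstrate:
        return ElasticSubstrate(self.E_pa, self.nu, self.thickness_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text)
        flow = d.pop("flow", None)
        cfg = cls(**d)
        if flow is not None:
            cfg.flow = FlowParams(**flow)
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
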