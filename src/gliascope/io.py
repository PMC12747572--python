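"""TIFF/CSV/YAML readers and writers shared by the pipeline stages.

Images travel as plain TIFF with a YAML sidecar (``<file>.tif.yaml``) holding
physical metadata (voxel pitch, frame rate) when the TIFF tags do not. Axis
layouts are fixed per stage: morphology stacks ZCYX, calcium movies TYX,
viability fields CYX. Records are written as UTF-8 CSV with a stable column
order and '.' decimals; NaN serialises as an empty field and reads back as
missing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import AxisMismatchError, SchemaError
from .images import CalciumMovie, MultichannelImage, VolumetricImage

__all__ = [
    "read_stack",
    "write_stack",
    "write_records",
    "read_records",
    "load_yaml",
    "dump_yaml",
]

_SIDECAR_SUFFIX = ".yaml"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def read_stack(
    path: str | Path, expected_axes: str
) -> VolumetricImage | CalciumMovie | MultichannelImage:
    """Read a TIFF with the stage's expected axis layout.

    ``expected_axes`` is one of ``"ZCYX"`` (morphology stack, returned as a
    :class:`VolumetricImage` with in-memory CZYX axes), ``"TYX"`` (calcium
    movie) or ``"CYX"`` (viability field). Metadata missing from the TIFF is
    taken from the YAML sidecar; defaults are 1 μm pitch and 10 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    meta = _read_sidecar(path)
    if data.ndim != len(expected_axes):
        raise AxisMismatchError(
            f"{path.name}: expected {expected_axes} ({len(expected_axes)} axes), "
            f"got shape {data.shape}"
        )
    if expected_axes == "ZCYX":
        pitch = meta.get("voxel_pitch_um", 1.0)
        if np.isscalar(pitch):
            pitch = (float(pitch),) * 3
        return VolumetricImage(
            data=np.moveaxis(data, 1, 0),
            voxel_pitch_um=tuple(pitch),
            channel_names=tuple(meta.get("channel_names", ())),
        )
    if expected_axes == "TYX":
        return CalciumMovie(
            frames=data,
            frame_rate_hz=float(meta.get("frame_rate_hz", 10.0)),
            pixel_pitch_um=float(meta.get("pixel_pitch_um", 0.65)),
        )
    if expected_axes == "CYX":
        return MultichannelImage(
            data=data,
            pixel_pitch_um=float(meta.get("pixel_pitch_um", 1.0)),
            channel_names=tuple(meta.get("channel_names", ())),
        )
    raise AxisMismatchError(f"unsupported axis layout {expected_axes!r}")


def write_stack(
    image: VolumetricImage | CalciumMovie | MultichannelImage, path: str | Path
) -> None:
    """Write an image container to TIFF plus its metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, VolumetricImage):
        data = np.moveaxis(image.data, 0, 1)  # CZYX -> ZCYX on disk
        meta = {
            "axes": "ZCYX",
            "voxel_pitch_um": list(image.voxel_pitch_um),
            "channel_names": list(image.channel_names),
        }
    elif isinstance(image, CalciumMovie):
        data = image.frames
        meta = {
            "axes": "TYX",
            "frame_rate_hz": image.frame_rate_hz,
            "pixel_pitch_um": image.pixel_pitch_um,
        }
    else:
        data = image.data
        meta = {
            "axes": "CYX",
            "pixel_pitch_um": image.pixel_pitch_um,
            "channel_names": list(image.channel_names),
        }
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def write_records(
    records: pd.DataFrame, path: str | Path, schema: Sequence[str] | None = None
) -> None:
    """Write records as CSV with a stable column order; round-trips losslessly.

    ``schema`` lists the required columns (and their order); missing columns
    raise :class:`SchemaError`. NaN is serialised as an empty field.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        missing = [c for c in schema if c not in records.columns]
        if missing:
            raise SchemaError(f"records missing columns {missing}")
        records = records[list(schema)]
    records.to_csv(path, index=False, na_rep="")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
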