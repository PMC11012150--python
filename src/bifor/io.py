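"""Multi-channel stack and manifest I/O.

Conventions used everywhere in this package:

* axis order is ``(Z,)Y,X``, coordinates are 0-based voxel indices;
* a stack holds named channel roles (``dapi``, ``red``, ``green``) — an
  :class:`ImageStack` never carries an anonymous channel;
* intensities are non-negative floats in memory and 16-bit unsigned on disk,
  clipped with a per-channel saturation flag when clipping occurred.

TIFF files are written with :mod:`tifffile` in its "shaped" dialect, which
stores a JSON description (channel roles, voxel size, saturation flags) in the
ImageDescription tag, so a stack round-trips with its metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelMismatchError, ManifestError

CHANNEL_ROLES = ("dapi", "red", "green")

MANIFEST_COLUMNS = ("scene_id", "condition", "replicate", "path", "beta_true")

_UINT16_MAX = np.iinfo(np.uint16).max


@dataclass
class ImageStack:
    """Aligned multi-channel intensity volumes with voxel-size metadata.

    Parameters
    ----------
    channels
        Mapping from channel role to a 2D ``(Y,X)`` or 3D ``(Z,Y,X)``
        non-negative intensity array. All channels must share one shape.
    voxel_size
        Micrometres per voxel, one entry per axis, same axis order as the data.
    saturated
        Per-channel flag set by :func:`write_stack` when values had to be
        clipped into the 16-bit range.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...]
    saturated: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {role: np.asarray(arr) for role, arr in self.channels.items()}
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise ChannelMismatchError("stack holds no channels")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ChannelMismatchError(f"channels have differing shapes: {shapes}")
        shape = next(iter(shapes))
        if len(shape) not in (2, 3):
            raise ChannelMismatchError(f"only 2D (Y,X) or 3D (Z,Y,X) stacks supported, got shape {shape}")
        if len(self.voxel_size) != len(shape):
            raise ChannelMismatchError(
                f"voxel_size has {len(self.voxel_size)} entries for {len(shape)}D data"
            )
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ChannelMismatchError(f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
            if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
                raise ChannelMismatchError(f"channel {role!r} contains non-finite values")
            if arr.size and arr.min() < 0:
                raise ChannelMismatchError(f"channel {role!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return len(self.shape)


def quantize_uint16(arr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Round-half-to-even to integers and clip into [0, 65535].

    Returns the uint16 array and a flag that is True when any value exceeded
    the representable range before clipping.
    """
    rounded = np.rint(np.asarray(arr, dtype=np.float64))
    saturated = bool(rounded.size) and bool((rounded > _UINT16_MAX).any())
    return np.clip(rounded, 0, _UINT16_MAX).astype(np.uint16), saturated


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-channel 16-bit TIFF with JSON metadata.

    Channel order on disk follows the insertion order of ``stack.channels``.
    Values outside the 16-bit range are clipped and the channel's
    ``saturated`` flag is set (on the stack and in the file metadata).
    """
    path = Path(path)
    roles = list(stack.channels)
    planes = []
    for role in roles:
        data, sat = quantize_uint16(stack.channels[role])
        if sat:
            stack.saturated[role] = True
        planes.append(data)
    arr = np.stack(planes, axis=0)
    axes = "CYX" if stack.ndim == 2 else "CZYX"
    metadata = {
        "axes": axes,
        "channels": roles,
        "voxel_size_um": list(stack.voxel_size),
        "saturated": {r: bool(stack.saturated.get(r, False)) for r in roles},
    }
    tifffile.imwrite(path, arr, photometric="minisblack", metadata=metadata)
    return path


def read_stack(path: str | Path, channel_order: Sequence[str] | None = None) -> ImageStack:
    """Read a multi-channel TIFF into an :class:`ImageStack`.

    Channel roles are taken from the file's JSON metadata when present;
    otherwise ``channel_order`` must name the role of each channel plane.
    An explicit ``channel_order`` overrides the metadata but must still match
    the channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if arr.ndim not in (3, 4):
        raise ChannelMismatchError(
            f"{path}: expected channel-first 2D or 3D data (3 or 4 array dims), got {arr.ndim}"
        )
    n_channels = arr.shape[0]
    roles = list(channel_order) if channel_order is not None else meta.get("channels")
    if roles is None:
        raise ChannelMismatchError(f"{path}: no channel metadata in file and no channel_order given")
    if len(roles) != n_channels:
        raise ChannelMismatchError(
            f"{path}: file has {n_channels} channels but {len(roles)} roles declared: {roles}"
        )
    voxel_size = meta.get("voxel_size_um")
    if voxel_size is None:
        voxel_size = (1.0,) * (arr.ndim - 1)
    saturated = dict(meta.get("saturated", {}))
    channels = {str(role): arr[i] for i, role in enumerate(roles)}
    return ImageStack(channels=channels, voxel_size=tuple(voxel_size), saturated=saturated)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as a single-channel 8-bit TIFF (255 = inside)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants; returns the (typed) manifest.

    ``scene_id`` must be unique and replicate ids must form a contiguous
    positive range ``1..R`` within each condition.
    """
    missing = [c for c in MANIFEST_COLUMNS if c != "beta_true" and c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {missing}")
    manifest = manifest.copy()
    if "beta_true" not in manifest.columns:
        manifest["beta_true"] = np.nan
    if len(manifest):
        manifest["replicate"] = manifest["replicate"].astype(int)
        manifest["beta_true"] = manifest["beta_true"].astype(float)
        dup = manifest["scene_id"][manifest["scene_id"].duplicated()]
        if len(dup):
            raise ManifestError(f"duplicate scene_id values: {sorted(set(dup))}")
        for condition, grp in manifest.groupby("condition"):
            reps = sorted(grp["replicate"].unique())
            if reps != list(range(1, len(reps) + 1)):
                raise ManifestError(
                    f"condition {condition!r}: replicate ids {reps} are not a contiguous range 1..R"
                )
    return manifest[list(MANIFEST_COLUMNS)]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_manifest(manifest).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed CSV
        raise ManifestError(f"malformed manifest CSV {path}: {exc}") from exc
    if df.empty and not len(df.columns):
        raise ManifestError(f"manifest {path} has no header")
    return validate_manifest(df)


def empty_manifest() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scene_id": pd.Series(dtype=str),
            "condition": pd.Series(dtype=str),
            "replicate": pd.Series(dtype=int),
            "path": pd.Series(dtype=str),
            "beta_true": pd.Series(dtype=float),
        }
    )


def read_channel_config(path: str | Path) -> list[str]:
    """Read a YAML/JSON snippet naming the channel order of a dataset."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    order = cfg.get("channel_order") if isinstance(cfg, Mapping) else cfg
    if not isinstance(order, list) or not all(r in CHANNEL_ROLES for r in order):
        raise ChannelMismatchError(f"invalid channel order in {path}: {json.dumps(order)}")
    return [str(r) for r in order]
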