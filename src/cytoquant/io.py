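"""Reading, normalizing and bundling fluorescence channel images.

Channel images arrive as single-plane grayscale TIFF or PNG rasters in
8-bit, 16-bit or floating-point form. On load every image is rescaled to
[0, 1] by dividing by the maximum possible value of its dtype (255 or
65535); floating-point inputs must already be in [0, 1] and pass through
unchanged. The four channels of one cytospin (DAPI, SOX10, EdU, VIME) are
bundled into a :class:`MultiChannelImage` which enforces co-registration
(identical shapes) and the intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

#: Channels a cytospin image must provide, in canonical order.
REQUIRED_CHANNELS: Tuple[str, ...] = ("DAPI", "SOX10", "EdU", "VIME")

_DTYPE_DIVISORS = {"u8": 255.0, "u16": 65535.0}


class ChannelLoadError(ValueError):
    """Raised when a channel file cannot be interpreted as a single-plane
    grayscale intensity image."""


@dataclass
class MultiChannelImage:
    """Co-registered per-channel 2-D intensity arrays normalized to [0, 1]."""

    channels: Dict[str, np.ndarray]
    source_paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing required channel {name!r}")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if len(shape) != 2:
                raise ValueError(f"channel {name!r} is not a 2-D array")
            if shape != first:
                raise ValueError(
                    f"channel shape mismatch: {shapes}"
                )
        for name, arr in self.channels.items():
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"channel {name!r} has values outside [0, 1]")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise ChannelLoadError(f"could not decode {path}: {exc}") from exc
    return np.asarray(arr)


def load_channel(path, bit_depth_policy: str = "auto") -> np.ndarray:
    """Load one grayscale channel and rescale it to [0, 1].

    Parameters
    ----------
    path : path-like
        Single-page grayscale TIFF or PNG.
    bit_depth_policy : {"auto", "u8", "u16", "float"}
        ``auto`` infers the divisor from the source dtype; the explicit
        policies additionally assert that the file has the expected dtype.

    Returns
    -------
    numpy.ndarray
        2-D float64 array with values in [0, 1].
    """
    path = Path(path)
    if bit_depth_policy not in ("auto", "u8", "u16", "float"):
        raise ValueError(f"unknown bit_depth_policy {bit_depth_policy!r}")
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ChannelLoadError(
            f"{path} is not a single-plane grayscale image (shape {arr.shape}); "
            "RGB and multi-page inputs are rejected"
        )

    kind = arr.dtype.kind
    if kind == "u" and arr.dtype.itemsize == 1:
        inferred = "u8"
    elif kind == "u" and arr.dtype.itemsize == 2:
        inferred = "u16"
    elif kind == "f":
        inferred = "float"
    else:
        raise ChannelLoadError(f"unsupported dtype {arr.dtype} in {path}")

    policy = inferred if bit_depth_policy == "auto" else bit_depth_policy
    if policy != inferred:
        raise ChannelLoadError(
            f"{path} has dtype {arr.dtype}, incompatible with policy {policy!r}"
        )

    if policy == "float":
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise ChannelLoadError(f"floating-point image {path} outside [0, 1]")
        return out
    return arr.astype(np.float64) / _DTYPE_DIVISORS[policy]


def assemble_image(channel_paths: Mapping[str, "str | Path"],
                   bit_depth_policy: str = "auto") -> MultiChannelImage:
    """Load the four required channels into a validated MultiChannelImage."""
    missing = [c for c in REQUIRED_CHANNELS if c not in channel_paths]
    if missing:
        raise ValueError(f"missing required channel(s): {missing}")
    channels = {}
    sources = {}
    for name, path in channel_paths.items():
        channels[name] = load_channel(path, bit_depth_policy)
        sources[name] = str(path)
    return MultiChannelImage(channels=channels, source_paths=sources)


def save_channel_u16(path, array: np.ndarray) -> None:
    """Write a [0, 1] intensity array as a 16-bit grayscale TIFF."""
    array = np.asarray(array, dtype=np.float64)
    if array.size and (array.min() < 0.0 or array.max() > 1.0):
        raise ValueError("intensity array outside [0, 1]")
    tifffile.imwrite(path, np.round(array * 65535.0).astype(np.uint16))


def save_label_map(path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit TIFF (labels must fit in uint16)."""
    labels = np.asarray(labels)
    if labels.size and labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be saved as uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))


def load_label_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
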