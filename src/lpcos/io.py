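"""Domain containers and raster image IO for fundus vessel analysis.

All pixel data is handled as floating point in [0, 1] internally.  Binary
masks (field of view, vessel ground truth, segmentations) are boolean
arrays.  PNG is used for 8-bit output and TIFF (via :mod:`tifffile`) as the
lossless float container for enhancement maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FundusImage",
    "BinaryMask",
    "ProbabilityMap",
    "ChannelStack",
    "read_image",
    "read_mask",
    "write_image_png",
    "write_mask_png",
    "write_float_tiff",
    "read_float_tiff",
    "assemble_channel_stack",
    "DatasetLayout",
]

MIN_SIDE = 64  # one network patch

CHANNEL_POLICIES = ("green", "luminance", "gray-as-is")
MASK_ROLES = ("fov", "vessel_gt", "segmentation")
COMBOS = ("NOR", "NOR+LPC", "NOR+LPC+LID")


@dataclass
class FundusImage:
    """A 2-D fundus photograph with intensities scaled to [0, 1].

    Parameters
    ----------
    pixels
        2-D float array in [0, 1].
    pixel_size_um
        Physical pixel size in micrometres, or ``None`` when unknown.
        Metric code that needs micrometres must be given it explicitly.
    source_channel
        How the scalar plane was obtained from the raster file.
    fov
        Optional paired field-of-view mask.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    source_channel: str = "gray-as-is"
    fov: "BinaryMask | None" = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("FundusImage pixels must be 2-D")
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(f"image {h}x{w} smaller than minimum side {MIN_SIDE}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.source_channel not in CHANNEL_POLICIES:
            raise ValueError(f"unknown source_channel {self.source_channel!r}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.fov is not None and self.fov.pixels.shape != self.pixels.shape:
            raise ValueError("FOV mask shape does not match image")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Boolean mask paired with a fundus image (FOV, ground truth or output)."""

    pixels: np.ndarray
    role: str = "vessel_gt"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask pixels must be 2-D")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    def validate_against(self, img: FundusImage) -> None:
        if self.pixels.shape != img.pixels.shape:
            raise ValueError(
                f"mask shape {self.pixels.shape} does not match image "
                f"shape {img.pixels.shape}"
            )


@dataclass
class ProbabilityMap:
    """Per-pixel vessel probability in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ProbabilityMap pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("probability map contains non-finite values")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)


CHANNEL_ORDER = ("NOR", "LPC", "LPC_ORIENT", "LPC_ORIENT_SIN", "LPC_ORIENT_COS", "LIDOS")


@dataclass
class ChannelStack:
    """Ordered, named 2-D feature channels fed to the network.

    Channel order is fixed to (NOR, LPC, LPC_ORIENT, LIDOS) regardless of
    the order in which channels were supplied.
    """

    names: tuple[str, ...]
    channels: np.ndarray  # (C, H, W)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (C, H, W) array")
        if len(self.names) != self.channels.shape[0]:
            raise ValueError("number of names must match number of channels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        for n in self.names:
            if n not in CHANNEL_ORDER:
                raise ValueError(f"unknown channel name {n!r}")
        order = [CHANNEL_ORDER.index(n) for n in self.names]
        if order != sorted(order):
            raise ValueError("channels must follow the fixed NOR/LPC/LPC_ORIENT/LIDOS order")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer or float raster to float64 in [0, 1]."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0:  # e.g. float TIFF stored on 0..255
        out = out / out.max()
    return out


def read_image(
    path: str | Path,
    channel_policy: str = "green",
    pixel_size_um: float | None = None,
) -> FundusImage:
    """Read a fundus photograph and reduce it to a scalar [0, 1] plane.

    ``channel_policy`` selects how RGB input collapses to one plane:
    ``green`` takes the green plane (highest vessel contrast in fundus
    photography), ``luminance`` the Rec. 601 weighted sum, ``gray-as-is``
    requires grayscale input.
    """
    path = Path(path)
    if channel_policy not in CHANNEL_POLICIES:
        raise ValueError(f"unknown channel policy {channel_policy!r}")
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot read image file {path}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if raw.ndim == 3:
        raw = raw[..., :3]
        plane = _to_unit_float(raw)
        if channel_policy == "green":
            plane = plane[..., 1]
        elif channel_policy == "luminance":
            plane = plane @ np.array([0.299, 0.587, 0.114])
        else:
            raise ValueError(
                f"{path} is RGB but channel policy is 'gray-as-is'"
            )
    elif raw.ndim == 2:
        plane = _to_unit_float(raw)
    else:
        raise ValueError(f"unsupported image dimensionality {raw.ndim} in {path}")
    return FundusImage(
        np.clip(plane, 0.0, 1.0),
        pixel_size_um=pixel_size_um,
        source_channel=channel_policy,
    )


def read_mask(
    path: str | Path,
    role: str = "vessel_gt",
    paired: FundusImage | None = None,
) -> BinaryMask:
    """Read a binary mask: any nonzero pixel becomes True."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read mask file {path}") from exc
    if raw.ndim == 3:
        raw = raw[..., :3].max(axis=-1)
    mask = BinaryMask(raw != 0, role=role)
    if paired is not None:
        mask.validate_against(paired)
    return mask


def write_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """Quantize a [0, 1] float array to 8-bit and write a PNG."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def write_mask_png(path: str | Path, mask: BinaryMask | np.ndarray) -> None:
    pix = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    iio.imwrite(Path(path), (pix.astype(np.uint8) * 255))


def write_float_tiff(path: str | Path, pixels: np.ndarray) -> None:
    """Lossless float container for enhancement maps."""
    tifffile.imwrite(Path(path), np.asarray(pixels, dtype=np.float32))


def read_float_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float64)


def encode_orientation(theta: np.ndarray) -> np.ndarray:
    """Encode an angle map in [0, pi) as theta/pi in [0, 1)."""
    return np.mod(np.asarray(theta, dtype=np.float64), np.pi) / np.pi


def assemble_channel_stack(
    norm: np.ndarray,
    lpc=None,
    lidos: np.ndarray | None = None,
    combo: str = "NOR",
    orientation_encoding: str = "angle",
) -> ChannelStack:
    """Assemble the network input channels for one image.

    ``combo`` is one of ``NOR`` (normalized image only), ``NOR+LPC``
    (adds the phase-congruency value and orientation channels) or
    ``NOR+LPC+LID`` (adds the orientation-score enhancement as well).
    The LPC orientation angle in [0, pi) is stored as theta/pi by default;
    ``orientation_encoding='sincos'`` substitutes sin(2*theta) and
    cos(2*theta) channels (no wrap discontinuity) — note this changes the
    channel count.
    """
    if combo not in COMBOS:
        raise ValueError(f"unknown channel combo {combo!r}")
    norm = np.asarray(norm, dtype=np.float64)
    names: list[str] = ["NOR"]
    chans: list[np.ndarray] = [norm]
    if combo in ("NOR+LPC", "NOR+LPC+LID"):
        if lpc is None:
            raise ValueError(f"combo {combo} requires an LPC result")
        lpc_val = np.asarray(lpc.lpc, dtype=np.float64)
        theta = np.asarray(lpc.orientation, dtype=np.float64)
        if lpc_val.shape != norm.shape or theta.shape != norm.shape:
            raise ValueError("LPC maps must share the image shape")
        names.append("LPC")
        chans.append(lpc_val)
        if orientation_encoding == "angle":
            names.append("LPC_ORIENT")
            chans.append(encode_orientation(theta))
        elif orientation_encoding == "sincos":
            # wrap-free double-angle encoding; carries one extra plane
            names.extend(["LPC_ORIENT_SIN", "LPC_ORIENT_COS"])
            chans.extend([np.sin(2 * theta), np.cos(2 * theta)])
        else:
            raise ValueError(f"unknown orientation encoding {orientation_encoding!r}")
    if combo == "NOR+LPC+LID":
        if lidos is None:
            raise ValueError("combo NOR+LPC+LID requires a LIDOS map")
        lidos = np.asarray(lidos, dtype=np.float64)
        if lidos.shape != norm.shape:
            raise ValueError("LIDOS map must share the image shape")
        names.append("LIDOS")
        chans.append(lidos)
    return ChannelStack(tuple(names), np.stack(chans))


@dataclass
class DatasetLayout:
    """Directory convention: images/, masks_fov/, masks_gt/ with matching stems."""

    root: Path

    IMAGES = "images"
    FOV = "masks_fov"
    GT = "masks_gt"

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def images_dir(self) -> Path:
        return self.root / self.IMAGES

    @property
    def fov_dir(self) -> Path:
        return self.root / self.FOV

    @property
    def gt_dir(self) -> Path:
        return self.root / self.GT

    def make_dirs(self) -> None:
        for d in (self.images_dir, self.fov_dir, self.gt_dir):
            d.mkdir(parents=True, exist_ok=True)

    def stems(self) -> list[str]:
        if not self.images_dir.is_dir():
            raise FileNotFoundError(f"no images directory under {self.root}")
        return sorted(p.stem for p in self.images_dir.iterdir() if p.is_file())

    def triple(self, stem: str) -> tuple[Path, Path, Path]:
        def find(d: Path) -> Path:
            hits = sorted(d.glob(stem + ".*"))
            if not hits:
                raise FileNotFoundError(f"no file with stem {stem!r} in {d}")
            return hits[0]

        return find(self.images_dir), find(self.fov_dir), find(self.gt_dir)

    def iter_triples(self) -> Iterator[tuple[str, Path, Path, Path]]:
        for stem in self.stems():
            yield (stem, *self.triple(stem))

    def write_manifest(self, payload: dict) -> None:
        (self.root / "manifest.json").write_text(json.dumps(payload, indent=2))

    def read_manifest(self) -> dict:
        return json.loads((self.root / "manifest.json").read_text())
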