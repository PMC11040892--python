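"""Reading micrographs and writing the six-folder results tree.

Input micrographs are 8-bit (or 16-bit, linearly rescaled) RGB rasters —
TIFF or PNG.  A completed analysis writes one artifact per image into each
of six fixed subfolders of a results root:

``Image``      copy of the original micrograph,
``Grayscale``  the green channel as 8-bit grayscale,
``Count``      the cell label map rendered with one distinct color per cell,
``Shokaku``    the original with a white circle around each accepted
               micronucleus,
``Palam``      the six-line parameter file used for the image,

plus one tab-separated counts file in ``Text``.
"""

from __future__ import annotations

import colorsys
import shutil
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError, ValidationError

__all__ = [
    "RGBMicrograph",
    "ChannelImage",
    "OutputTree",
    "read_rgb_micrograph",
    "split_channels",
    "render_outputs",
    "write_counts_text",
]


@dataclass(frozen=True)
class RGBMicrograph:
    """An H x W x 3 grid of 8-bit pixels plus its source identifier."""

    pixels: np.ndarray
    path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"micrograph pixels must be H x W x 3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("micrograph must have H >= 1 and W >= 1")
        if px.dtype != np.uint8:
            raise ValidationError("micrograph pixels must be 8-bit")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ChannelImage:
    """A single extracted channel as an 8-bit grayscale grid."""

    pixels: np.ndarray
    channel_tag: str

    def __post_init__(self) -> None:
        if self.channel_tag not in ("red", "green"):
            raise ValidationError(
                f"channel_tag must be 'red' or 'green', got {self.channel_tag!r}"
            )


def read_rgb_micrograph(path: str | Path) -> RGBMicrograph:
    """Read a TIFF/PNG micrograph as an 8-bit RGB grid.

    16-bit inputs are rescaled to 8-bit by integer division by 257 (the
    full-range linear map).  An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder-specific error types vary
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got 1 channel"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        n = arr.shape[2] if arr.ndim == 3 else arr.ndim
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got {n} channels"
        )
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: unsupported pixel type {arr.dtype}; need 8- or 16-bit"
        )
    return RGBMicrograph(pixels=arr, path=str(path))


def split_channels(m: RGBMicrograph) -> tuple[ChannelImage, ChannelImage]:
    """Extract the red and green planes; the blue plane is discarded."""
    return (
        ChannelImage(m.pixels[:, :, 0].copy(), "red"),
        ChannelImage(m.pixels[:, :, 1].copy(), "green"),
    )


@dataclass(frozen=True)
class OutputTree:
    """The fixed six-subfolder results tree."""

    root: Path

    SUBFOLDERS = ("Image", "Grayscale", "Count", "Shokaku", "Text", "Palam")

    @classmethod
    def create(cls, root: str | Path) -> "OutputTree":
        root = Path(root)
        for sub in cls.SUBFOLDERS:
            (root / sub).mkdir(parents=True, exist_ok=True)
        return cls(root=root)

    def folder(self, name: str) -> Path:
        if name not in self.SUBFOLDERS:
            raise ValidationError(f"unknown output subfolder {name!r}")
        return self.root / name


def _label_palette_color(label: int) -> tuple[int, int, int]:
    # Golden-angle hue sequence keyed by label id: deterministic, and
    # consecutive labels get well-separated hues.
    hue = (label * 0.61803398875) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 1.0)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def render_count_image(cell_labels: np.ndarray) -> np.ndarray:
    """Render a label map with one distinct color per cell on black."""
    cell_labels = np.asarray(cell_labels)
    out = np.zeros((*cell_labels.shape, 3), dtype=np.uint8)
    for label in np.unique(cell_labels):
        if label <= 0:
            continue
        out[cell_labels == label] = _label_palette_color(int(label))
    return out


def render_shokaku_image(pixels: np.ndarray, accepted_mn) -> np.ndarray:
    """Mark each accepted micronucleus with a white circle on the original.

    The circle is a 2 px stroke at radius equal to the micronucleus
    equivalent radius plus 4 px.
    """
    out = np.asarray(pixels).copy()
    h, w = out.shape[:2]
    for rec in accepted_mn:
        radius = float(np.sqrt(rec.area / np.pi)) + 4.0
        cr, cc = rec.centroid
        extent = int(np.ceil(radius + 2))
        r0 = max(0, int(np.floor(cr)) - extent)
        r1 = min(h, int(np.ceil(cr)) + extent + 1)
        c0 = max(0, int(np.floor(cc)) - extent)
        c1 = min(w, int(np.ceil(cc)) + extent + 1)
        rr, cc_grid = np.mgrid[r0:r1, c0:c1]
        dist = np.sqrt((rr - cr) ** 2 + (cc_grid - cc) ** 2)
        band = np.abs(dist - radius) <= 1.0
        out[r0:r1, c0:c1][band] = (255, 255, 255)
    return out


def render_outputs(
    m: RGBMicrograph,
    cell_labels: np.ndarray,
    accepted_mn,
    tree: OutputTree,
    stem: str | None = None,
) -> dict[str, Path]:
    """Write the per-image artifacts of a completed analysis.

    Returns the path written into each subfolder keyed by subfolder name.
    """
    if stem is None:
        stem = Path(m.path).stem if m.path else "image"
    paths: dict[str, Path] = {}

    image_path = tree.folder("Image") / (
        Path(m.path).name if m.path else f"{stem}.png"
    )
    if m.path and Path(m.path).exists():
        shutil.copyfile(m.path, image_path)
    else:
        iio.imwrite(image_path.with_suffix(".png"), m.pixels)
        image_path = image_path.with_suffix(".png")
    paths["Image"] = image_path

    gray_path = tree.folder("Grayscale") / f"{stem}.png"
    iio.imwrite(gray_path, m.pixels[:, :, 1])
    paths["Grayscale"] = gray_path

    count_path = tree.folder("Count") / f"{stem}.png"
    iio.imwrite(count_path, render_count_image(cell_labels))
    paths["Count"] = count_path

    shokaku_path = tree.folder("Shokaku") / f"{stem}.png"
    iio.imwrite(shokaku_path, render_shokaku_image(m.pixels, accepted_mn))
    paths["Shokaku"] = shokaku_path

    return paths


def write_counts_text(results, tree: OutputTree,
                      filename: str = "counts.txt") -> Path:
    """Write the tab-separated per-image counts plus a terminal sum row."""
    results = list(results)
    if not results:
        raise ValidationError("cannot write a counts file for zero results")
    lines = []
    total_sum = 0
    mn_sum = 0
    for res in results:
        name = Path(res.name).stem if res.name else "image"
        lines.append(f"{name}\t{res.total_cells}\t{res.mn_cells}")
        total_sum += res.total_cells
        mn_sum += res.mn_cells
    lines.append(f"total\t{total_sum}\t{mn_sum}")
    path = tree.folder("Text") / filename
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
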