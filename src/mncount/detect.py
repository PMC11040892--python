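"""Core detection pipeline for micronucleus/cell scoring.

The pipeline follows the staining logic of acridine orange: nuclear
material is green, cytoplasm is red.  The green channel is binarized and
cleaned, then eroded with a large square structuring element — connected
components that survive the erosion are nuclei (restored to their original
extent), components that vanish are micronucleus candidates.  Candidates
are accepted by area and circularity.  The cytoplasm is recovered from a
sigmoid-enhanced composite of the red and green channels, cut into
individual cells by a marker-controlled watershed seeded at the nuclei,
and each accepted micronucleus is assigned to the cell containing its
centroid.  A cell with at least one assigned micronucleus counts as one
micronucleated (MN) cell, regardless of how many micronuclei it carries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import ValidationError
from .io import RGBMicrograph, split_channels
from .params import DetectionParams, auto_detection_params

__all__ = [
    "RegionRecord",
    "RegionTable",
    "CellRecord",
    "ImageResult",
    "binarize",
    "erode",
    "dilate",
    "clean_mask",
    "classify_blobs_by_erosion",
    "sigmoid_enhance",
    "cytoplasm_mask",
    "separate_cells",
    "measure_regions",
    "filter_micronuclei",
    "classify_cells",
    "analyze_image",
]

_EIGHT = np.ones((3, 3), bool)


# --- elementary morphology --------------------------------------------------
#
# Everything outside the image counts as background for both erosion and
# dilation, so the operators agree exactly with sliding-window min/max
# filters under constant zero padding.

def _check_kernel(k: int) -> None:
    if k < 3 or k % 2 == 0:
        raise ValidationError(f"kernel width must be odd and >= 3, got {k}")


def erode(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Morphological erosion by a ``kernel``x``kernel`` square element."""
    _check_kernel(kernel)
    return ndi.minimum_filter(
        mask.astype(np.uint8), size=kernel, mode="constant", cval=0
    ).astype(bool)


def dilate(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Morphological dilation by a ``kernel``x``kernel`` square element."""
    _check_kernel(kernel)
    return ndi.maximum_filter(
        mask.astype(np.uint8), size=kernel, mode="constant", cval=0
    ).astype(bool)


def binarize(img: np.ndarray, th: int) -> np.ndarray:
    """Threshold a channel image: a pixel is foreground iff intensity >= th."""
    return np.asarray(img) >= th


def clean_mask(mask: np.ndarray, kernel_s: int) -> np.ndarray:
    """Opening then closing with the small square element.

    The opening removes speckle smaller than the element; the closing fills
    pinholes of comparable size.
    """
    opened = dilate(erode(mask, kernel_s), kernel_s)
    return erode(dilate(opened, kernel_s), kernel_s)


def classify_blobs_by_erosion(
    green_mask: np.ndarray, kernel_l: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split green blobs into nuclei and micronucleus candidates by size.

    Erodes the cleaned green mask with the large square element.  A
    connected component (8-connectivity) with a nonempty eroded remnant is
    a nucleus and is restored to its full original extent (geodesic
    reconstruction by component membership); a component that erodes away
    completely is a micronucleus candidate.  The two outputs partition the
    input mask exactly.
    """
    green_mask = np.asarray(green_mask, dtype=bool)
    eroded = erode(green_mask, kernel_l)
    labels, n = ndi.label(green_mask, structure=_EIGHT)
    if n == 0:
        empty = np.zeros_like(green_mask)
        return empty, empty.copy()
    surviving = np.unique(labels[eroded])
    surviving = surviving[surviving > 0]
    nuclei = np.isin(labels, surviving)
    mn_candidates = green_mask & ~nuclei
    return nuclei, mn_candidates


def sigmoid_enhance(img: np.ndarray, center: float, gain: float) -> np.ndarray:
    """Sigmoid gradation: s(v) = round(255 / (1 + exp(-gain * (v - center)))).

    Intensities above the center are pushed toward white and those below
    toward black; the mapping is strictly monotone so ordering is kept.
    """
    if not 0 <= center <= 255:
        raise ValidationError(f"sigmoid center must be in [0, 255], got {center}")
    if gain <= 0:
        raise ValidationError(f"sigmoid gain must be > 0, got {gain}")
    v = np.arange(256, dtype=np.float64)
    lut = np.round(255.0 / (1.0 + np.exp(-gain * (v - center))))
    return lut.astype(np.uint8)[np.asarray(img, dtype=np.uint8)]


def cytoplasm_mask(
    red: np.ndarray, green: np.ndarray, params: DetectionParams
) -> np.ndarray:
    """Recover the filled cytoplasm footprint (nuclei included).

    The red and green channels are superimposed by per-pixel maximum, the
    composite is sigmoid-enhanced around the window level, thresholded by
    Otsu's method, cleaned with the small kernel and hole-filled so every
    nucleus pixel lies inside the cytoplasm mask.
    """
    red = np.asarray(red)
    green = np.asarray(green)
    if red.shape != green.shape:
        raise ValidationError("red and green channels must share a shape")
    composite = np.maximum(red, green)
    enhanced = sigmoid_enhance(composite, params.window_level,
                               params.sigmoid_gain)
    if enhanced.min() == enhanced.max():
        return np.zeros(enhanced.shape, dtype=bool)
    # skimage's Otsu value separates classes as foreground > threshold
    mask = enhanced > threshold_otsu(enhanced)
    mask = clean_mask(mask, params.kernel_s)
    return ndi.binary_fill_holes(mask)


def separate_cells(cyto: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Cut the fused cytoplasm mask into one labeled region per nucleus.

    Marker-controlled watershed on the negated Euclidean distance transform
    of the cytoplasm mask, with the (restored) nucleus components as
    markers.  Watershed-line pixels belong to no cell, and cytoplasm
    components containing no nucleus stay unlabeled (debris/ghosts are not
    cells).  Nuclei pixels outside the cytoplasm are dropped with a warning.
    """
    cyto = np.asarray(cyto, dtype=bool)
    nuclei = np.asarray(nuclei, dtype=bool)
    inside = nuclei & cyto
    if (nuclei & ~cyto).any():
        warnings.warn("nucleus pixels outside the cytoplasm mask were dropped",
                      stacklevel=2)
    markers, n = ndi.label(inside, structure=_EIGHT)
    if n == 0:
        return np.zeros(cyto.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(cyto)
    return watershed(-distance, markers, mask=cyto,
                     watershed_line=True).astype(np.int32)


# --- region measurement -----------------------------------------------------

#: Moore neighborhood in clockwise order starting west (rows grow downward).
_CLOCKWISE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
)
_SQRT2 = math.sqrt(2.0)


def boundary_chain_length(mask: np.ndarray) -> float:
    """Length of the closed 8-connected outer boundary chain of one region.

    Moore-neighbor tracing; orthogonal steps count 1 and diagonal steps
    sqrt(2).  A single pixel has chain length 0 by convention.  ``mask``
    must contain exactly one 8-connected region.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValidationError("empty region")
    if pts.shape[0] == 1:
        return 0.0
    padded = np.pad(mask, 1)

    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = (int(pts[order[0], 0]) + 1, int(pts[order[0], 1]) + 1)

    def next_on_boundary(p, backtrack):
        rel = (backtrack[0] - p[0], backtrack[1] - p[1])
        k = _CLOCKWISE.index(rel)
        for j in range(1, 9):
            off = _CLOCKWISE[(k + j) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if padded[q]:
                before = _CLOCKWISE[(k + j - 1) % 8]
                return q, (p[0] + before[0], p[1] + before[1])
        raise AssertionError("unreachable: region has >1 pixel")

    # The start pixel is topmost-leftmost, so its west neighbor is background.
    p, backtrack = start, (start[0], start[1] - 1)
    q, next_backtrack = next_on_boundary(p, backtrack)
    first_move = (p, q)
    length = 0.0
    for _ in range(8 * pts.shape[0] + 8):
        step = abs(q[0] - p[0]) + abs(q[1] - p[1])
        length += _SQRT2 if step == 2 else 1.0
        p, backtrack = q, next_backtrack
        q, next_backtrack = next_on_boundary(p, backtrack)
        if (p, q) == first_move:
            return length
    raise AssertionError("boundary trace did not close")


@dataclass(frozen=True)
class RegionRecord:
    """Geometry of one labeled connected region."""

    label: int
    area: int
    perimeter: float
    centroid: tuple[float, float]
    circularity: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive


@dataclass
class RegionTable:
    """A collection of measured regions."""

    records: list[RegionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.records],
                "area": [r.area for r in self.records],
                "perimeter": [r.perimeter for r in self.records],
                "centroid_row": [r.centroid[0] for r in self.records],
                "centroid_col": [r.centroid[1] for r in self.records],
                "circularity": [r.circularity for r in self.records],
            }
        )


def measure_regions(mask_or_labels: np.ndarray) -> RegionTable:
    """Measure area, chain perimeter, centroid and circularity per region.

    Accepts a boolean mask (labeled internally with 8-connectivity) or an
    integer label map.  Circularity is ``min(1, 4*pi*A / P^2)`` with P the
    outer boundary chain length; single-pixel regions get circularity 1.
    """
    arr = np.asarray(mask_or_labels)
    if arr.dtype == bool:
        labels, _ = ndi.label(arr, structure=_EIGHT)
    else:
        labels = arr.astype(np.int64)
    records: list[RegionRecord] = []
    objects = ndi.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == idx
        area = int(region.sum())
        perim = boundary_chain_length(region)
        rows, cols = np.nonzero(region)
        centroid = (
            float(rows.mean() + sl[0].start),
            float(cols.mean() + sl[1].start),
        )
        if perim == 0.0:
            circ = 1.0
        else:
            circ = min(1.0, 4.0 * math.pi * area / perim**2)
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        records.append(RegionRecord(idx, area, perim, centroid, circ, bbox))
    return RegionTable(records)


def filter_micronuclei(
    candidates: RegionTable, params: DetectionParams
) -> RegionTable:
    """Accept candidates with area >= noise floor and circularity >= MN TH."""
    kept = [
        r
        for r in candidates
        if r.area >= params.noise_reduction
        and r.circularity >= params.micronucleus_th
    ]
    return RegionTable(kept)


# --- cell classification ----------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One scored cell: its cytoplasm label, nucleus, and assigned MN."""

    cell_id: int
    cytoplasm_label: int
    nucleus_label: int | None
    mn_labels: frozenset[int]

    @property
    def is_mn_cell(self) -> bool:
        return len(self.mn_labels) > 0


def _label_at_centroid(cell_labels: np.ndarray,
                       centroid: tuple[float, float]) -> int:
    r = int(round(centroid[0]))
    c = int(round(centroid[1]))
    h, w = cell_labels.shape
    if not (0 <= r < h and 0 <= c < w):
        return 0
    return int(cell_labels[r, c])


def classify_cells(
    cell_labels: np.ndarray,
    nuclei: RegionTable,
    accepted_mn: RegionTable,
) -> list[CellRecord]:
    """Build one record per cell label and assign accepted micronuclei.

    A micronucleus belongs to the cell whose label contains its centroid;
    micronuclei whose centroid falls on a watershed line or on background
    are discarded.  A cell with one or more assigned micronuclei is one MN
    cell regardless of the number of micronuclei.
    """
    cell_labels = np.asarray(cell_labels)
    cell_ids = np.unique(cell_labels)
    cell_ids = cell_ids[cell_ids > 0]

    nucleus_of: dict[int, int] = {}
    for rec in nuclei:
        cid = _label_at_centroid(cell_labels, rec.centroid)
        if cid > 0 and cid not in nucleus_of:
            nucleus_of[cid] = rec.label

    mn_of: dict[int, set[int]] = {int(cid): set() for cid in cell_ids}
    for rec in accepted_mn:
        cid = _label_at_centroid(cell_labels, rec.centroid)
        if cid > 0:
            mn_of[cid].add(rec.label)

    return [
        CellRecord(
            cell_id=int(cid),
            cytoplasm_label=int(cid),
            nucleus_label=nucleus_of.get(int(cid)),
            mn_labels=frozenset(mn_of[int(cid)]),
        )
        for cid in cell_ids
    ]


@dataclass
class ImageResult:
    """Counts, per-cell records, parameters and intermediate masks."""

    name: str
    total_cells: int
    mn_cells: int
    cells: list[CellRecord]
    params: DetectionParams
    green_binary: np.ndarray
    nuclei_mask: np.ndarray
    mn_candidate_mask: np.ndarray
    cytoplasm: np.ndarray
    cell_labels: np.ndarray
    accepted_mn: RegionTable

    def __post_init__(self) -> None:
        assert self.total_cells == len(self.cells)
        assert self.mn_cells == sum(c.is_mn_cell for c in self.cells)
        assert self.mn_cells <= self.total_cells


def _drop_border_cells(cell_labels: np.ndarray) -> np.ndarray:
    # mask cleanup treats outside as background, so a truncated cell can sit
    # one pixel off the frame edge; test contact on a 2 px band
    band = np.concatenate(
        [
            cell_labels[:2].ravel(), cell_labels[-2:].ravel(),
            cell_labels[:, :2].ravel(), cell_labels[:, -2:].ravel(),
        ]
    )
    on_border = np.unique(band)
    on_border = on_border[on_border > 0]
    out = cell_labels.copy()
    out[np.isin(out, on_border)] = 0
    return out


def analyze_image(
    micrograph: RGBMicrograph,
    params: DetectionParams | None = None,
    exclude_border: bool = False,
) -> ImageResult:
    """Run the full pipeline on one micrograph.

    With ``params=None`` the parameters are initialized automatically from
    the green histogram (binarization TH) and the nucleus-size pre-pass
    (kernel and noise floor).  Cells touching the image border are counted
    by default, so the whole imaged field is scored; ``exclude_border``
    drops them.  The analysis is deterministic: identical input and
    parameters give an identical result.
    """
    red, green = split_channels(micrograph)
    if params is None:
        params = auto_detection_params(green.pixels)

    green_binary = clean_mask(
        binarize(green.pixels, params.binarization_th), params.kernel_s
    )
    nuclei_mask, mn_candidate_mask = classify_blobs_by_erosion(
        green_binary, params.kernel_l
    )
    mn_candidates = measure_regions(mn_candidate_mask)
    accepted_mn = filter_micronuclei(mn_candidates, params)

    cyto = cytoplasm_mask(red.pixels, green.pixels, params)
    cell_labels = separate_cells(cyto, nuclei_mask)
    if exclude_border:
        cell_labels = _drop_border_cells(cell_labels)

    nuclei_table = measure_regions(nuclei_mask.astype(bool))
    cells = classify_cells(cell_labels, nuclei_table, accepted_mn)

    return ImageResult(
        name=micrograph.path if micrograph.path else "<memory>",
        total_cells=len(cells),
        mn_cells=sum(c.is_mn_cell for c in cells),
        cells=cells,
        params=params,
        green_binary=green_binary,
        nuclei_mask=nuclei_mask,
        mn_candidate_mask=mn_candidate_mask,
        cytoplasm=cyto,
        cell_labels=cell_labels,
        accepted_mn=accepted_mn,
    )
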