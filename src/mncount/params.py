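"""The six-parameter detection model and its plain-text parameter files.

Every image analysis is governed by six tunable values: a green-channel
binarization threshold, two square structuring-element widths (a small one
for mask cleanup, a large one that sets the nucleus-vs-micronucleus size
cut), a minimum area below which green specks are discarded as noise, a
circularity threshold for accepting micronuclei, and the center of the
sigmoid gradation that emphasizes the cytoplasm.  The sigmoid gain is a
seventh, configuration-level knob kept out of the six-line parameter file
so the file format stays fixed.

The same six-line dialect serves both the per-image ``Palam`` files written
during an analysis run and the ``PalamLock.txt`` file that drives batch
reanalysis.  Line order: binarization TH, kernel S, kernel L, noise
reduction, micronucleus TH, window level.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import FormatError, ValidationError

__all__ = [
    "DetectionParams",
    "GreenHistogram",
    "BINARIZATION_LEVELS",
    "DEFAULT_TH_BINS",
    "auto_binarization_th",
    "default_params",
    "estimate_nucleus_diameter",
    "auto_detection_params",
    "write_palam",
    "read_palam",
]

#: The five representative binarization thresholds selectable automatically.
BINARIZATION_LEVELS = (65, 75, 85, 120, 165)

#: Upper-exclusive bin edges on the green-histogram peak intensity that map a
#: peak to one of the five levels (peak < 50 -> 65, 50-69 -> 75, 70-99 -> 85,
#: 100-149 -> 120, >= 150 -> 165).  Overridable via ``auto_binarization_th``.
DEFAULT_TH_BINS = (50, 70, 100, 150)

#: Default sigmoid gain g (per intensity unit) used when none is configured.
DEFAULT_SIGMOID_GAIN = 0.05

#: Fallback nucleus equivalent diameter (px) when the coarse pre-pass finds
#: no usable nuclei (blank or degenerate images).
FALLBACK_NUCLEUS_DIAMETER = 20.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DetectionParams:
    """The six tunable parameters governing one image's analysis.

    Parameters
    ----------
    binarization_th:
        Green-channel intensity cutoff (0-255); pixels >= th are foreground.
    kernel_s:
        Odd width (>= 3) of the small square structuring element used to
        fill pinholes and remove speckle after binarization.
    kernel_l:
        Odd width (> kernel_s) of the large square structuring element whose
        erosion separates nuclei (survive) from micronuclei (vanish).
    noise_reduction:
        Minimum region area in px^2; smaller green remnants are noise.
    micronucleus_th:
        Circularity threshold in [0, 1]; eroded-away blobs below it are
        rejected as debris.  1 accepts only perfectly round spots.
    window_level:
        Center intensity c of the sigmoid gradation emphasizing cytoplasm.
    sigmoid_gain:
        Sigmoid steepness g > 0.  Configuration-level; not serialized.
    """

    binarization_th: int
    kernel_s: int
    kernel_l: int
    noise_reduction: int
    micronucleus_th: float
    window_level: int
    sigmoid_gain: float = DEFAULT_SIGMOID_GAIN

    def __post_init__(self) -> None:
        if not 0 <= self.binarization_th <= 255:
            raise ValidationError(
                f"binarization_th must be in [0, 255], got {self.binarization_th}"
            )
        for name in ("kernel_s", "kernel_l"):
            k = getattr(self, name)
            if k < 3 or k % 2 == 0:
                raise ValidationError(f"{name} must be odd and >= 3, got {k}")
        if self.kernel_s >= self.kernel_l:
            raise ValidationError(
                f"kernel_s ({self.kernel_s}) must be smaller than "
                f"kernel_l ({self.kernel_l})"
            )
        if self.noise_reduction < 0:
            raise ValidationError(
                f"noise_reduction must be >= 0, got {self.noise_reduction}"
            )
        if not 0.0 <= self.micronucleus_th <= 1.0:
            raise ValidationError(
                f"micronucleus_th must be in [0, 1], got {self.micronucleus_th}"
            )
        if not 0 <= self.window_level <= 255:
            raise ValidationError(
                f"window_level must be in [0, 255], got {self.window_level}"
            )
        if self.sigmoid_gain <= 0:
            raise ValidationError(
                f"sigmoid_gain must be > 0, got {self.sigmoid_gain}"
            )

    def replace(self, **overrides) -> "DetectionParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class GreenHistogram:
    """256-bin intensity tally of a green channel image.

    The peak excludes bin 0, which is dominated by true background; ties
    break toward the lower intensity.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValidationError(
                f"histogram must have 256 bins, got shape {counts.shape}"
            )
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_image(cls, green: np.ndarray) -> "GreenHistogram":
        green = np.asarray(green)
        if green.dtype != np.uint8:
            raise ValidationError("green channel must be 8-bit")
        return cls(np.bincount(green.ravel(), minlength=256))

    @property
    def peak_intensity(self) -> int:
        """Modal nonzero intensity (0 when no nonzero pixel exists)."""
        nonzero = self.counts[1:]
        if nonzero.sum() == 0:
            return 0
        return int(np.argmax(nonzero)) + 1


def auto_binarization_th(
    hist: GreenHistogram,
    bins: tuple[int, ...] = DEFAULT_TH_BINS,
    levels: tuple[int, ...] = BINARIZATION_LEVELS,
) -> int:
    """Select one of the representative binarization thresholds.

    The modal nonzero green intensity is mapped monotonically onto the five
    representative levels: a brighter histogram peak yields a higher
    threshold.  A blank image (no nonzero pixel) falls back to the lowest
    level with a warning.
    """
    if len(levels) != len(bins) + 1:
        raise ValidationError("need exactly one more level than bin edge")
    peak = hist.peak_intensity
    if peak == 0:
        warnings.warn(
            "green histogram has no nonzero intensities; "
            f"falling back to binarization TH {levels[0]}",
            stacklevel=2,
        )
        return levels[0]
    idx = int(np.searchsorted(np.asarray(bins), peak, side="right"))
    return levels[idx]


def default_params(
    nucleus_diameter_estimate: float,
    binarization_th: int = 85,
    sigmoid_gain: float = DEFAULT_SIGMOID_GAIN,
) -> DetectionParams:
    """Build the default parameter set for a given nucleus size.

    The large kernel scales with the nucleus equivalent diameter
    (``odd >= max(7, round(0.6 * diameter))``) so that nuclei survive the
    erosion step while micronuclei do not; the noise floor follows the
    kernel (11 px^2 up to kernel 15, else 21 px^2).  Micronucleus TH 0.5 and
    window level 118 are the fixed defaults of the method.
    """
    if nucleus_diameter_estimate < 6:
        raise ValidationError(
            "nucleus diameter estimate must be >= 6 px "
            f"(got {nucleus_diameter_estimate}); image scale too small"
        )
    k = max(7, _round_half_up(0.6 * nucleus_diameter_estimate))
    if k % 2 == 0:
        k += 1
    noise = 11 if k <= 15 else 21
    return DetectionParams(
        binarization_th=binarization_th,
        kernel_s=3,
        kernel_l=k,
        noise_reduction=noise,
        micronucleus_th=0.5,
        window_level=118,
        sigmoid_gain=sigmoid_gain,
    )


def estimate_nucleus_diameter(
    green: np.ndarray,
    min_area: float = 50.0,
    fallback: float = FALLBACK_NUCLEUS_DIAMETER,
) -> float:
    """Coarse pre-pass estimate of the median nucleus equivalent diameter.

    Binarizes the green channel at Otsu's threshold and takes the
    area-weighted median equivalent diameter (``sqrt(4A/pi)``) of
    8-connected components larger than ``min_area`` px^2.  Weighting by
    area keeps the estimate anchored on the nuclei, which dominate the
    green foreground, even when many micronucleus-sized spots or debris
    streaks clear the area floor.  Degenerate images (constant, foreground
    covering most of the frame, or no components above ``min_area``) fall
    back to a 20 px default with a warning.  The estimate is clipped to
    [6, 80] px so a pathological frame cannot request an absurd kernel.
    """
    green = np.asarray(green)
    if green.min() == green.max():
        warnings.warn(
            "constant green channel; using fallback nucleus diameter",
            stacklevel=2,
        )
        return fallback
    mask = green >= threshold_otsu(green)
    if mask.mean() > 0.5:
        warnings.warn(
            "Otsu pre-pass selected most of the frame; "
            "using fallback nucleus diameter",
            stacklevel=2,
        )
        return fallback
    labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        warnings.warn("no green components; using fallback nucleus diameter",
                      stacklevel=2)
        return fallback
    areas = np.bincount(labels.ravel())[1:]
    areas = areas[areas > min_area]
    if areas.size == 0:
        warnings.warn(
            "no green component larger than the pre-pass area floor; "
            "using fallback nucleus diameter",
            stacklevel=2,
        )
        return fallback
    order = np.argsort(areas)
    areas = areas[order]
    diameters = np.sqrt(4.0 * areas / np.pi)
    # area-weighted median diameter
    cumulative = np.cumsum(areas)
    idx = int(np.searchsorted(cumulative, cumulative[-1] / 2.0))
    return float(np.clip(diameters[idx], 6.0, 80.0))


def auto_detection_params(
    green: np.ndarray,
    th_bins: tuple[int, ...] = DEFAULT_TH_BINS,
    sigmoid_gain: float = DEFAULT_SIGMOID_GAIN,
) -> DetectionParams:
    """Full automatic initialization from a green channel image."""
    hist = GreenHistogram.from_image(green)
    th = auto_binarization_th(hist, bins=th_bins)
    diameter = estimate_nucleus_diameter(green)
    return default_params(diameter, binarization_th=th,
                          sigmoid_gain=sigmoid_gain)


# --- Palam / PalamLock dialect ---------------------------------------------

_PALAM_FIELDS = (
    ("binarization_th", int),
    ("kernel_s", int),
    ("kernel_l", int),
    ("noise_reduction", int),
    ("micronucleus_th", float),
    ("window_level", int),
)


def write_palam(params: DetectionParams, path: str | Path) -> Path:
    """Write the six parameter values, one per line, in the fixed order."""
    path = Path(path)
    values = [getattr(params, name) for name, _ in _PALAM_FIELDS]
    text = "\n".join(repr(v) if isinstance(v, float) else str(v)
                     for v in values)
    path.write_text(text + "\n", encoding="utf-8")
    return path


def read_palam(
    path: str | Path,
    sigmoid_gain: float = DEFAULT_SIGMOID_GAIN,
) -> DetectionParams:
    """Parse a Palam/PalamLock file back into a parameter set.

    Raises :class:`FormatError` citing the offending line number when the
    file has the wrong line count or an unparsable value.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    while lines and lines[-1].strip() == "":
        lines.pop()
    if len(lines) != len(_PALAM_FIELDS):
        raise FormatError(
            f"{path}: line {len(lines) + 1}: expected "
            f"{len(_PALAM_FIELDS)} lines, found {len(lines)}"
        )
    kwargs = {}
    for i, ((name, cast), raw) in enumerate(zip(_PALAM_FIELDS, lines), start=1):
        try:
            kwargs[name] = cast(raw.strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {i}: cannot parse {name!r} from {raw!r}"
            ) from exc
    try:
        return DetectionParams(sigmoid_gain=sigmoid_gain, **kwargs)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
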