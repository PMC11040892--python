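"""Folder-level workflows: initial analysis, individual and batch reanalysis.

An initial analysis walks a folder of micrographs in filename order,
derives each image's parameters automatically, writes every artifact of
the six-folder results tree, stores one Palam parameter file per image and
seeds a ``PalamLock.txt`` from the first image's parameters.  Individual
reanalysis re-runs a single image with overrides merged onto its stored
parameters; batch reanalysis re-runs the whole folder with the single
parameter set in ``PalamLock.txt``.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .detect import ImageResult, analyze_image
from .errors import MNCountError, StateError, ValidationError
from .io import (
    OutputTree,
    read_rgb_micrograph,
    render_outputs,
    write_counts_text,
)
from .params import DetectionParams, read_palam, write_palam

__all__ = [
    "IMAGE_EXTENSIONS",
    "initial_analysis",
    "individual_reanalysis",
    "batch_reanalysis",
]

logger = logging.getLogger("mncount")

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}


def _image_files(folder: Path) -> list[Path]:
    return sorted(
        p
        for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def _run_one(
    path: Path,
    params: DetectionParams | None,
    tree: OutputTree,
    exclude_border: bool,
    th_bins=None,
    sigmoid_gain: float | None = None,
) -> ImageResult:
    micrograph = read_rgb_micrograph(path)
    if params is None and (th_bins is not None or sigmoid_gain is not None):
        from .params import auto_detection_params

        green = micrograph.pixels[:, :, 1]
        kwargs = {}
        if th_bins is not None:
            kwargs["th_bins"] = tuple(th_bins)
        if sigmoid_gain is not None:
            kwargs["sigmoid_gain"] = sigmoid_gain
        params = auto_detection_params(green, **kwargs)
    result = analyze_image(micrograph, params, exclude_border=exclude_border)
    render_outputs(micrograph, result.cell_labels, result.accepted_mn, tree,
                   stem=path.stem)
    write_palam(result.params, tree.folder("Palam") / f"{path.stem}.txt")
    logger.info(
        "%s: %d cells, %d MN cells (TH %d, kernel %d/%d, noise %d, "
        "MN TH %.2f, window %d)",
        path.name, result.total_cells, result.mn_cells,
        result.params.binarization_th, result.params.kernel_s,
        result.params.kernel_l, result.params.noise_reduction,
        result.params.micronucleus_th, result.params.window_level,
    )
    return result


def initial_analysis(
    folder: str | Path,
    results_root: str | Path,
    exclude_border: bool = False,
    th_bins=None,
    sigmoid_gain: float | None = None,
) -> tuple[OutputTree, list[ImageResult], list[Path]]:
    """Analyze every image in a folder with automatic parameters.

    Returns the output tree, the per-image results (filename order) and
    the list of files that failed and were skipped.  Raises
    :class:`ValidationError` when the folder holds no candidate images.
    """
    folder = Path(folder)
    files = _image_files(folder)
    if not files:
        raise ValidationError(f"no images to analyze in {folder}")
    tree = OutputTree.create(results_root)
    results: list[ImageResult] = []
    failures: list[Path] = []
    for path in files:
        try:
            results.append(
                _run_one(path, None, tree, exclude_border,
                         th_bins=th_bins, sigmoid_gain=sigmoid_gain)
            )
        except MNCountError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            failures.append(path)
    if not results:
        raise ValidationError(f"every image in {folder} failed to analyze")
    write_palam(results[0].params, tree.root / "Palam" / "PalamLock.txt")
    write_counts_text(results, tree)
    return tree, results, failures


def individual_reanalysis(
    image: str | Path,
    results_root: str | Path,
    overrides: dict | None = None,
    exclude_border: bool = False,
) -> ImageResult:
    """Re-run one image with overrides merged onto its stored parameters.

    Only that image's artifacts and Palam file are rewritten.  Requires a
    prior initial analysis (the stored Palam file supplies the base
    parameters).
    """
    image = Path(image)
    tree = OutputTree.create(results_root)
    palam_path = tree.folder("Palam") / f"{image.stem}.txt"
    if not palam_path.exists():
        raise StateError(
            f"no stored parameters for {image.name}; run the initial "
            "analysis first"
        )
    params = read_palam(palam_path)
    if overrides:
        params = params.replace(**overrides)
    return _run_one(image, params, tree, exclude_border)


def batch_reanalysis(
    folder: str | Path,
    palamlock_path: str | Path,
    results_root: str | Path,
    exclude_border: bool = False,
) -> tuple[OutputTree, list[ImageResult], list[Path]]:
    """Re-run every image in a folder with the single PalamLock parameter set.

    Per-image Palam files are overwritten with the PalamLock values and the
    counts file is regenerated.
    """
    folder = Path(folder)
    params = read_palam(palamlock_path)
    files = _image_files(folder)
    if not files:
        raise ValidationError(f"no images to analyze in {folder}")
    tree = OutputTree.create(results_root)
    results: list[ImageResult] = []
    failures: list[Path] = []
    for path in files:
        try:
            results.append(_run_one(path, params, tree, exclude_border))
        except MNCountError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            failures.append(path)
    if not results:
        raise ValidationError(f"every image in {folder} failed to analyze")
    write_counts_text(results, tree)
    return tree, results, failures
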