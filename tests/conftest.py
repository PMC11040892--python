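import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mncount.detect import DetectionParams
from mncount.synth import SynthSpec, generate_micrograph

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_params() -> DetectionParams:
    return DetectionParams(
        binarization_th=65,
        kernel_s=3,
        kernel_l=13,
        noise_reduction=11,
        micronucleus_th=0.5,
        window_level=118,
    )


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    # small field for fast tests: 8 well-separated cells
    return SynthSpec(height=512, width=512, n_cells=8, mn_cell_rate=0.25,
                     seed=11)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_micrograph(small_spec)


@pytest.fixture(scope="session")
def synth_folder(tmp_path_factory):
    """Folder of three small synthetic micrographs plus their truths."""
    import tifffile

    folder = tmp_path_factory.mktemp("micrographs")
    truths = []
    for i, seed in enumerate((21, 22, 23)):
        spec = SynthSpec(height=512, width=512, n_cells=6, mn_cell_rate=0.3,
                         seed=seed)
        micrograph, truth = generate_micrograph(spec)
        tifffile.imwrite(folder / f"img_{i:02d}.tiff", micrograph.pixels)
        truths.append(truth)
    return folder, truths


def random_masks(n: int, max_side: int = 32, seed: int = 12345):
    """Seeded stream of random boolean masks of varying size/density."""
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n):
        h = int(rng.integers(4, max_side + 1))
        w = int(rng.integers(4, max_side + 1))
        p = rng.uniform(0.2, 0.7)
        masks.append(rng.random((h, w)) < p)
    return masks
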