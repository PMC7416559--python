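import numpy as np
import pytest

from ecmarch import segmentation as seg
from ecmarch import synthetic_data as sd


def make_single_fiber(width, noise_sd=0.0, seed=3, size=128, blur=1.0):
    """Horizontal single-fiber image with exact ground truth."""
    spec = sd.FiberImageSpec(
        image_size=(size, size),
        n_fibers=1,
        diameter_mean=width,
        diameter_sd=0.0,
        orientation_mu=0.0,
        orientation_kappa=1e9,
        blur_sigma=blur,
        noise_sd=noise_sd,
        seed=seed,
    )
    return sd.generate_fiber_image(spec)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return (a & b).sum() / (a | b).sum()


@pytest.fixture(scope="session")
def fiber_scene():
    """A moderately dense noisy fibrous scene with ground truth."""
    spec = sd.FiberImageSpec(
        image_size=(128, 128),
        n_fibers=15,
        diameter_mean=5.0,
        diameter_sd=1.0,
        orientation_kappa=0.0,
        blur_sigma=1.0,
        noise_sd=0.05,
        seed=5,
    )
    return sd.generate_fiber_image(spec)


@pytest.fixture(scope="session")
def sparse_labels(fiber_scene):
    """500 annotated pixels per class drawn from the scene's ground truth."""
    _, truth = fiber_scene
    rng = np.random.default_rng(0)
    labels = np.full(truth.true_mask.shape, -1)
    for coords, val in (
        (np.argwhere(truth.true_mask.pixels), 1),
        (np.argwhere(~truth.true_mask.pixels), 0),
    ):
        sel = coords[rng.choice(len(coords), 500, replace=False)]
        labels[sel[:, 0], sel[:, 1]] = val
    return labels


@pytest.fixture(scope="session")
def trained_classifier(fiber_scene, sparse_labels):
    image, _ = fiber_scene
    return seg.train_pixel_classifier(image, sparse_labels, seed=0)


def plus_mask(size=60, width=5):
    """Union of a horizontal and a vertical bar crossing at the center."""
    m = np.zeros((size, size), dtype=bool)
    mid = size // 2
    half = width // 2
    m[mid - half : mid + half + 1, :] = True
    m[:, mid - half : mid + half + 1] = True
    return seg.BinaryMask(m)
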