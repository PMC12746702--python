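import warnings

import numpy as np
import pytest

from ovomorph import (
    SceneSpec,
    render_scene,
    sample_population,
    young_population,
)
from ovomorph.segmentation import segment_cells, segment_nuclei

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_scene():
    """A noise-free 20-cell scene with truth, shared across tests."""
    pop = young_population()
    params = sample_population(pop, 20, seed=42)
    scene = SceneSpec(image_shape=(900, 900), n_cells=20, seed=42)
    image, truth = render_scene(params, scene)
    return image, truth, params


@pytest.fixture(scope="session")
def segmented_scene(small_scene):
    """Segmentation of the shared scene (membrane channel for cell borders)."""
    image, truth, _ = small_scene
    nuclei = segment_nuclei(image)
    cells = segment_cells(image, "membrane", nuclei)
    return image, truth, nuclei, cells


def best_iou(truth_mask: np.ndarray, labels: np.ndarray) -> float:
    """IoU of a truth mask with its best-overlapping predicted label."""
    cand = np.unique(labels[truth_mask])
    cand = cand[cand > 0]
    best = 0.0
    for l in cand:
        pred = labels == l
        best = max(best, (truth_mask & pred).sum() / (truth_mask | pred).sum())
    return best
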