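import numpy as np
import pytest

from lamincycle import PHASE_PRESETS, PHASES, render_cell
from lamincycle.colocalization import cell_mask_from_channels
from lamincycle.imaging_core import extract_features, morphology_mask


def gallery_cell_seed(gallery_seed: int, phase_index: int, i: int) -> int:
    """Deterministic per-cell seed used by make_gallery."""
    return (gallery_seed * 100_003 + phase_index * 1_009 + i) % (2**31)


def analyze_rendered(cell):
    """Derive masks and features from a rendered cell the pipeline way."""
    img = cell.image
    cell_mask = cell_mask_from_channels(img.channel("laminA"), img.channel("tubulin"))
    nucleus = morphology_mask(img.channel("chromatin"))
    masks = {"cell": cell_mask, "nucleus": nucleus}
    return img, masks, extract_features(img, masks)


@pytest.fixture(scope="session")
def interphase_cell():
    return render_cell(PHASE_PRESETS["interphase"], seed=0)


@pytest.fixture(scope="session")
def gallery():
    """10 cells per phase (gallery seed 0) with pipeline-derived masks/features."""
    out = []
    for pi, phase in enumerate(PHASES):
        for i in range(10):
            cell = render_cell(PHASE_PRESETS[phase], gallery_cell_seed(0, pi, i))
            img, masks, features = analyze_rendered(cell)
            out.append({"image": img, "masks": masks, "features": features, "phase": phase})
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
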