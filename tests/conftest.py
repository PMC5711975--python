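"""Shared fixtures: small synthetic slides generated once per session."""
from __future__ import annotations

import numpy as np
import pytest

from ciquant import synthetic
from ciquant.datatypes import RegionMasks


def small_slide_params(**overrides) -> synthetic.SyntheticSlideParams:
    fields = dict(
        image_size=(512, 512),
        n_groups=12,
        group_size_range=(3, 8),
        individualized_cell_fraction=0.02,
        tumor_core_fraction=0.04,
        n_stromal_cells=15,
        noise_level=0.0,
        seed=42,
    )
    fields.update(overrides)
    return synthetic.SyntheticSlideParams(**fields)


@pytest.fixture(scope="session")
def noisefree_slide():
    """A small noise-free IDC slide with its ground truth."""
    params = small_slide_params()
    image, truth = synthetic.generate_slide(params)
    return params, image, truth


@pytest.fixture(scope="session")
def noisy_slide():
    """The same geometry rendered with the default noise level."""
    params = small_slide_params(noise_level=1.0)
    image, truth = synthetic.generate_slide(params)
    return params, image, truth


@pytest.fixture()
def truth_masks(noisefree_slide):
    """RegionMasks built from the generator's exact masks."""
    _, _, truth = noisefree_slide
    return RegionMasks(
        tissue=truth.tissue_mask,
        adipose=truth.adipose_mask,
        tumor=truth.tumor_mask,
        exclusion=truth.exclusion_mask,
        core=truth.core_mask,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
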