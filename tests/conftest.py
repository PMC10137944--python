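import numpy as np
import pytest

from hepaploidy import SyntheticPatchSpec, generate_if_patch, generate_labelled_mask


@pytest.fixture(scope="session")
def if_spec():
    """Well-separated fluorescence-like layout used across segmentation tests."""
    return SyntheticPatchSpec(n_cells=10, binuclear_fraction=0.4, seed=1)


@pytest.fixture(scope="session")
def if_patch(if_spec):
    return generate_if_patch(if_spec)


@pytest.fixture(scope="session")
def separable_mask():
    """Labelled mask whose sibling/inter-cell gaps straddle the 15.54 px
    threshold and whose per-class areas are widely separated, so every
    downstream stage can be checked against the truth exactly."""
    spec = SyntheticPatchSpec(
        height=620, width=620, n_cells=45, binuclear_fraction=0.4,
        nucleus_radius_mean=6.0, nucleus_radius_sd=0.25,
        intra_cell_nucleus_gap=4.0, min_inter_cell_gap=20.0,
        ploidy_class_fractions=(0.6, 0.25, 0.15), area_multiplier=1.55,
        seed=11)
    labels, classes, truth = generate_labelled_mask(spec)
    return spec, labels, classes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
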