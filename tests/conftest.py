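import numpy as np
import pytest

from atlaskit import (
    SyntheticConfig,
    generate_feature_table,
    generate_label_cohort,
    load_reference_cohort,
)


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 30-subject reference cohort."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def syn_config():
    """Study-scale synthetic configuration: 10 subjects on a 64^3, 2 mm grid."""
    return SyntheticConfig(seed=7, n_subjects=10)


@pytest.fixture(scope="session")
def syn_cohort(syn_config):
    """Rasterised synthetic cohort (labels, masks, truth), shared across tests."""
    labels, masks, truth = generate_label_cohort(syn_config)
    return labels, masks, truth


@pytest.fixture(scope="session")
def syn_table(syn_config, syn_cohort):
    """Feature table belonging to the shared synthetic cohort."""
    _, _, truth = syn_cohort
    return generate_feature_table(syn_config, truth)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale configuration (32^3 grid) for fast geometric unit tests."""
    return SyntheticConfig(
        seed=11,
        n_subjects=4,
        grid_shape=(32, 32, 32),
        shell_inner_mm=10.0,
        shell_outer_mm=16.0,
        torque_shift_mm=4.0,
        deform_amplitude_mm=1.0,
        deform_smoothness_mm=6.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    labels, masks, truth = generate_label_cohort(tiny_config)
    return labels, masks, truth


def make_block_volume(code=84, shape=(20, 20, 20), block=None, voxel_mm=1.0, space="native"):
    """A label volume containing one rectangular block of a single code."""
    from atlaskit import LabelVolume

    grid = np.zeros(shape, dtype=np.int32)
    block = block if block is not None else (slice(5, 15), slice(5, 15), slice(5, 15))
    grid[block] = code
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return LabelVolume(grid=grid, affine=affine, space=space)
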