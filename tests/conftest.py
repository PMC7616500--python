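import pytest

from stitchkit import fixtures


@pytest.fixture
def small_spec() -> fixtures.FixtureSpec:
    """A small, fast capture-area spec used across test modules."""
    return fixtures.FixtureSpec(
        seed=7, grid_rows=4, grid_cols=6, n_genes=12, image_shape=(60, 80), noise_sd=1.0
    )


@pytest.fixture
def three_sections(small_spec):
    areas, transforms = fixtures.make_overlapping_sections(small_spec, 3)
    return areas, transforms
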