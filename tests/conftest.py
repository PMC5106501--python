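import numpy as np
import pytest

from gliamorph import (
    SegmentationParams,
    SyntheticSpec,
    default_region,
    generate_image,
    make_preset,
)
from gliamorph.pipeline import domain_field_layout


@pytest.fixture(scope="session")
def ramified_preset():
    return make_preset("ramified_braak2")


@pytest.fixture(scope="session")
def dystrophic_preset():
    return make_preset("dystrophic_braak56")


def _separated_field(preset, seed, size_px=1024):
    sep, n, margin = domain_field_layout(preset, size_px, size_px, 0.5)
    spec = SyntheticSpec(
        preset=preset,
        width_px=size_px,
        height_px=size_px,
        px_size_um=0.5,
        region=default_region(size_px, size_px, margin),
        n_cells=n,
        min_separation_um=sep,
        seed=seed,
    )
    return generate_image(spec), spec


@pytest.fixture(scope="session")
def ramified_field(ramified_preset):
    """A 1024x1024 field of well-separated ramified cells (session-cached)."""
    return _separated_field(ramified_preset, seed=7)


@pytest.fixture(scope="session")
def dystrophic_field(dystrophic_preset):
    return _separated_field(dystrophic_preset, seed=7)


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
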