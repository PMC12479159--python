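import numpy as np
import pytest

from mitodyn.synthetic import CellGeometry, SyntheticCellSpec, generate_cell


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCellSpec:
    """Compact cell for fast unit tests (few mitochondria, short epoch)."""
    return SyntheticCellSpec(
        image_shape=(256, 256),
        nucleus_radius=4_000.0,
        cell_radius=12_000.0,
        n_mito=12,
        n_frames=8,
        perinuclear_fraction=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_geometry(small_spec) -> CellGeometry:
    return generate_cell(small_spec)


@pytest.fixture(scope="session")
def tmrm_spec() -> SyntheticCellSpec:
    """Cell sized for TMRM recovery tests: >=12 mitochondria per region."""
    return SyntheticCellSpec(
        image_shape=(384, 384),
        nucleus_radius=5_000.0,
        cell_radius=17_000.0,
        n_mito=60,
        perinuclear_fraction=0.35,
        seed=7,
    )


@pytest.fixture(scope="session")
def tmrm_geometry(tmrm_spec) -> CellGeometry:
    return generate_cell(tmrm_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
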