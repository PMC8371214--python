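"""Shared fixtures: synthetic ground truths and bead clouds built once."""

import numpy as np
import pytest

import igsas
from igsas.models import BeadModel, fill_ellipsoid


def bare_model(points: np.ndarray, region: str = "FAB1") -> BeadModel:
    """Wrap raw coordinates as a single-region bead model."""
    n = len(points)
    return BeadModel(points, np.arange(1, n + 1), np.array(["A"] * n, dtype=object),
                     np.array(["UNK"] * n, dtype=object),
                     np.array([region] * n, dtype=object))


@pytest.fixture(scope="session")
def igg3_truth():
    return igsas.make_ground_truth("igg3_like", seed=1)


@pytest.fixture(scope="session")
def compact_truth():
    return igsas.make_ground_truth("compact_control", seed=1)


@pytest.fixture(scope="session")
def sphere_2000():
    """Uniform bead sphere, radius 3 nm, ~2000 beads."""
    rng = np.random.default_rng(7)
    pts = fill_ellipsoid(2000, (3.0, 3.0, 3.0), rng, min_spacing=0.18)
    return bare_model(pts)


@pytest.fixture(scope="session")
def small_cloud():
    rng = np.random.default_rng(3)
    return bare_model(rng.normal(scale=2.0, size=(120, 3)))


def lattice_rod(radius: float = 1.0, length: float = 30.0,
                sxy: float = 0.15, sz: float = 0.5) -> np.ndarray:
    """Deterministic bead fill of a long cylinder (for cross-section tests)."""
    g = np.arange(-radius, radius + sxy / 2, sxy)
    zz = np.arange(-length / 2, length / 2 + sz / 2, sz)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    disk = np.column_stack([xx.ravel(), yy.ravel()])
    disk = disk[(disk ** 2).sum(axis=1) <= radius ** 2]
    return np.concatenate([np.column_stack([disk, np.full(len(disk), z)])
                           for z in zz])
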