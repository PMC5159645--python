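import numpy as np
import pytest

from rnasnap.structure_asa import AtomSet


@pytest.fixture
def single_atom() -> AtomSet:
    return AtomSet(
        names=["C1'"],
        elements=["C"],
        radii=np.array([1.9]),
        coords=np.array([[0.0, 0.0, 0.0]]),
        residue_index=np.array([0]),
        residue_base=["A"],
    )


def make_pair(d: float, r: float = 1.9) -> AtomSet:
    """Two equal atoms on the x axis at distance d."""
    return AtomSet(
        names=["C1'", "C2'"],
        elements=["C", "C"],
        radii=np.array([r, r]),
        coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        residue_index=np.array([0, 0]),
        residue_base=["A", "A"],
    )


@pytest.fixture
def random_cluster() -> AtomSet:
    """20 atoms in a compact random cluster (seeded)."""
    rng = np.random.default_rng(42)
    n = 20
    coords = rng.uniform(-5, 5, size=(n, 3))
    radii = rng.uniform(1.4, 1.9, size=n)
    return AtomSet(
        names=[f"C{i}" for i in range(n)],
        elements=["C"] * n,
        radii=radii,
        coords=coords,
        residue_index=np.zeros(n, dtype=int),
        residue_base=["A"] * n,
    )
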