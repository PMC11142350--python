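import numpy as np
import pytest

from atlasconcord.ontology import AtlasHierarchy, Region


def make_random_hierarchy(n: int, rng: np.random.Generator, name: str = "rand") -> AtlasHierarchy:
    """Uniform random recursive tree on n nodes (node i's parent < i)."""
    regions = [Region(1, "R1", "Region 1", "gray", None)]
    for i in range(2, n + 1):
        parent = int(rng.integers(1, i))
        regions.append(Region(i, f"R{i}", f"Region {i}", "gray", parent))
    return AtlasHierarchy(name, regions)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_hierarchy():
    """Root with two leaf children."""
    return AtlasHierarchy(
        "tiny",
        [
            Region(1, "ROOT", "Whole brain", "gray", None),
            Region(2, "A", "Area A", "gray", 1),
            Region(3, "B", "Area B", "gray", 1),
        ],
    )


@pytest.fixture
def layered_hierarchy():
    """A cortical area with layer children plus an unlayered sibling."""
    return AtlasHierarchy(
        "layers",
        [
            Region(1, "ROOT", "Whole brain", "gray", None),
            Region(2, "MO", "Primary motor area", "gray", 1),
            Region(3, "MO1", "Primary motor area, layer 1", "gray", 2),
            Region(4, "MO5", "Primary motor area, layer 5", "gray", 2),
            Region(5, "SS", "Somatosensory area", "gray", 1),
        ],
    )
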