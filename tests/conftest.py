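import numpy as np
import pytest

from tunnelmetrics import ChannelProfile, ProteinChannelSet, SphereNode


def random_profile(rng: np.random.Generator, n_nodes: int = 6,
                   channel_id: str = "T1") -> ChannelProfile:
    """A random walk centerline with positive radii: generic geometry input."""
    steps = rng.uniform(0.5, 3.0, size=(n_nodes - 1, 1)) * _unit_vectors(rng, n_nodes - 1)
    centers = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    radii = rng.uniform(0.5, 4.0, size=n_nodes)
    nodes = tuple(SphereNode(*c, r) for c, r in zip(centers, radii))
    return ChannelProfile(channel_id, nodes)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_channel_set(rng: np.random.Generator, n_channels: int = 3,
                       protein_id: str = "P1") -> ProteinChannelSet:
    channels = tuple(
        random_profile(rng, n_nodes=int(rng.integers(2, 9)), channel_id=f"T{i}")
        for i in range(n_channels)
    )
    return ProteinChannelSet(
        protein_id=protein_id, species="Methanococcus testii", enzyme="Mmr",
        subunit="alpha", source="predicted", channels=channels,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
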