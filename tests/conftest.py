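import numpy as np
import pytest

from layerprop.network import Layer, MultiLayerNetwork


def random_network(
    rng: np.random.Generator,
    layer_sizes: tuple[int, ...] = (15, 15),
    density: float = 0.4,
) -> MultiLayerNetwork:
    """Random K-layer network with dense-ish symmetric intra blocks."""
    layers = [
        Layer(f"L{k}", tuple(f"L{k}n{i}" for i in range(n)))
        for k, n in enumerate(layer_sizes)
    ]
    intra = []
    for n in layer_sizes:
        w = rng.random((n, n)) * (rng.random((n, n)) < density)
        w = np.triu(w, 1)
        intra.append(w + w.T)
    inter = [
        rng.random((layer_sizes[k], layer_sizes[k + 1]))
        * (rng.random((layer_sizes[k], layer_sizes[k + 1])) < density)
        for k in range(len(layer_sizes) - 1)
    ]
    return MultiLayerNetwork(layers, intra, inter)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_layer(rng):
    return random_network(rng, (12, 8))
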