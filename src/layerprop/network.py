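"""Multi-layered network data model.

A multi-layered network stratifies nodes into K ordered layers. Edges are
either *intra-layer* (both endpoints in one layer; each layer's weights form
a symmetric block with zero diagonal) or *inter-layer* (endpoints in two
*adjacent* layers, where adjacency is the declared layer order). The full
N x N weight matrix W is therefore block tri-diagonal with at most 3K - 2
non-zero blocks: K symmetric diagonal blocks and 2K - 2 banded rectangular
off-diagonal blocks.

Global node order is layer order, then within-layer declaration order; every
matrix and vector in this package uses that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class NetworkValidationError(ValueError):
    """Base class for invalid layered-network input."""


class UnknownNodeError(NetworkValidationError):
    """An edge endpoint does not resolve to a declared node id."""


class NonAdjacentLayerError(NetworkValidationError):
    """An inter-layer edge connects layers that are not consecutive."""


class NegativeWeightError(NetworkValidationError):
    """An edge carries a negative weight."""


class DuplicateEdgeError(NetworkValidationError):
    """The same undirected edge was supplied more than once."""


class SelfLoopError(NetworkValidationError):
    """An intra-layer edge connects a node to itself."""


@dataclass(frozen=True)
class Layer:
    """One stratum of the network.

    Parameters
    ----------
    name
        Layer identifier, unique within the network.
    node_ids
        Ordered node identifiers, unique within the layer.
    """

    name: str
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if len(self.node_ids) < 1:
            raise NetworkValidationError(f"layer {self.name!r} has no nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkValidationError(f"duplicate node ids in layer {self.name!r}")

    @property
    def size(self) -> int:
        return len(self.node_ids)


@dataclass
class MultiLayerNetwork:
    """Validated K-layer network with explicit weight blocks.

    Attributes
    ----------
    layers
        Ordered layers.
    intra_blocks
        One (n_k, n_k) symmetric non-negative array per layer, zero diagonal.
    inter_blocks
        One (n_p, n_{p+1}) non-negative array per adjacent layer pair.
    """

    layers: list[Layer]
    intra_blocks: list[np.ndarray]
    inter_blocks: list[np.ndarray]
    _offsets: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise NetworkValidationError("network needs at least one layer")
        if len({lay.name for lay in self.layers}) != len(self.layers):
            raise NetworkValidationError("duplicate layer names")
        if len(self.intra_blocks) != len(self.layers):
            raise NetworkValidationError("one intra block per layer required")
        if len(self.inter_blocks) != len(self.layers) - 1:
            raise NetworkValidationError("one inter block per adjacent pair required")
        offsets = [0]
        for lay, blk in zip(self.layers, self.intra_blocks):
            blk = np.asarray(blk, dtype=float)
            if blk.shape != (lay.size, lay.size):
                raise NetworkValidationError(
                    f"intra block of layer {lay.name!r} has shape {blk.shape}, "
                    f"expected {(lay.size, lay.size)}"
                )
            if not np.array_equal(blk, blk.T):
                raise NetworkValidationError(f"intra block of {lay.name!r} not symmetric")
            if (blk < 0).any():
                raise NegativeWeightError(f"negative weight in intra block {lay.name!r}")
            if np.diag(blk).any():
                raise SelfLoopError(f"non-zero diagonal in intra block {lay.name!r}")
            offsets.append(offsets[-1] + lay.size)
        for k, blk in enumerate(self.inter_blocks):
            blk = np.asarray(blk, dtype=float)
            expect = (self.layers[k].size, self.layers[k + 1].size)
            if blk.shape != expect:
                raise NetworkValidationError(
                    f"inter block {k} has shape {blk.shape}, expected {expect}"
                )
            if (blk < 0).any():
                raise NegativeWeightError(f"negative weight in inter block {k}")
        self._offsets = offsets

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def total_size(self) -> int:
        return self._offsets[-1]

    def layer_slice(self, name_or_index: str | int) -> slice:
        """Global-index slice of one layer's nodes."""
        k = self.layer_index(name_or_index)
        return slice(self._offsets[k], self._offsets[k + 1])

    def layer_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, int):
            return name_or_index
        for k, lay in enumerate(self.layers):
            if lay.name == name_or_index:
                return k
        raise KeyError(f"no layer named {name_or_index!r}")

    def node_index(self, layer: str | int, node_id: str) -> int:
        """Global index of a node, addressed by (layer, id)."""
        k = self.layer_index(layer)
        try:
            return self._offsets[k] + self.layers[k].node_ids.index(node_id)
        except ValueError:
            raise UnknownNodeError(
                f"node {node_id!r} not in layer {self.layers[k].name!r}"
            ) from None

    def global_node_ids(self) -> list[tuple[str, str]]:
        """(layer name, node id) pairs in global order."""
        return [(lay.name, nid) for lay in self.layers for nid in lay.node_ids]

    def assemble(self) -> np.ndarray:
        """Dense N x N block tri-diagonal weight matrix W."""
        n = self.total_size
        w = np.zeros((n, n))
        for k, blk in enumerate(self.intra_blocks):
            s = self.layer_slice(k)
            w[s, s] = blk
        for k, blk in enumerate(self.inter_blocks):
            sp, sq = self.layer_slice(k), self.layer_slice(k + 1)
            w[sp, sq] = blk
            w[sq, sp] = blk.T
        return w


@dataclass
class SeparatedWeights:
    """W split into its intra-layer and inter-layer parts (W = W_intra + W_inter).

    ``intra_blocks`` keeps the per-layer diagonal blocks; ``inter_blocks`` the
    banded upper off-diagonal blocks. The dense views ``W_intra``/``W_inter``
    place each part in the full N x N frame.
    """

    layers: list[Layer]
    intra_blocks: list[np.ndarray]
    inter_blocks: list[np.ndarray]

    @property
    def total_size(self) -> int:
        return sum(lay.size for lay in self.layers)

    def layer_slices(self) -> list[slice]:
        out, off = [], 0
        for lay in self.layers:
            out.append(slice(off, off + lay.size))
            off += lay.size
        return out

    @property
    def W_intra(self) -> np.ndarray:
        n = self.total_size
        w = np.zeros((n, n))
        for s, blk in zip(self.layer_slices(), self.intra_blocks):
            w[s, s] = blk
        return w

    @property
    def W_inter(self) -> np.ndarray:
        n = self.total_size
        w = np.zeros((n, n))
        sl = self.layer_slices()
        for k, blk in enumerate(self.inter_blocks):
            w[sl[k], sl[k + 1]] = blk
            w[sl[k + 1], sl[k]] = blk.T
        return w


IntraEdge = tuple[str, str, float]
InterEdge = tuple[str, str, float]


def assemble(
    layers: Sequence[Layer],
    intra_edge_lists: Mapping[str, Iterable[IntraEdge]] | None = None,
    inter_edge_lists: Mapping[tuple[str, str], Iterable[InterEdge]] | None = None,
) -> MultiLayerNetwork:
    """Build a validated network from per-layer edge lists.

    Parameters
    ----------
    layers
        Ordered layers; order defines adjacency.
    intra_edge_lists
        Mapping layer name -> iterable of (node_a, node_b, weight). Undirected;
        each unordered pair may appear once.
    inter_edge_lists
        Mapping (layer_a, layer_b) -> iterable of (node_in_a, node_in_b, weight).
        The two layers must be adjacent in the declared order; keys may name the
        pair in either direction.

    Raises
    ------
    UnknownNodeError, NonAdjacentLayerError, NegativeWeightError,
    DuplicateEdgeError, SelfLoopError
        On the corresponding malformed input.
    """
    layers = list(layers)
    by_name = {lay.name: k for k, lay in enumerate(layers)}
    if len(by_name) != len(layers):
        raise NetworkValidationError("duplicate layer names")
    pos = {
        (lay.name, nid): i
        for lay in layers
        for i, nid in enumerate(lay.node_ids)
    }

    intra_blocks = [np.zeros((lay.size, lay.size)) for lay in layers]
    for lname, edges in (intra_edge_lists or {}).items():
        if lname not in by_name:
            raise UnknownNodeError(f"unknown layer {lname!r} in intra edges")
        k = by_name[lname]
        blk = intra_blocks[k]
        seen: set[tuple[int, int]] = set()
        for a, b, w in edges:
            w = float(w)
            if (lname, a) not in pos or (lname, b) not in pos:
                missing = a if (lname, a) not in pos else b
                raise UnknownNodeError(f"node {missing!r} not in layer {lname!r}")
            i, j = pos[(lname, a)], pos[(lname, b)]
            if i == j:
                raise SelfLoopError(f"self-loop on {a!r} in layer {lname!r}")
            if w < 0:
                raise NegativeWeightError(f"negative weight {w} on ({a!r}, {b!r})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise DuplicateEdgeError(f"duplicate intra edge ({a!r}, {b!r}) in {lname!r}")
            seen.add(key)
            blk[i, j] = blk[j, i] = w

    inter_blocks = [
        np.zeros((layers[k].size, layers[k + 1].size)) for k in range(len(layers) - 1)
    ]
    for (la, lb), edges in (inter_edge_lists or {}).items():
        if la not in by_name or lb not in by_name:
            missing = la if la not in by_name else lb
            raise UnknownNodeError(f"unknown layer {missing!r} in inter edges")
        p, q = by_name[la], by_name[lb]
        if abs(p - q) != 1:
            raise NonAdjacentLayerError(
                f"inter-layer edges between non-adjacent layers {la!r} and {lb!r}"
            )
        flip = p > q
        if flip:
            p, q, la, lb = q, p, lb, la
        blk = inter_blocks[p]
        seen_pairs: set[tuple[int, int]] = set()
        for a, b, w in edges:
            if flip:
                a, b = b, a
            w = float(w)
            if (la, a) not in pos:
                raise UnknownNodeError(f"node {a!r} not in layer {la!r}")
            if (lb, b) not in pos:
                raise UnknownNodeError(f"node {b!r} not in layer {lb!r}")
            if w < 0:
                raise NegativeWeightError(f"negative weight {w} on ({a!r}, {b!r})")
            i, j = pos[(la, a)], pos[(lb, b)]
            if (i, j) in seen_pairs:
                raise DuplicateEdgeError(f"duplicate inter edge ({a!r}, {b!r})")
            seen_pairs.add((i, j))
            blk[i, j] = w

    return MultiLayerNetwork(layers, intra_blocks, inter_blocks)


def separate(network: MultiLayerNetwork) -> SeparatedWeights:
    """Split the network's weight matrix into intra- and inter-layer parts.

    The two parts reconstruct the assembled W exactly:
    ``separated.W_intra + separated.W_inter == network.assemble()`` entrywise.
    """
    return SeparatedWeights(
        layers=list(network.layers),
        intra_blocks=[np.asarray(b, dtype=float).copy() for b in network.intra_blocks],
        inter_blocks=[np.asarray(b, dtype=float).copy() for b in network.inter_blocks],
    )
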