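"""Tanimoto similarity on binary feature profiles.

Intra-layer weights are computed from binary incidence profiles (e.g. a
disease x protein matrix) with the Tanimoto kernel

    s(x, y) = (x . y) / (||x||^2 + ||y||^2 - x . y),

which for bit vectors equals |A n B| / |A u B| on the support sets. The
pairwise form zeroes the diagonal so the result can be used directly as an
intra-layer weight block (the graph convention has no self-loops). Two
all-zero vectors get similarity 0: an entity with an empty profile connects
to nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BitProfileMatrix:
    """Binary incidence profiles: one bit row per entity, one column per feature."""

    entity_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        vals = np.asarray(self.values)
        if vals.shape != (len(self.entity_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.feature_ids)} features"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("profile entries must be binary")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        object.__setattr__(self, "values", vals.astype(np.int8))


def tanimoto(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Tanimoto similarity of two equal-length bit vectors, in [0, 1].

    Defined as 0 when both vectors are all-zero.
    """
    x_i = np.asarray(x_i)
    x_j = np.asarray(x_j)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError(f"bit vectors must share one length; got {x_i.shape}, {x_j.shape}")
    for v in (x_i, x_j):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("bit vectors must contain only 0 and 1")
    dot = int(x_i @ x_j)
    denom = int(x_i.sum()) + int(x_j.sum()) - dot
    return dot / denom if denom else 0.0


def pairwise_tanimoto(profiles: BitProfileMatrix | np.ndarray) -> np.ndarray:
    """Symmetric Tanimoto similarity block over all row pairs, zero diagonal.

    Entry (i, j) is ``tanimoto(row_i, row_j)``; the diagonal is set to 0 so the
    output is a valid intra-layer weight block.
    """
    m = profiles.values if isinstance(profiles, BitProfileMatrix) else np.asarray(profiles)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("profile entries must be binary")
    m = m.astype(float)
    dot = m @ m.T
    norms = m.sum(axis=1)
    denom = norms[:, None] + norms[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, 0.0)
    # exact symmetry despite floating point: average once
    return (sim + sim.T) / 2.0
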