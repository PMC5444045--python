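"""Fast multi-layer solver: Nyström column sampling + the Woodbury identity.

The exact multi-layer solve inverts I + mu_a L_intra + mu_b L_inter, an O(N^3)
operation. Here the inter-layer Laplacian — positive semidefinite and, in a
layered network, typically the low-rank, sparse part — is replaced by its
Nyström approximation

    L_inter  ~=  C Q+ C',

built from r sampled columns C and the pseudo-inverse of their intersection
block Q. Writing A = I + mu_a L_intra (block diagonal, inverted layer by
layer) the solution follows from the Woodbury identity

    (A + U B U')^{-1} = A^{-1} - A^{-1} U (B^{-1} + U' A^{-1} U)^{-1} U' A^{-1},

so only per-layer factorizations and one r x r system are needed. Only the
inter-layer part is approximated: approximating the intra-layer Laplacians
would blur each layer's own structure.

Because Q+ can be rank-deficient while Woodbury requires an invertible core,
the factorization is truncated to the numerical rank of Q (relative singular
value cutoff ``rank_tol``): with Q = V diag(w) V' restricted to w above the
cutoff, U = C V and B = mu_b diag(1/w) is invertible on the retained space,
so the identity is exact for the approximation actually used.

Column sampling is uniform without replacement, implemented as the first r
entries of a seeded random permutation; for a fixed seed, larger r extends
the smaller sample, which makes the approximation error behave monotonically
in r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .network import SeparatedWeights
from .propagation import LabelVector, ScoreVector, SSLParameters, laplacian, solve_multi_direct


class RankDeficiencyWarning(UserWarning):
    """The sampled Nyström core had lower numerical rank than requested."""


@dataclass
class NystromFactor:
    """Low-rank factorization H ~= C Q+ C' of a positive semidefinite matrix.

    ``C`` holds r exact columns of H at ``sampled_indices``; ``Q_pinv`` is the
    pseudo-inverse of the r x r intersection block, truncated at
    ``effective_rank`` (the numerical rank of Q).
    """

    C: np.ndarray
    Q_pinv: np.ndarray
    sampled_indices: np.ndarray
    effective_rank: int
    # reduced factorization: H ~= U diag(1/core_eigvals) U', core invertible
    U: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    core_eigvals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def reconstruct(self) -> np.ndarray:
        """Symmetrized Nyström reconstruction (C Q+ C' averaged with its transpose)."""
        m = self.C @ self.Q_pinv @ self.C.T
        return (m + m.T) / 2.0


def nystrom(
    H: np.ndarray,
    r: int,
    seed: int | np.random.Generator | None = None,
    *,
    rank_tol: float = 1e-10,
    check: bool = True,
    psd_tol: float = 1e-8,
) -> NystromFactor:
    """Nyström approximation of a PSD matrix from r uniformly sampled columns.

    Parameters
    ----------
    H
        Symmetric positive semidefinite (N, N) matrix.
    r
        Number of columns to sample, 1 <= r <= N.
    seed
        Seed or generator for the column sample.
    rank_tol
        Relative eigenvalue cutoff defining the numerical rank of the
        intersection block Q.
    check
        Verify symmetry and positive semidefiniteness (to ``psd_tol``) first.

    With r = N the reconstruction is exact (H H+ H = H for PSD H); rank-q
    matrices are reconstructed exactly from any q columns spanning their range.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if H.ndim != 2 or H.shape[1] != n:
        raise ValueError("H must be square")
    if not 1 <= r <= n:
        raise ValueError(f"sample size r={r} out of range [1, {n}]")
    if check:
        if not np.allclose(H, H.T, atol=1e-10, rtol=0.0):
            raise ValueError("H must be symmetric")
        if np.linalg.eigvalsh(H).min() < -psd_tol * max(1.0, abs(H).max()):
            raise ValueError("H must be positive semidefinite")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.permutation(n)[:r])
    C = H[:, idx].copy()
    Q = H[np.ix_(idx, idx)]

    w, V = np.linalg.eigh((Q + Q.T) / 2.0)
    keep = w > rank_tol * max(w.max(initial=0.0), 0.0) if w.size else np.zeros(0, bool)
    rank = int(keep.sum())
    if rank < r:
        warnings.warn(
            f"Nystrom core rank {rank} < sample size {r}; factorization truncated",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    Vk, wk = V[:, keep], w[keep]
    Q_pinv = Vk @ np.diag(1.0 / wk) @ Vk.T if rank else np.zeros((r, r))
    U = C @ Vk
    return NystromFactor(
        C=C,
        Q_pinv=Q_pinv,
        sampled_indices=idx,
        effective_rank=rank,
        U=U,
        core_eigvals=wk,
    )


class BlockDiagonalSPD:
    """Cholesky-factorized block-diagonal symmetric positive-definite operator.

    Inverting a block-diagonal matrix block by block is exactly the structure
    that makes the Woodbury correction cheap: the dominant cost is the largest
    layer's factorization, not the full matrix's.
    """

    def __init__(self, blocks: list[np.ndarray]):
        self.blocks = [np.asarray(b, dtype=float) for b in blocks]
        self._factors = [cho_factor(b) for b in self.blocks]
        self.shape = (sum(b.shape[0] for b in self.blocks),) * 2

    def solve(self, X: np.ndarray) -> np.ndarray:
        """Apply A^{-1} to a vector or matrix, block by block."""
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X, dtype=float)
        off = 0
        for blk, fac in zip(self.blocks, self._factors):
            m = blk.shape[0]
            out[off : off + m] = cho_solve(fac, X[off : off + m])
            off += m
        return out

    def dense(self) -> np.ndarray:
        a = np.zeros(self.shape)
        off = 0
        for blk in self.blocks:
            m = blk.shape[0]
            a[off : off + m, off : off + m] = blk
            off += m
        return a


def woodbury_solve(
    A: np.ndarray | BlockDiagonalSPD,
    C: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    *,
    cond_limit: float = 1e14,
) -> np.ndarray:
    """Solve (A + C B C') x = Y via the Woodbury identity.

    ``A`` may be a dense invertible matrix or a :class:`BlockDiagonalSPD`, in
    which case A^{-1} is applied per layer block. ``B`` must be invertible and
    the inner matrix B^{-1} + C' A^{-1} C well conditioned; both are checked
    numerically. With an empty C the correction vanishes and the result is
    A^{-1} Y.
    """
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(C, dtype=float)
    if isinstance(A, BlockDiagonalSPD):
        a_solve = A.solve
        n = A.shape[0]
    else:
        A = np.asarray(A, dtype=float)
        n = A.shape[0]
        from scipy.linalg import lu_factor, lu_solve

        lu = lu_factor(A)
        a_solve = lambda X: lu_solve(lu, X)  # noqa: E731
    if C.ndim != 2 or C.shape[0] != n:
        raise ValueError(f"C must be ({n}, r)")
    r = C.shape[1]
    ainv_y = a_solve(Y)
    if r == 0:
        return ainv_y
    B = np.asarray(B, dtype=float)
    if B.shape != (r, r):
        raise ValueError(f"B must be ({r}, {r})")
    if np.linalg.cond(B) > cond_limit:
        raise np.linalg.LinAlgError("core matrix B is numerically singular")
    b_inv = np.linalg.solve(B, np.eye(r))
    ainv_c = a_solve(C)
    inner = b_inv + C.T @ ainv_c
    if np.linalg.cond(inner) > cond_limit:
        raise np.linalg.LinAlgError("inner Woodbury system is numerically singular")
    correction = ainv_c @ np.linalg.solve(inner, C.T @ ainv_y)
    return ainv_y - correction


def solve_multi_fast(
    separated: SeparatedWeights,
    Y: np.ndarray | LabelVector,
    params: SSLParameters,
    r: int,
    seed: int | np.random.Generator | None = None,
    *,
    rank_tol: float = 1e-10,
) -> ScoreVector:
    """Approximate multi-layer scores via Nyström + Woodbury.

    Sets A = I + mu_a L_intra (inverted per layer block), approximates
    L_inter by its rank-r Nyström factorization, and solves

        f ~= (A + mu_b C Q+ C')^{-1} Y

    through the Woodbury identity. With r = N the result matches the exact
    solver to working precision. For mu_b = 0 the inter-layer term vanishes
    and the call delegates to the exact (block-decoupled) path.
    """
    y = Y.values if isinstance(Y, LabelVector) else np.asarray(Y, dtype=float)
    n = separated.total_size
    if y.shape[0] != n:
        raise ValueError(f"label length {y.shape[0]} != network size {n}")
    if params.mu_b == 0:
        return solve_multi_direct(separated, y, params)
    if not 1 <= r <= n:
        raise ValueError(f"sample size r={r} out of range [1, {n}]")

    a_op = BlockDiagonalSPD(
        [
            np.eye(blk.shape[0]) + params.mu_a * laplacian(blk, check=False)
            for blk in separated.intra_blocks
        ]
    )
    l_inter = laplacian(separated.W_inter, check=False)
    factor = nystrom(l_inter, r, seed, rank_tol=rank_tol, check=False)
    if factor.effective_rank == 0:
        # no inter-layer structure sampled; system reduces to A f = Y
        return ScoreVector(a_op.solve(y))
    B = params.mu_b * np.diag(1.0 / factor.core_eigvals)
    f = woodbury_solve(a_op, factor.U, B, y)
    return ScoreVector(f)
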