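"""Graph-Laplacian semi-supervised learning: cost functionals and exact solvers.

Single layer: given a weight matrix W with Laplacian L = D - W, labels Y
(zero for unlabeled nodes) and trade-off mu >= 0, scores minimize

    ||f - Y||^2 + mu f' L f        =>        f = (I + mu L)^{-1} Y.

Multi-layer: the weight matrix splits into intra-layer and inter-layer parts
with separate Laplacians and trade-offs mu_a, mu_b, and

    f = (I + mu_a L_intra + mu_b L_inter)^{-1} Y.

The smoothness term f' L f equals one half of the pairwise double sum
sum_{i,j} W_ij (f_i - f_j)^2; this package takes f' L f as canonical so that
the closed-form solutions above minimize the cost exactly. Systems are solved
by symmetric positive-definite (Cholesky) factorization, never by explicit
inversion; I + mu L is positive definite for any mu >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .network import SeparatedWeights


@dataclass
class LabelVector:
    """Per-node labels in global node order; 0 marks an unlabeled node."""

    values: np.ndarray
    labeled_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.labeled_mask is None:
            self.labeled_mask = self.values != 0
        else:
            self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
            if self.labeled_mask.shape != self.values.shape:
                raise ValueError("labeled_mask must match label length")
            if np.any(self.values[~self.labeled_mask] != 0):
                raise ValueError("unlabeled nodes must carry label 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SSLParameters:
    """Trade-off parameters between label fit and graph smoothness.

    mu_a weights the intra-layer smoothness penalty, mu_b the inter-layer one;
    mu is the single-layer trade-off. All must be non-negative.
    """

    mu_a: float = 1.0
    mu_b: float = 1.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_a, self.mu_b, self.mu) < 0:
            raise ValueError("trade-off parameters must be non-negative")


@dataclass
class ScoreVector:
    """Solver output: one real score per node in global order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return self.values.size


def laplacian(W: np.ndarray, *, check: bool = True) -> np.ndarray:
    """Unnormalized graph Laplacian L = D - W, D = diag(row sums).

    Positive semidefinite for symmetric non-negative W; every row sums to 0.
    """
    W = np.asarray(W, dtype=float)
    if check:
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12, rtol=0.0):
            raise ValueError("weight matrix must be symmetric")
        if (W < 0).any():
            raise ValueError("weight matrix must be non-negative")
    return np.diag(W.sum(axis=1)) - W


def cost(
    f: np.ndarray,
    Y: np.ndarray | LabelVector,
    separated: SeparatedWeights,
    params: SSLParameters,
) -> float:
    """Multi-layer SSL objective at f.

    ||f - Y||^2 + mu_a f' L_intra f + mu_b f' L_inter f. Non-negative; zero
    when f reproduces the labels and no smoothness penalty applies.
    """
    f = np.asarray(f, dtype=float)
    y = Y.values if isinstance(Y, LabelVector) else np.asarray(Y, dtype=float)
    n = separated.total_size
    if f.shape != (n,) or y.shape != (n,):
        raise ValueError(f"f and Y must have length {n}")
    l_intra = laplacian(separated.W_intra, check=False)
    l_inter = laplacian(separated.W_inter, check=False)
    return float(
        (f - y) @ (f - y) + params.mu_a * (f @ l_intra @ f) + params.mu_b * (f @ l_inter @ f)
    )


def _spd_solve(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    c, low = cho_factor(M)
    return cho_solve((c, low), Y)


def solve_single(W: np.ndarray, Y: np.ndarray | LabelVector, mu: float) -> ScoreVector:
    """Single-layer scores f = (I + mu L)^{-1} Y.

    For mu = 0 this is the identity map (f = Y); an isolated node keeps its
    label. Raises if the residual check fails, which cannot happen for a valid
    non-negative symmetric W and mu >= 0.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    W = np.asarray(W, dtype=float)
    y = Y.values if isinstance(Y, LabelVector) else np.asarray(Y, dtype=float)
    if y.shape[0] != W.shape[0]:
        raise ValueError("label length must match the weight matrix")
    M = np.eye(W.shape[0]) + mu * laplacian(W)
    f = _spd_solve(M, y)
    _check_residual(M, f, y)
    return ScoreVector(f)


def solve_multi_direct(
    separated: SeparatedWeights,
    Y: np.ndarray | LabelVector,
    params: SSLParameters,
) -> ScoreVector:
    """Multi-layer scores f = (I + mu_a L_intra + mu_b L_inter)^{-1} Y.

    Exact dense solve via Cholesky factorization. With mu_b = 0 the system
    decouples over layers and the result equals the stacked per-layer
    single-layer solutions.
    """
    y = Y.values if isinstance(Y, LabelVector) else np.asarray(Y, dtype=float)
    n = separated.total_size
    if y.shape[0] != n:
        raise ValueError(f"label length {y.shape[0]} != network size {n}")
    M = system_matrix(separated, params)
    f = _spd_solve(M, y)
    _check_residual(M, f, y)
    return ScoreVector(f)


def system_matrix(separated: SeparatedWeights, params: SSLParameters) -> np.ndarray:
    """The positive-definite system matrix I + mu_a L_intra + mu_b L_inter."""
    n = separated.total_size
    return (
        np.eye(n)
        + params.mu_a * laplacian(separated.W_intra, check=False)
        + params.mu_b * laplacian(separated.W_inter, check=False)
    )


def _check_residual(M: np.ndarray, f: np.ndarray, y: np.ndarray, tol: float = 1e-8) -> None:
    ny = np.linalg.norm(y)
    if ny == 0:
        return
    rel = np.linalg.norm(M @ f - y) / ny
    if rel > tol:
        raise ArithmeticError(f"linear solve residual {rel:.2e} exceeds {tol:.0e}")
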