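"""Low-multilinear-rank (truncated HOSVD / Tucker) denoising of CSI tensors.

The complex (x, y, spectral) tensor of a CSI acquisition is highly
structured: spatial modes are smooth, and the spectral mode is spanned by
a handful of metabolite lineshapes.  Projecting onto the leading
higher-order singular subspaces — core ranks (8, 8, 12) for the 16x16x128
protocol — removes most thermal noise while preserving the signal.

The truncated HOSVD is the single-pass projector: the mode-k factor is
the matrix of leading left singular vectors of the mode-k unfolding, and
the denoised tensor is the multilinear projection onto those subspaces.
An optional HOOI refinement (alternating updates of the factors) is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CsiTensor

__all__ = ["CoreRanks", "unfold", "fold", "hosvd_truncate", "multilinear_rank",
           "mode_singular_values"]


@dataclass(frozen=True)
class CoreRanks:
    """Tucker core size per mode: (spatial_x, spatial_y, spectral)."""

    spatial_x: int = 8
    spatial_y: int = 8
    spectral: int = 12

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.spatial_x, self.spatial_y, self.spectral)

    def validate(self, shape: tuple[int, ...]) -> None:
        for r, n, name in zip(self.as_tuple(), shape,
                              ("spatial_x", "spatial_y", "spectral")):
            if not (1 <= r <= n):
                raise ValueError(
                    f"rank {name}={r} invalid for tensor dimension {n}")


def _as_array(tensor) -> np.ndarray:
    return tensor.data if isinstance(tensor, CsiTensor) else np.asarray(tensor)


def unfold(tensor, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: rows are the mode fibres.

    Column ordering is the row-major (C-order) flattening of the remaining
    axes in their original order, so ``fold(unfold(T, m), m, T.shape) == T``.
    """
    arr = _as_array(tensor)
    if mode not in (0, 1, 2):
        raise ValueError("mode must be 0, 1 or 2")
    return np.moveaxis(arr, mode, 0).reshape(arr.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    if mode not in (0, 1, 2):
        raise ValueError("mode must be 0, 1 or 2")
    moved = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    return np.moveaxis(np.asarray(matrix).reshape(moved), 0, mode)


def _mode_product(arr: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k product: multiply ``mat`` into axis ``mode`` of ``arr``."""
    return fold(mat @ unfold(arr, mode), mode,
                arr.shape[:mode] + (mat.shape[0],) + arr.shape[mode + 1:])


def mode_singular_values(tensor) -> list[np.ndarray]:
    """Singular-value spectrum of each mode unfolding (diagnostic output)."""
    arr = _as_array(tensor)
    return [np.linalg.svd(unfold(arr, m), compute_uv=False) for m in range(3)]


def hosvd_truncate(tensor, ranks: CoreRanks | tuple[int, int, int],
                   hooi_iters: int = 0):
    """Project onto the leading multilinear subspaces (truncated HOSVD).

    The result has multilinear rank componentwise <= ``ranks``, is
    idempotent, reduces to the identity when ranks equal the dimensions,
    and satisfies the quasi-optimality bound
    ``||T - T_hat||^2 <= sum_k sum_{i>r_k} sigma_{k,i}^2``.

    ``hooi_iters > 0`` runs that many alternating (HOOI) refinement sweeps
    starting from the HOSVD factors; the default is the plain HOSVD.
    """
    arr = _as_array(tensor)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D tensor")
    if not isinstance(ranks, CoreRanks):
        ranks = CoreRanks(*ranks)
    ranks.validate(arr.shape)
    r = ranks.as_tuple()

    factors = []
    for m in range(3):
        u, _, _ = np.linalg.svd(unfold(arr, m), full_matrices=False)
        factors.append(u[:, : r[m]])

    for _ in range(hooi_iters):
        for m in range(3):
            proj = arr
            for k in range(3):
                if k != m:
                    proj = _mode_product(proj, factors[k].conj().T, k)
            u, _, _ = np.linalg.svd(unfold(proj, m), full_matrices=False)
            factors[m] = u[:, : r[m]]

    core = arr
    for m in range(3):
        core = _mode_product(core, factors[m].conj().T, m)
    out = core
    for m in range(3):
        out = _mode_product(out, factors[m], m)

    if isinstance(tensor, CsiTensor):
        return tensor.with_data(out)
    return out


def multilinear_rank(tensor, tol: float = 1e-10) -> tuple[int, int, int]:
    """Numerical rank of each mode unfolding at relative tolerance ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    arr = _as_array(tensor)
    ranks = []
    for m in range(3):
        s = np.linalg.svd(unfold(arr, m), compute_uv=False)
        if s.size == 0 or s[0] == 0:
            ranks.append(0)
        else:
            ranks.append(int(np.sum(s > tol * s[0])))
    return tuple(ranks)
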