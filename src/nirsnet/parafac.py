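"""Trilinear PARAFAC (canonical polyadic) decomposition by ALS.

Used to isolate movement-artifact signatures on short time x channel x
wavelength segments: motion artifacts are typically shared across channels
and wavelengths with a common time course, i.e. well approximated by one or
two trilinear components, whereas the hemodynamic background is not.
Tensors here are tiny (a few hundred samples x 50 channels x 2
wavelengths), so a plain NumPy alternating-least-squares solver is
adequate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CPDecomposition", "cp_als", "reconstruct"]


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product."""
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


@dataclass
class CPDecomposition:
    """Rank-R CP model: tensor ~ sum_r w_r a_r (x) b_r (x) c_r."""

    weights: np.ndarray
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]
    converged: bool
    n_iter: int
    rel_error: float

    def component(self, r: int) -> np.ndarray:
        a, b, c = self.factors
        return self.weights[r] * np.einsum("i,j,k->ijk", a[:, r], b[:, r], c[:, r])


def reconstruct(weights: np.ndarray, factors) -> np.ndarray:
    a, b, c = factors
    return np.einsum("r,ir,jr,kr->ijk", weights, a, b, c)


def cp_als(
    tensor: np.ndarray,
    rank: int,
    n_iter: int = 500,
    tol: float = 1e-10,
    seed: int | None = 0,
) -> CPDecomposition:
    """Fit a rank-``rank`` CP model by alternating least squares.

    Factors are initialized from the leading singular vectors of each
    unfolding (falling back to random columns when the rank exceeds a mode
    dimension). Columns are normalized to unit 2-norm each sweep, with the
    scale collected in ``weights``. Convergence is declared when the
    relative reconstruction error improves by less than ``tol``.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("cp_als expects a 3-way tensor")
    rng = np.random.default_rng(seed)
    norm_x = np.linalg.norm(tensor)
    if norm_x == 0:
        zero = [np.zeros((s, rank)) for s in tensor.shape]
        return CPDecomposition(np.zeros(rank), tuple(zero), True, 0, 0.0)

    factors = []
    for mode in range(3):
        unf = _unfold(tensor, mode)
        u, _, _ = np.linalg.svd(unf, full_matrices=False)
        k = min(rank, u.shape[1])
        fac = np.empty((tensor.shape[mode], rank))
        fac[:, :k] = u[:, :k]
        if k < rank:
            fac[:, k:] = rng.standard_normal((tensor.shape[mode], rank - k))
        factors.append(fac)

    weights = np.ones(rank)
    prev_err = np.inf
    converged = False
    it = 0
    for it in range(1, n_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # unfolding convention: modes ordered, khatri-rao of the later x earlier
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            rhs = _unfold(tensor, mode) @ kr
            try:
                factors[mode] = np.linalg.solve(gram.T, rhs.T).T
            except np.linalg.LinAlgError:
                factors[mode] = rhs @ np.linalg.pinv(gram)
            norms = np.linalg.norm(factors[mode], axis=0)
            norms[norms == 0] = 1.0
            factors[mode] /= norms
            weights = norms
        err = np.linalg.norm(tensor - reconstruct(weights, factors)) / norm_x
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err
    final_err = np.linalg.norm(tensor - reconstruct(weights, factors)) / norm_x
    return CPDecomposition(weights, tuple(factors), converged, it, final_err)
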