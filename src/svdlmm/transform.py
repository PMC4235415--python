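"""Per-family spectral loading matrix G with GG' = A.

The correlated polygenic effect rho ~ N(0, sigma_g^2 A) is rewritten as
G u with u ~ N(0, sigma_g^2 I): factor each family block A_f = U_f S_f U_f'
and set G_f = U_f S_f^{1/2}, so that G_f G_f' = A_f and the random effects
entering the likelihood are independent univariate normals.  Because A is
exactly block-diagonal by family, the decomposition is done per block
(O(sum n_f^3) instead of O(n^3)) and the assembled G is block-diagonal in
the same ordering.

For symmetric positive semi-definite A the singular value decomposition and
the symmetric eigendecomposition coincide; the latter is used for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import FamilyOffsets, RelationshipMatrix

__all__ = ["LoadingMatrix", "block_decompose", "reconstruction_error"]


@dataclass
class LoadingMatrix:
    """Block-diagonal loading matrix; ``blocks[f]`` matches family f of the offsets."""

    blocks: list[np.ndarray]
    offsets: FamilyOffsets
    ids: list[str]

    @property
    def n(self) -> int:
        return self.offsets.n

    def assembled(self) -> np.ndarray:
        """Dense n x n block-diagonal view."""
        n = self.n
        out = np.zeros((n, n))
        for blk, sl in zip(self.blocks, self.offsets.slices()):
            out[sl, sl] = blk
        return out

    def matvec(self, u: np.ndarray) -> np.ndarray:
        """G @ u exploiting block structure."""
        out = np.empty(self.n)
        for blk, sl in zip(self.blocks, self.offsets.slices()):
            out[sl] = blk @ u[sl]
        return out


def block_decompose(
    A: RelationshipMatrix | np.ndarray,
    off: FamilyOffsets,
    tol: float = 1e-8,
) -> LoadingMatrix:
    """Factor each family block of A as G_f G_f' = A_f.

    Eigenvalues in [-tol, 0) are clamped to zero (floating-point noise on an
    exactly PSD pedigree matrix); an eigenvalue below -tol means the block is
    not a valid relationship matrix and raises ``ValueError``.  Only the
    product G_f G_f' is contractual — eigenvector sign and order are
    implementation detail.
    """
    values = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, dtype=float)
    ids = A.ids if isinstance(A, RelationshipMatrix) else [str(i) for i in range(values.shape[0])]
    if values.shape[0] != off.n:
        raise ValueError(f"matrix size {values.shape[0]} != offsets total {off.n}")
    blocks: list[np.ndarray] = []
    for fam, sl in zip(off.families, off.slices()):
        blk = values[sl, sl]
        w, U = np.linalg.eigh((blk + blk.T) / 2.0)
        if w.min() < -tol:
            raise ValueError(
                f"block for family {fam!r} not positive semi-definite "
                f"(min eigenvalue {w.min():.3e})"
            )
        w = np.clip(w, 0.0, None)
        blocks.append(U * np.sqrt(w))
    return LoadingMatrix(blocks=blocks, offsets=off, ids=list(ids))


def reconstruction_error(G: LoadingMatrix, A: RelationshipMatrix | np.ndarray) -> float:
    """max |GG' - A| over all entries."""
    values = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, dtype=float)
    if values.shape != (G.n, G.n):
        raise ValueError(f"shape mismatch: A is {values.shape}, G is {G.n}x{G.n}")
    err = 0.0
    resid = np.abs(values).copy()
    for blk, sl in zip(G.blocks, G.offsets.slices()):
        resid[sl, sl] = np.abs(blk @ blk.T - values[sl, sl])
    err = float(resid.max()) if resid.size else 0.0
    return err
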