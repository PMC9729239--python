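"""Small linear-algebra helpers shared by the MR estimators.

LD submatrices extracted from reference panels are frequently
near-singular, so every inversion in the package goes through an
eigenvalue-clipped decomposition with a uniform floor.
"""

from __future__ import annotations

import numpy as np

#: Eigenvalue floor applied before any LD-matrix inversion.
EIG_FLOOR = 1e-8


def _clipped_eigh(R: np.ndarray, floor: float = EIG_FLOOR):
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    return np.maximum(w, floor), V


def regularized_inverse(R: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Inverse of a symmetric matrix with eigenvalues clipped at ``floor``."""
    w, V = _clipped_eigh(R, floor)
    return (V / w) @ V.T


def inverse_sqrt(R: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    The symmetric (not Cholesky) root keeps sandwich expressions
    permutation-invariant.
    """
    w, V = _clipped_eigh(R, floor)
    return (V / np.sqrt(w)) @ V.T


def psd_clip(R: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix onto the eigenvalue-floored PSD cone."""
    w, V = _clipped_eigh(R, floor)
    return (V * w) @ V.T
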