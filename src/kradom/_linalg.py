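"""Shared dense linear-algebra helpers (jittered Cholesky and PSD inverses)."""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla


def chol_psd(M: np.ndarray, jitter: float = 1e-10, max_tries: int = 8):
    """Lower Cholesky factor of a (numerically) PSD matrix.

    Escalates a diagonal jitter (relative to the mean diagonal) by factors
    of 10 until factorisation succeeds.  Returns ``(L, jitter_used)``;
    raises ``np.linalg.LinAlgError`` if the matrix is indefinite beyond the
    jitter tolerance.
    """
    M = np.asarray(M, dtype=float)
    scale = max(float(np.mean(np.diag(M))), 1.0)
    eps = 0.0
    for k in range(max_tries):
        try:
            L = sla.cholesky(M + eps * np.eye(M.shape[0]), lower=True)
            return L, eps
        except np.linalg.LinAlgError:
            eps = jitter * scale * 10**k
    raise np.linalg.LinAlgError(
        f"matrix not positive definite within jitter tolerance ({eps:g})"
    )


def inv_psd(M: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Inverse of a symmetric PSD matrix via jittered Cholesky."""
    L, _ = chol_psd(M, jitter=jitter)
    Linv = sla.solve_triangular(L, np.eye(L.shape[0]), lower=True)
    return Linv.T @ Linv


def logdet_from_chol(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))
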