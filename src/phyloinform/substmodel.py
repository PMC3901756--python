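"""Nucleotide substitution models (JC69, HKY85) for simulation and
likelihood work.

Rate matrices are normalised so that branch "length" d is the expected
number of substitutions per site. HKY transition probabilities are
computed by spectral decomposition of the reversible rate matrix, which
vectorises cleanly over per-site distances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["jc_prob", "hky_spectral", "transition_matrices", "stationary_mismatch"]

STATE_ORDER = "ACGT"
_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T


def jc_prob(d) -> np.ndarray:
    """JC69 transition-probability matrix for expected distance *d*.

    P(same) = 1/4 + 3/4 e^(-4d/3); P(different) = 1/4 - 1/4 e^(-4d/3).
    Accepts a scalar (returns 4x4) or an array (returns (..., 4, 4)).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("expected distance d must be >= 0")
    e = np.exp(-4.0 * d / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    out = np.broadcast_to(diff[..., None, None], d.shape + (4, 4)).copy()
    idx = np.arange(4)
    out[..., idx, idx] = same[..., None]
    return out


def build_hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY85 rate matrix Q, scaled to one expected substitution per unit d."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs <= 0):
        raise ValueError("freqs must be 4 positive numbers")
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must sum to 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i in _PURINES and j in _PURINES) or (
                i in _PYRIMIDINES and j in _PYRIMIDINES
            )
            Q[i, j] = (kappa if transition else 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(freqs, np.diag(Q))
    return Q / mu


def hky_spectral(kappa: float, freqs):
    """Eigendecomposition (evals, U, Uinv) of the HKY rate matrix.

    Uses the pi-symmetrised form so the decomposition is real and stable:
    S = D^{1/2} Q D^{-1/2} is symmetric for a reversible Q.
    """
    freqs = np.asarray(freqs, dtype=float)
    Q = build_hky_rate_matrix(kappa, freqs)
    sq = np.sqrt(freqs)
    S = (sq[:, None] * Q) / sq[None, :]
    evals, V = np.linalg.eigh((S + S.T) / 2.0)
    U = V / sq[:, None]
    Uinv = V.T * sq[None, :]
    return evals, U, Uinv


def transition_matrices(d, spectral) -> np.ndarray:
    """P(d) for an array of distances, shape (..., 4, 4).

    ``spectral`` is the (evals, U, Uinv) triple from :func:`hky_spectral`.
    Tiny negative entries from roundoff are clipped and rows renormalised.
    """
    evals, U, Uinv = spectral
    d = np.asarray(d, dtype=float)
    expo = np.exp(np.multiply.outer(d, evals))  # (..., 4)
    P = np.einsum("ik,...k,kj->...ij", U, expo, Uinv)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=-1, keepdims=True)
    return P


def stationary_mismatch(freqs) -> float:
    """Probability two independent stationary draws differ (1 - sum pi^2);
    the saturation ceiling of the uncorrected p-distance."""
    freqs = np.asarray(freqs, dtype=float)
    return float(1.0 - np.sum(freqs**2))
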