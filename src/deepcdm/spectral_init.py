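"""Non-iterative spectral initialization for one layer.

Pipeline: truncated-SVD denoising of the binary (pseudo-)response matrix with
entrywise clipping, inverse-link linearization, a second SVD of the
column-centered linearized matrix, Varimax rotation of the top-``K`` loading
structure, thresholding + binarization to a provisional Q-matrix, and a
rescaling step that exploits the binary latent scale: per-attribute person
scores are split by 1-D 2-means into provisional profiles, from which the
starting proportions and (support-restricted least-squares) coefficients are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from .model_core import EffectBasis, LayerCoefficients
from .one_layer_em import fitting_basis
from .synthetic_data import empirical_profile_distribution

__all__ = [
    "InitResult",
    "usvt_denoise",
    "linearize",
    "varimax_rotation",
    "varimax_loadings",
    "threshold_and_binarize",
    "rescale_and_score",
    "default_threshold",
    "spectral_init",
]

DEFAULT_CLIP = 1e-3


@dataclass
class InitResult:
    """Starting values for one layer plus spectral diagnostics."""

    coeffs: LayerCoefficients
    Q0: np.ndarray
    pi0: np.ndarray
    profiles0: np.ndarray  # provisional (N, K) binary profiles
    diagnostics: dict = field(default_factory=dict)


def usvt_denoise(X: np.ndarray, rank: int, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Rank-``rank`` truncated-SVD reconstruction, clipped to ``[clip, 1-clip]``."""
    X = np.asarray(X, dtype=np.float64)
    if rank < 1 or rank > min(X.shape):
        raise ValueError(f"rank must be in [1, {min(X.shape)}], got {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    P = (U[:, :rank] * S[:rank]) @ Vt[:rank]
    return np.clip(P, clip, 1.0 - clip)


def linearize(P: np.ndarray, link: str = "inverse_logit") -> np.ndarray:
    """Entrywise inverse link; the logit requires entries strictly inside (0, 1)."""
    P = np.asarray(P, dtype=np.float64)
    if link == "identity":
        return P.copy()
    if link != "inverse_logit":
        raise ValueError(f"unknown link {link!r}")
    if np.any(P <= 0.0) or np.any(P >= 1.0):
        raise ValueError("linearize requires entries strictly inside (0, 1); clip first")
    return logit(P)


def varimax_rotation(loadings: np.ndarray, normalize: bool = True,
                     max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal rotation matrix maximizing the Varimax criterion.

    Standard SVD-based iteration with optional Kaiser row normalization.
    """
    L = np.asarray(loadings, dtype=np.float64)
    p, k = L.shape
    if k == 1:
        return np.eye(1)
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    crit = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        G = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        new = s.sum()
        if new < crit * (1.0 + tol):
            break
        crit = new
    return R


def varimax_loadings(linearized: np.ndarray, K: int):
    """Top-``K`` rotated loading structure of the (column-centered) linearized
    matrix.

    Returns ``(rotated_loadings, info)`` where ``rotated_loadings`` is
    ``M x K`` (one row per unit), scaled by the singular values over
    ``sqrt(N)`` so that it tracks the coefficient magnitudes, and ``info``
    carries the rotation matrix, singular values, and column means (the
    intercept carriers).
    """
    L = np.asarray(linearized, dtype=np.float64)
    N, M = L.shape
    if K > min(N, M):
        raise ValueError(f"K={K} exceeds min matrix dimension {min(N, M)}")
    col_means = L.mean(axis=0)
    Lc = L - col_means
    U, S, Vt = np.linalg.svd(Lc, full_matrices=False)
    if K < S.size and S[K - 1] - S[K] < 1e-8 * max(S[0], 1.0):
        warnings.warn("near-tied singular values at the retained rank", UserWarning)
    loadings = Vt[:K].T * (S[:K] / np.sqrt(N))
    R = varimax_rotation(loadings)
    rotated = loadings @ R
    info = {
        "rotation": R,
        "singular_values": S.copy(),
        "column_means": col_means,
        "centered": Lc,
    }
    return rotated, info


def default_threshold(K: int, N: int, M: int, multiplier: float = 2.0,
                      loading_scale: float = 0.0,
                      relative: float = 0.35) -> float:
    """Relaxed loading threshold.

    The noise floor is ``multiplier * sqrt(K log(max(N, M)) / N)``.  Spurious
    cross-loadings induced by correlated attributes scale with the loadings
    themselves rather than with ``1/sqrt(N)``, so when the rotated loading
    magnitude ``loading_scale`` is supplied the threshold is at least
    ``relative * loading_scale`` (thresholds proportional to the general
    coefficient magnitude).
    """
    return max(multiplier * np.sqrt(K * np.log(max(N, M)) / N),
               relative * loading_scale)


def threshold_and_binarize(loadings: np.ndarray, tau: float):
    """Zero near-zero loadings and read off the provisional Q-matrix.

    Entries with ``|loading| < tau`` are set to zero; every column is
    sign-flipped so its largest-magnitude surviving entry is positive; an
    all-zero column has its top-``|loading|`` entry restored (with a warning).
    Returns ``(sparse_loadings, Q0)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    L = np.array(loadings, dtype=np.float64)
    sparse = np.where(np.abs(L) >= tau, L, 0.0)
    for k in range(L.shape[1]):
        if not np.any(sparse[:, k]):
            j = int(np.argmax(np.abs(L[:, k])))
            sparse[j, k] = L[j, k]
            warnings.warn(f"all loadings of column {k} fell below tau; restored the top entry",
                          UserWarning)
        top = int(np.argmax(np.abs(sparse[:, k])))
        if sparse[top, k] < 0:
            sparse[:, k] = -sparse[:, k]
    Q0 = (sparse != 0).astype(np.int8)
    return sparse, Q0


def _two_means_split(scores: np.ndarray, max_iter: int = 100):
    """Deterministic 1-D 2-means: centers start at the 25%/75% quantiles;
    returns the midpoint threshold.  Falls back to the median on an empty
    cluster."""
    lo, hi = np.quantile(scores, [0.25, 0.75])
    if lo == hi:
        return float(np.median(scores))
    c0, c1 = float(lo), float(hi)
    for _ in range(max_iter):
        mid = 0.5 * (c0 + c1)
        lower = scores <= mid
        if lower.all() or (~lower).all():
            warnings.warn("empty cluster in 2-means score split; using the median",
                          UserWarning)
            return float(np.median(scores))
        n0, n1 = float(scores[lower].mean()), float(scores[~lower].mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return 0.5 * (c0 + c1)


def _supported_columns(basis: EffectBasis, q_row: np.ndarray) -> np.ndarray:
    """Boolean mask of basis columns whose effect subset lies inside the unit's
    q-row support (intercept always allowed).  For DINA-style restriction the
    caller narrows this further."""
    req = set(int(k) for k in np.where(q_row == 1)[0])
    return np.array([set(S) <= req for S in basis.columns], dtype=bool)


def rescale_and_score(linearized: np.ndarray, sparse_loadings: np.ndarray,
                      Q0: np.ndarray, measurement_model: str = "main_effect",
                      dina_restrict: bool = False) -> InitResult:
    """Turn the rotated loading structure into correctly scaled starting values.

    Person scores for attribute ``k`` are the projections of the centered
    linearized rows onto loading column ``k``; a 2-means split binarizes them
    into provisional profiles.  ``pi0`` is their empirical distribution and
    the starting coefficients are per-unit least squares of the linearized
    rows on the profiles' effect design, restricted to the ``Q0`` support.
    """
    L = np.asarray(linearized, dtype=np.float64)
    N, M = L.shape
    K = Q0.shape[1]
    Lc = L - L.mean(axis=0)
    A0 = np.zeros((N, K), dtype=np.int8)
    for k in range(K):
        col = sparse_loadings[:, k]
        norm2 = float(col @ col)
        scores = Lc @ col / (norm2 if norm2 > 0 else 1.0)
        thr = _two_means_split(scores)
        A0[:, k] = scores > thr
    pi0 = empirical_profile_distribution(A0, K)

    basis = fitting_basis(measurement_model, K)
    X = basis.design_matrix(A0)
    values = np.zeros((M, basis.n_columns))
    for j in range(M):
        mask = _supported_columns(basis, Q0[j])
        if dina_restrict:
            req = tuple(int(k) for k in np.where(Q0[j] == 1)[0])
            keep = {(), req}
            mask &= np.array([S in keep for S in basis.columns], dtype=bool)
        cols = np.where(mask)[0]
        sol, *_ = np.linalg.lstsq(X[:, cols], L[:, j], rcond=None)
        values[j, cols] = sol
    coeffs = LayerCoefficients(basis.model, K, values)
    return InitResult(coeffs, np.asarray(Q0, dtype=np.int8), pi0, A0)


def spectral_init(X: np.ndarray, K: int, measurement_model: str = "main_effect",
                  link: str = "inverse_logit", rank: int | None = None,
                  clip: float = DEFAULT_CLIP, tau: float | None = None,
                  threshold_multiplier: float = 2.0,
                  direct_varimax: bool = False,
                  dina_restrict: bool = False) -> InitResult:
    """Full initialization pipeline for one layer.

    ``rank`` defaults to ``K + 1`` (signal plus the intercept direction);
    ``tau`` defaults to :func:`default_threshold`.  ``direct_varimax`` skips
    the denoise/linearize steps and rotates the raw matrix's loading
    structure instead (comparison variant, off by default).  Deterministic
    for a fixed input matrix.
    """
    X = np.asarray(X, dtype=np.float64)
    N, M = X.shape
    if rank is None:
        rank = min(K + 1, min(N, M))
    if direct_varimax:
        linearized = X
    else:
        P = usvt_denoise(X, rank, clip)
        linearized = linearize(P, link)
    rotated, info = varimax_loadings(linearized, K)
    if tau is None:
        tau = default_threshold(K, N, M, threshold_multiplier,
                                loading_scale=float(np.abs(rotated).max()))
    sparse, Q0 = threshold_and_binarize(rotated, tau)
    result = rescale_and_score(linearized, sparse, Q0, measurement_model,
                               dina_restrict=dina_restrict)
    result.diagnostics.update(
        rank=rank,
        clip=clip,
        tau=tau,
        singular_values=info["singular_values"],
        rotation=info["rotation"],
        direct_varimax=direct_varimax,
    )
    return result
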