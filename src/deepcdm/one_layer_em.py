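"""L1-penalized EM for a single-layer CDM with saturated latent proportions.

The observed (or pseudo-observed) matrix ``Z`` holds ``N`` binary rows over
``M`` units; the latent layer has ``K`` binary attributes with a free
categorical distribution ``pi`` over its ``2^K`` profiles.  The E-step
computes per-person profile posteriors in log space; the M-step maximizes a
weighted Bernoulli log-likelihood minus an L1 penalty on the non-intercept
coefficients via cyclical coordinate descent on the IRLS quadratic
approximation (soft-thresholding exactly zeroes coefficients); the proportion
update is the posterior mean.

Only the inverse-logit link is supported for fitting.  DINA layers are fitted
in the all-effect basis (the DINA structure is recovered afterwards from the
dominant coefficient), so fitted coefficient sets always use the main-effect
or all-effect basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .model_core import (
    EffectBasis,
    LayerCoefficients,
    LayerSpec,
    _bernoulli_logpmf_matrix,
    conditional_prob_table,
    effect_design_matrix,
    enumerate_profiles,
)

__all__ = [
    "ProfilePosterior",
    "PenaltyConfig",
    "ExpandedRegression",
    "LayerFit",
    "fitting_basis",
    "e_step",
    "expand_weighted_regression",
    "m_step_beta",
    "m_step_pi",
    "fit_one_layer",
    "bic",
    "count_parameters",
]

_WEIGHT_DROP = 1e-12

#: Box bound on fitted coefficients.  Quasi-separated (pseudo-)data would
#: otherwise send intercepts or unpenalized coefficients to infinity; at this
#: magnitude the inverse logit is saturated to ~3e-7.
BETA_MAX = 15.0


def fitting_basis(measurement_model: str, K: int) -> EffectBasis:
    """Effect basis used when *estimating* a layer: main-effect layers keep
    the main basis; all-effect and DINA layers are both fitted in the
    saturated all-effect basis."""
    if measurement_model == "main_effect":
        return EffectBasis.main_effect(K)
    if measurement_model in ("all_effect", "dina"):
        return EffectBasis.all_effect(K)
    raise ValueError(f"unknown measurement model {measurement_model!r}")


@dataclass
class ProfilePosterior:
    """``(N, 2^K)`` posterior weights over attribute profiles, one row per person."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("posterior weights must be 2-D")
        rows = self.weights.sum(axis=1)
        if np.any(self.weights < -1e-12) or np.any(np.abs(rows - 1.0) > 1e-8):
            raise ValueError("posterior rows must be nonnegative and sum to 1")

    @property
    def n_profiles(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class PenaltyConfig:
    lambda_: float = 0.0
    penalize_intercept: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be nonnegative")


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def e_step(data: np.ndarray, coeffs: LayerCoefficients, pi: np.ndarray,
           link: str = "inverse_logit"):
    """Posterior profile weights and the marginal log-likelihood.

    ``w_{im} \\propto pi_m * prod_j P_j(m)^{z_ij} (1 - P_j(m))^{1 - z_ij}``,
    computed in log space with per-row max subtraction.
    Returns ``(ProfilePosterior, loglik)``.
    """
    data = np.asarray(data, dtype=np.float64)
    theta = conditional_prob_table(coeffs, link)
    # keep the log-likelihood finite when expit saturates at large coefficients
    theta = np.clip(theta, 1e-12, 1.0 - 1e-12)
    ll = _bernoulli_logpmf_matrix(data, theta)  # (N, 2^K)
    pi = np.asarray(pi, dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    log_post = ll + log_pi[None, :]
    norm = logsumexp(log_post, axis=1)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("person with zero total likelihood in E-step")
    W = np.exp(log_post - norm[:, None])
    return ProfilePosterior(W), float(norm.sum())


# ---------------------------------------------------------------------------
# M-step: weighted penalized logistic regressions
# ---------------------------------------------------------------------------

@dataclass
class ExpandedRegression:
    """The E-step's weighted GLM view: one row per (person, profile) pair.

    ``design`` has one row per kept pair; ``outcomes[:, j]`` is the unit-``j``
    outcome ``z_{ij}`` replicated over profiles; ``weights`` are the posterior
    weights ``w_{im}``.  Pairs with weight below 1e-12 are dropped.
    ``profile_index`` retains each row's profile for exact aggregation.
    """

    design: np.ndarray
    outcomes: np.ndarray
    weights: np.ndarray
    profile_index: np.ndarray
    basis: EffectBasis

    @property
    def n_units(self) -> int:
        return self.outcomes.shape[1]

    @property
    def n_profiles(self) -> int:
        return 2 ** self.basis.K

    def sufficient_stats(self):
        """Collapse to per-profile totals: ``n_m = sum_i w_im`` and
        ``s_{m j} = sum_i w_im z_{ij}`` (exact; design rows repeat by profile)."""
        P = self.n_profiles
        n = np.bincount(self.profile_index, weights=self.weights, minlength=P)
        wz = self.weights[:, None] * self.outcomes
        s = np.column_stack([
            np.bincount(self.profile_index, weights=wz[:, j], minlength=P)
            for j in range(self.n_units)
        ])
        return n, s


def expand_weighted_regression(data: np.ndarray, posterior: ProfilePosterior,
                               basis: EffectBasis) -> ExpandedRegression:
    """Expand ``(data, posterior)`` to the ``N * 2^K``-row weighted dataset."""
    data = np.asarray(data, dtype=np.float64)
    N = data.shape[0]
    P = posterior.n_profiles
    if P != 2 ** basis.K:
        raise ValueError("posterior width does not match basis profile space")
    X_prof = basis.design_matrix(enumerate_profiles(basis.K))  # (P, ncols)
    w = posterior.weights.ravel()  # person-major
    keep = w >= _WEIGHT_DROP
    prof_idx = np.tile(np.arange(P), N)[keep]
    design = X_prof[prof_idx]
    outcomes = np.repeat(data, P, axis=0)[keep]
    return ExpandedRegression(design, outcomes, w[keep], prof_idx, basis)


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _fit_units_logistic(X: np.ndarray, n: np.ndarray, S: np.ndarray, lam: float,
                        Beta: np.ndarray, penalized: np.ndarray,
                        support: np.ndarray, inner_tol: float = 1e-7,
                        outer_tol: float = 1e-5,
                        max_outer: int = 8, max_sweeps: int = 30) -> np.ndarray:
    """Per unit, maximize
    ``sum_m [s_m log p_m + (n_m - s_m) log(1 - p_m)] - lam * sum |beta_k|``
    (over penalized coordinates) by IRLS with cyclical coordinate descent and
    soft-thresholding on each quadratic approximation.

    All units share the profile design ``X`` (P, C) and trial weights ``n``
    (P,), so the updates are vectorized across units: ``S`` is (P, U) success
    weights, ``Beta`` (U, C) starting coefficients, ``support`` (U, C) the
    coordinates allowed to be nonzero.
    """
    Beta = np.where(support, Beta, 0.0)
    pos = n > 0
    X, n, S = X[pos], n[pos], S[pos]
    if X.shape[0] == 0 or not support.any():
        return Beta
    C = X.shape[1]
    xsq = X**2
    nn = n[:, None]

    def _objective(B):
        # per-unit penalized weighted Bernoulli log-likelihood
        eta = X @ B.T
        ll = (S * eta - nn * np.logaddexp(0.0, eta)).sum(axis=0)
        pen = lam * np.abs(B[:, penalized]).sum(axis=1)
        return ll - pen

    Beta_start = Beta.copy()
    obj_start = _objective(Beta_start)
    for _ in range(max_outer):
        eta = X @ Beta.T  # (P, U)
        p = expit(eta)
        w = np.maximum(nn * p * (1.0 - p), 1e-10)
        r = (S - nn * p) / w  # working residual z - eta
        Beta_outer = Beta.copy()
        for _sweep in range(max_sweeps):
            max_delta = 0.0
            for k in range(C):
                wk2 = xsq[:, k] @ w  # (U,)
                rho = X[:, k] @ (w * r) + wk2 * Beta[:, k]
                if penalized[k]:
                    new = _soft(rho, lam) / wk2
                else:
                    new = rho / wk2
                new = np.clip(new, -BETA_MAX, BETA_MAX)
                new = np.where(support[:, k], new, 0.0)
                delta = new - Beta[:, k]
                if np.any(delta):
                    r -= X[:, k][:, None] * delta[None, :]
                    Beta[:, k] = new
                    max_delta = max(max_delta, float(np.abs(delta).max()))
            if max_delta < inner_tol:
                break
        if np.max(np.abs(Beta - Beta_outer)) < outer_tol:
            break
    # ascent safeguard: the IRLS quadratic is not a majorizer, so backtrack
    # any unit whose penalized objective decreased (generalized EM only needs
    # a non-decrease)
    worse = _objective(Beta) < obj_start - 1e-12
    for _ in range(30):
        if not worse.any():
            break
        Beta[worse] = 0.5 * (Beta[worse] + Beta_start[worse])
        worse = _objective(Beta) < obj_start - 1e-12
    if worse.any():
        Beta[worse] = Beta_start[worse]
    return Beta


def _fit_unit_logistic(X, n, s, lam, beta, penalized, support, **kw):
    """Single-unit convenience wrapper around :func:`_fit_units_logistic`."""
    out = _fit_units_logistic(X, n, np.asarray(s)[:, None], lam,
                              np.asarray(beta)[None, :], penalized,
                              np.asarray(support)[None, :], **kw)
    return out[0]


def m_step_beta(expanded: ExpandedRegression, lam: float,
                beta_init: np.ndarray | None = None,
                penalize_intercept: bool = False,
                support_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-unit penalized weighted logistic updates on the expanded dataset.

    Returns the ``(n_units, n_columns)`` coefficient matrix.  ``support_mask``
    (same shape) pins masked-out coefficients to zero — used by confirmatory
    fitting.
    """
    basis = expanded.basis
    C = basis.n_columns
    U = expanded.n_units
    X_prof = basis.design_matrix(enumerate_profiles(basis.K))
    n, s = expanded.sufficient_stats()
    if beta_init is None:
        beta_init = np.zeros((U, C))
    penalized = np.ones(C, dtype=bool)
    if not penalize_intercept:
        penalized[0] = False
    if support_mask is None:
        support_mask = np.ones((U, C), dtype=bool)
    return _fit_units_logistic(
        X_prof, n, s, lam, np.asarray(beta_init, dtype=np.float64),
        penalized, np.asarray(support_mask, dtype=bool),
    )


def m_step_pi(posterior: ProfilePosterior) -> np.ndarray:
    """Closed-form proportion update: the average posterior row."""
    pi = posterior.weights.mean(axis=0)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# the one-layer EM driver
# ---------------------------------------------------------------------------

@dataclass
class LayerFit:
    """One layer's estimates and fitting trace."""

    coeffs: LayerCoefficients
    pi: np.ndarray
    objective_trace: list
    n_iter: int
    converged: bool
    loglik: float
    bic: float
    lam: float
    measurement_model: str = "main_effect"

    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coeffs.values))


def _penalty_value(values: np.ndarray, lam: float, penalize_intercept: bool) -> float:
    slopes = values if penalize_intercept else values[:, 1:]
    return float(lam * np.abs(slopes).sum())


def fit_one_layer(data: np.ndarray, K: int, measurement_model: str, lam: float,
                  init, tol: float = 1e-4, max_iter: int = 500,
                  penalize_intercept: bool = False,
                  support_mask: np.ndarray | None = None,
                  compute_bic: bool = True) -> LayerFit:
    """Penalized EM until the relative change of the penalized observed-data
    objective drops below ``tol`` (or ``max_iter``).

    ``init`` is a ``(B0, pi0)`` pair; ``B0`` may be a
    :class:`LayerCoefficients` in the fitting basis or a raw value matrix.
    The objective trace is non-decreasing up to numerical slack.
    """
    data = np.asarray(data, dtype=np.float64)
    N = data.shape[0]
    basis = fitting_basis(measurement_model, K)
    B0, pi0 = init
    if isinstance(B0, LayerCoefficients):
        values = np.array(B0.values, dtype=np.float64)
    else:
        values = np.array(B0, dtype=np.float64)
    if values.shape != (data.shape[1], basis.n_columns):
        raise ValueError(
            f"init coefficients must be {(data.shape[1], basis.n_columns)}, got {values.shape}"
        )
    if support_mask is not None:
        values = np.where(support_mask, values, 0.0)
    pi = np.asarray(pi0, dtype=np.float64)
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()

    trace: list = []
    converged = False
    coeffs = LayerCoefficients(basis.model, K, values)
    posterior = None
    for it in range(max_iter):
        posterior, ll = e_step(data, coeffs, pi)
        obj = ll - _penalty_value(coeffs.values, lam, penalize_intercept)
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite penalized objective")
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(obj - prev) / (abs(prev) + 1.0) < tol:
                converged = True
                break
        # direct sufficient statistics: exactly the expanded weighted dataset
        # of expand_weighted_regression collapsed per profile (design rows only
        # depend on the profile), without materializing the N * 2^K rows
        n_prof = posterior.weights.sum(axis=0)
        s_prof = posterior.weights.T @ data
        penalized = np.ones(basis.n_columns, dtype=bool)
        penalized[0] = penalize_intercept
        mask = (np.ones_like(values, dtype=bool) if support_mask is None
                else np.asarray(support_mask, dtype=bool))
        values = _fit_units_logistic(
            basis.design_matrix(enumerate_profiles(K)), n_prof, s_prof, lam,
            coeffs.values.copy(), penalized, mask,
        )
        coeffs = LayerCoefficients(basis.model, K, values)
        pi = m_step_pi(posterior)
    _, final_ll = e_step(data, coeffs, pi)
    fit = LayerFit(coeffs, pi, trace, len(trace), converged, final_ll,
                   float("nan"), lam, measurement_model)
    if compute_bic:
        fit.bic = bic(fit, N)
    return fit


def count_parameters(fit: LayerFit) -> int:
    """Nonzero coefficients (intercepts included) plus the ``2^K - 1`` free
    proportion parameters."""
    return fit.n_nonzero() + (2**fit.coeffs.K - 1)


def bic(fit: LayerFit, N: int) -> float:
    """``-2 loglik + log(N) * #parameters`` with the unpenalized layer
    log-likelihood at the fitted parameters."""
    if N < 1:
        raise ValueError("N must be positive")
    return float(-2.0 * fit.loglik + np.log(N) * count_parameters(fit))
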