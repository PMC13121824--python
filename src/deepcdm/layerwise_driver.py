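"""Bottom-up layer-wise estimation of deep CDMs.

For each layer, from the observed responses upward: spectrally initialize,
fit the L1-penalized one-layer EM over a grid of penalty strengths, keep the
smallest-BIC fit, read the layer's Q-matrix off the surviving coefficients,
and sample pseudo-observations from the fitted marginal attribute
distribution to serve as the next layer's data.  A confirmatory variant
restricts the coefficient support to known Q-matrices, and a brute-force
classical EM over the joint latent space is provided as a small-scale
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model_core import (
    DeepCDMSpec,
    LayerCoefficients,
    _bernoulli_logpmf_matrix,
    conditional_prob_table,
    enumerate_profiles,
    layer_transition_matrix,
    marginalize_down,
    profiles_to_indices,
)
from .one_layer_em import (
    LayerFit,
    ProfilePosterior,
    e_step,
    expand_weighted_regression,
    fit_one_layer,
    fitting_basis,
    m_step_pi,
    _fit_units_logistic,
    _penalty_value,
)
from .spectral_init import spectral_init

__all__ = [
    "DeepFitResult",
    "FullEMResult",
    "impute_pseudo_samples",
    "recover_q",
    "lambda_grid_from_init",
    "q_support_mask",
    "fit_exploratory",
    "fit_confirmatory",
    "fit_full_em_bruteforce",
]

MAX_BRUTEFORCE_STATES = 2**12

DEFAULT_TRUNC = 0.06  # coefficient truncation before Q recovery
DEFAULT_N_LAMBDA = 15
DEFAULT_LAMBDA_MIN_RATIO = 1e-3


@dataclass
class DeepFitResult:
    """Assembled output of a layer-wise fit."""

    spec: DeepCDMSpec
    layer_fits: list  # LayerFit, d = 1..D
    q_hats: list  # recovered (or known) Q-matrices
    cascade_marginals: list  # p^(d) implied by the deepest pi and fitted coefficients
    layer1_posterior: np.ndarray  # (N, 2^{K_1})
    layer1_map: np.ndarray  # (N, K_1) MAP profiles
    total_bic: float
    provenance: dict
    mode: str = "exploratory"

    @property
    def D(self) -> int:
        return self.spec.D


# ---------------------------------------------------------------------------
# pseudo-observation imputation
# ---------------------------------------------------------------------------

def impute_pseudo_samples(pi: np.ndarray, M: int, rng, mode: str = "marginal",
                          posteriors: np.ndarray | None = None) -> np.ndarray:
    """Binary pseudo-observations of a latent layer.

    ``marginal`` (default): ``M`` iid profile draws from ``pi``.
    ``posterior``: one draw per person from their posterior row.
    ``map``: each person's argmax profile.
    """
    pi = np.asarray(pi, dtype=np.float64)
    if pi.sum() <= 0:
        raise ValueError("pi has no mass")
    K = int(np.log2(len(pi)))
    if 2**K != len(pi):
        raise ValueError("pi length must be a power of two")
    profiles = enumerate_profiles(K)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if mode == "marginal":
        idx = rng.choice(len(pi), size=M, p=pi / pi.sum())
    elif mode in ("posterior", "map"):
        if posteriors is None:
            raise ValueError(f"mode={mode!r} requires per-person posteriors")
        W = np.asarray(posteriors, dtype=np.float64)
        if mode == "map":
            idx = W.argmax(axis=1)
        else:
            cum = W.cumsum(axis=1)
            cum /= cum[:, -1:]
            u = rng.random(W.shape[0])
            idx = (u[:, None] < cum).argmax(axis=1)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    return profiles[idx].copy()


# ---------------------------------------------------------------------------
# Q-matrix recovery
# ---------------------------------------------------------------------------

def recover_q(coeffs: LayerCoefficients, measurement_model: str,
              trunc: float = DEFAULT_TRUNC) -> np.ndarray:
    """Read the Q-matrix off fitted coefficients.

    Non-intercept coefficients with ``|beta| < trunc`` are zeroed first.
    Main-effect: ``q_{jk} = 1`` iff the main effect of attribute ``k``
    survives.  All-effect and DINA (fitted in the all-effect basis): the
    largest-magnitude surviving coefficient's attribute subset becomes the
    unit's q-row (for DINA this is the single required set).
    """
    K = coeffs.K
    if coeffs.model == "dina":
        Q = np.zeros((coeffs.n_units, K), dtype=np.int8)
        for j, req in enumerate(coeffs.required_sets):
            if abs(coeffs.values[j, 1]) >= trunc:
                Q[j, list(req)] = 1
            else:
                warnings.warn(f"unit {j}: DINA coefficient below truncation", UserWarning)
        return Q
    basis = coeffs.basis()
    vals = coeffs.values.copy()
    vals[:, 1:] = np.where(np.abs(vals[:, 1:]) >= trunc, vals[:, 1:], 0.0)
    Q = np.zeros((coeffs.n_units, K), dtype=np.int8)
    if coeffs.model == "main_effect":
        Q[:, :] = (vals[:, 1:] != 0.0).astype(np.int8)
        if np.any(Q.sum(axis=1) == 0):
            warnings.warn("some units had every coefficient truncated (zero q-row)",
                          UserWarning)
        return Q
    # all-effect basis: dominant surviving effect defines the row
    for j in range(coeffs.n_units):
        row = vals[j, 1:]
        if not np.any(row):
            warnings.warn(f"unit {j}: every coefficient truncated (zero q-row)", UserWarning)
            continue
        c = int(np.argmax(np.abs(row))) + 1
        Q[j, list(basis.columns[c])] = 1
    return Q


# ---------------------------------------------------------------------------
# penalty grids and confirmatory support
# ---------------------------------------------------------------------------

def lambda_grid_from_init(data: np.ndarray, init_coeffs: LayerCoefficients,
                          init_pi: np.ndarray, n_lambda: int = DEFAULT_N_LAMBDA,
                          min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO) -> np.ndarray:
    """Log-spaced penalty grid from ``lambda_max`` down to
    ``lambda_max * min_ratio``, where ``lambda_max`` is the smallest penalty
    that zeroes every slope at the initialization's posterior (largest
    absolute slope-coordinate gradient of the weighted log-likelihood at the
    per-unit intercept-only solution)."""
    pi = np.maximum(np.asarray(init_pi, dtype=np.float64), 1e-12)
    pi = pi / pi.sum()
    posterior, _ = e_step(np.asarray(data, dtype=np.float64), init_coeffs, pi)
    basis = init_coeffs.basis() if init_coeffs.model != "dina" else None
    if basis is None:
        raise ValueError("lambda grid needs a shared (main/all) fitting basis")
    expanded = expand_weighted_regression(np.asarray(data, dtype=np.float64),
                                          posterior, basis)
    n, s = expanded.sufficient_stats()
    X = basis.design_matrix(enumerate_profiles(basis.K))
    total = n.sum()
    lam_max = 0.0
    for j in range(expanded.n_units):
        pbar = s[:, j].sum() / total
        grad = X[:, 1:].T @ (s[:, j] - n * pbar)
        lam_max = max(lam_max, float(np.abs(grad).max()))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _relabel_init_to_q(init, Q_known: np.ndarray, measurement_model: str):
    """Re-express a spectral initialization in a known Q-matrix's column order.

    The initializer's attribute labels are arbitrary (whatever order the
    rotation produced), so before restricting to a known Q's support the init
    columns are matched to the known columns by Q-agreement assignment and the
    coefficients and starting proportions are relabeled accordingly.  Returns
    ``(values, pi0)`` in the known labels.
    """
    from scipy.optimize import linear_sum_assignment

    Q_known = np.asarray(Q_known)
    Q0 = np.asarray(init.Q0)
    K = Q_known.shape[1]
    agree = np.zeros((K, K))
    for t in range(K):
        for e in range(K):
            agree[t, e] = np.mean(Q_known[:, t] == Q0[:, e])
    rows, cols = linear_sum_assignment(-agree)
    perm = np.empty(K, dtype=np.int64)
    perm[rows] = cols  # known attribute t <- init attribute perm[t]

    basis = fitting_basis(measurement_model, K)
    col_of = {S: c for c, S in enumerate(basis.columns)}
    old = init.coeffs.values
    values = np.empty_like(old)
    for c, S in enumerate(basis.columns):
        values[:, c] = old[:, col_of[tuple(sorted(perm[t] for t in S))]]
    # profile m in the known labels has init bit perm[t] equal to its bit t
    bits = enumerate_profiles(K).astype(np.int64)
    old_idx = bits @ (1 << perm)
    pi0 = np.asarray(init.pi0)[old_idx]
    return values, pi0


def q_support_mask(Q: np.ndarray, measurement_model: str) -> np.ndarray:
    """Boolean ``(n_units, n_columns)`` mask of fitting-basis coefficients
    allowed under a known Q-matrix (intercepts always allowed)."""
    Q = np.asarray(Q)
    n_units, K = Q.shape
    basis = fitting_basis(measurement_model, K)
    mask = np.zeros((n_units, basis.n_columns), dtype=bool)
    for j in range(n_units):
        req = set(int(k) for k in np.where(Q[j] == 1)[0])
        if measurement_model == "dina":
            allowed = {(), tuple(sorted(req))}
            mask[j] = [S in allowed for S in basis.columns]
        else:
            mask[j] = [set(S) <= req for S in basis.columns]
    return mask


# ---------------------------------------------------------------------------
# exploratory / confirmatory drivers
# ---------------------------------------------------------------------------

def _fit_layer_path(Z, K, model, grid, init, tol, max_iter, trunc=DEFAULT_TRUNC,
                    refit=True, warm_start=False):
    """Fit one layer over a descending penalty grid; returns
    ``(best_fit, path)`` with ``path`` a list of per-penalty diagnostics.

    Each penalty yields a candidate support (the recovered Q plus the
    model's effect rules); with ``refit`` (default) the final model for that
    penalty is an *unpenalized* EM restricted to the candidate support, which
    removes the L1 shrinkage bias, and BIC selection compares those final
    models.  Every penalty restarts from the spectral initialization:
    warm-starting from the previous (larger) penalty's solution is unsafe here
    because the fully shrunk intercept-only solution is a degenerate EM fixed
    point (a flat posterior kills the coefficient gradient), so the whole path
    would stay collapsed.
    """
    grid = np.sort(np.asarray(grid, dtype=np.float64))[::-1]
    fits, path = [], []
    prev = None
    for lam in grid:
        start = (prev.coeffs, prev.pi) if (warm_start and prev is not None) else init
        fit = fit_one_layer(Z, K, model, float(lam), start, tol=tol,
                            max_iter=max_iter)
        entry = {
            "lambda": float(lam),
            "bic": fit.bic,
            "loglik": fit.loglik,
            "n_nonzero": fit.n_nonzero(),
            "converged": bool(fit.converged),
            "n_iter": fit.n_iter,
        }
        prev = fit
        if refit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                Q_cand = recover_q(fit.coeffs, model, trunc)
            mask = q_support_mask(Q_cand, model)
            final = fit_one_layer(
                Z, K, model, 0.0,
                (np.where(mask, fit.coeffs.values, 0.0), fit.pi),
                tol=tol, max_iter=max_iter, support_mask=mask,
            )
            final.lam = float(lam)  # provenance: the penalty that chose the support
            entry["refit_bic"] = final.bic
            entry["refit_n_nonzero"] = final.n_nonzero()
            fit = final
        fits.append(fit)
        path.append(entry)
    if not any(f.converged for f in fits):
        raise RuntimeError(f"layer failed to converge at every penalty; path={path}")
    best = min(fits, key=lambda f: f.bic)
    return best, path


def _assemble(spec, data, fits, q_hats, provenance, mode) -> DeepFitResult:
    D = spec.D
    cascade = [None] * D
    cascade[D - 1] = fits[D - 1].pi.copy()
    for d in range(D - 1, 0, -1):
        T = layer_transition_matrix(fits[d].coeffs, spec.layer_specs[d].link)
        cascade[d - 1] = marginalize_down(cascade[d], T)
    posterior, _ = e_step(data, fits[0].coeffs, fits[0].pi)
    profiles1 = enumerate_profiles(spec.widths[1])
    map1 = profiles1[posterior.weights.argmax(axis=1)].copy()
    total_bic = float(sum(f.bic for f in fits))
    return DeepFitResult(spec, fits, q_hats, cascade, posterior.weights, map1,
                         total_bic, provenance, mode)


def fit_exploratory(data: np.ndarray, spec: DeepCDMSpec, *,
                    lambda_grids=None, seed: int = 0, tolerances=None,
                    max_iter: int = 500, trunc: float = DEFAULT_TRUNC,
                    n_lambda: int = DEFAULT_N_LAMBDA,
                    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                    pseudo_multiplier: float = 1.0,
                    imputation_mode: str = "marginal",
                    refit: bool = True,
                    warm_start: bool = False,
                    init_kwargs=None) -> DeepFitResult:
    """Layer-wise penalized EM with per-layer BIC selection of the penalty.

    Layer 1 consumes the observed responses; each deeper layer consumes
    pseudo-observations sampled from the previous layer's fitted marginal
    profile distribution (``pseudo_multiplier * N`` draws).  Each penalty's
    candidate support is refit without penalty before BIC comparison (see
    ``_fit_layer_path``); disable with ``refit=False`` to select among the
    raw penalized fits.  Deterministic in ``seed``.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.isin(data, (0.0, 1.0)).all():
        raise ValueError("response matrix must be binary")
    D = spec.D
    N = data.shape[0]
    if tolerances is None:
        tolerances = [1e-3] + [1e-4] * (D - 1)
    init_kwargs = dict(init_kwargs or {})
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0x1E,))
    impute_rngs = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(D)]

    Z = data
    fits, q_hats, paths, grids_used = [], [], [], []
    for d in range(1, D + 1):
        K = spec.widths[d]
        model = spec.layer_specs[d - 1].measurement_model
        init = spectral_init(Z, K, model, **init_kwargs)
        if lambda_grids is not None and lambda_grids[d - 1] is not None:
            grid = np.asarray(lambda_grids[d - 1], dtype=np.float64)
        else:
            grid = lambda_grid_from_init(Z, init.coeffs, init.pi0,
                                         n_lambda=n_lambda,
                                         min_ratio=lambda_min_ratio)
        best, path = _fit_layer_path(Z, K, model, grid, (init.coeffs, init.pi0),
                                     tolerances[d - 1], max_iter, trunc=trunc,
                                     refit=refit, warm_start=warm_start)
        fits.append(best)
        q_hats.append(recover_q(best.coeffs, model, trunc))
        paths.append(path)
        grids_used.append([float(x) for x in grid])
        if d < D:
            M = int(round(pseudo_multiplier * N))
            post = None
            if imputation_mode in ("posterior", "map"):
                post = e_step(Z, best.coeffs, best.pi)[0].weights
                M = post.shape[0]
            Z = impute_pseudo_samples(best.pi, M, impute_rngs[d - 1],
                                      mode=imputation_mode, posteriors=post)
    provenance = {
        "mode": "exploratory",
        "seed": int(seed),
        "lambda_grids": grids_used,
        "selected_lambdas": [f.lam for f in fits],
        "lambda_paths": paths,
        "tolerances": list(tolerances),
        "trunc": float(trunc),
        "pseudo_multiplier": float(pseudo_multiplier),
        "imputation_mode": imputation_mode,
        "refit": bool(refit),
        "warm_start": bool(warm_start),
        "N": int(N),
    }
    return _assemble(spec, data, fits, q_hats, provenance, "exploratory")


def fit_confirmatory(data: np.ndarray, spec: DeepCDMSpec, Q_known: list, *,
                     lam=0.0, seed: int = 0, tolerances=None,
                     max_iter: int = 500, pseudo_multiplier: float = 1.0,
                     imputation_mode: str = "marginal",
                     init_kwargs=None) -> DeepFitResult:
    """Layer-wise EM with coefficient support restricted to known Q-matrices.

    The penalty defaults to zero (no selection needed); Q recovery is skipped
    and ``q_hats`` echoes ``Q_known``.  With a single unpenalized fit per
    layer (no penalty path), a tight EM tolerance is cheap, so the default is
    1e-5 for every layer.
    """
    data = np.asarray(data, dtype=np.float64)
    D = spec.D
    N = data.shape[0]
    if len(Q_known) != D:
        raise ValueError(f"need {D} Q-matrices")
    lams = [float(lam)] * D if np.isscalar(lam) else [float(x) for x in lam]
    if tolerances is None:
        tolerances = [1e-5] * D
    init_kwargs = dict(init_kwargs or {})
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0x1E,))
    impute_rngs = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(D)]

    Z = data
    fits = []
    for d in range(1, D + 1):
        K = spec.widths[d]
        model = spec.layer_specs[d - 1].measurement_model
        Q = np.asarray(Q_known[d - 1])
        if Q.shape != (spec.widths[d - 1], K):
            raise ValueError(f"Q^({d}) has shape {Q.shape}, expected "
                             f"{(spec.widths[d - 1], K)}")
        mask = q_support_mask(Q, model)
        init = spectral_init(Z, K, model, dina_restrict=(model == "dina"),
                             **init_kwargs)
        init_values, init_pi = _relabel_init_to_q(init, Q, model)
        init_values = np.where(mask, init_values, 0.0)
        fit = fit_one_layer(Z, K, model, lams[d - 1], (init_values, init_pi),
                            tol=tolerances[d - 1], max_iter=max_iter,
                            support_mask=mask)
        fits.append(fit)
        if d < D:
            M = int(round(pseudo_multiplier * N))
            post = None
            if imputation_mode in ("posterior", "map"):
                post = e_step(Z, fit.coeffs, fit.pi)[0].weights
                M = post.shape[0]
            Z = impute_pseudo_samples(fit.pi, M, impute_rngs[d - 1],
                                      mode=imputation_mode, posteriors=post)
    provenance = {
        "mode": "confirmatory",
        "seed": int(seed),
        "lambdas": lams,
        "tolerances": list(tolerances),
        "pseudo_multiplier": float(pseudo_multiplier),
        "imputation_mode": imputation_mode,
        "N": int(N),
    }
    q_hats = [np.asarray(Q, dtype=np.int8) for Q in Q_known]
    return _assemble(spec, data, fits, q_hats, provenance, "confirmatory")


# ---------------------------------------------------------------------------
# classical full EM (brute force over the joint latent space)
# ---------------------------------------------------------------------------

@dataclass
class FullEMResult:
    """Baseline classical-EM output on tiny models."""

    spec: DeepCDMSpec
    coeffs: list  # fitted LayerCoefficients per layer (fitting bases)
    pi: np.ndarray  # deepest-layer proportions
    objective_trace: list
    n_iter: int
    converged: bool
    loglik: float  # unpenalized marginal log-likelihood at the optimum

    def layer_marginals(self) -> list:
        D = self.spec.D
        out = [None] * D
        out[D - 1] = self.pi.copy()
        for d in range(D - 1, 0, -1):
            T = layer_transition_matrix(self.coeffs[d], self.spec.layer_specs[d].link)
            out[d - 1] = marginalize_down(out[d], T)
        return out


def fit_full_em_bruteforce(data: np.ndarray, spec: DeepCDMSpec, init, *,
                           lam=0.0, tol: float = 1e-4,
                           max_iter: int = 500) -> FullEMResult:
    """Classical EM with the E-step enumerating every joint latent
    configuration (guarded at ``2^12`` states) — the small-scale baseline the
    layer-wise estimator is checked against.

    ``init`` is ``(coeffs_list, pi)`` with coefficients in the fitting bases.
    """
    data = np.asarray(data, dtype=np.float64)
    D = spec.D
    N = data.shape[0]
    sizes = [2 ** spec.widths[d] for d in range(1, D + 1)]
    n_joint = int(np.prod(sizes))
    if n_joint > MAX_BRUTEFORCE_STATES:
        raise ValueError(f"{n_joint} joint states exceeds brute-force guard "
                         f"{MAX_BRUTEFORCE_STATES}")
    lams = [float(lam)] * D if np.isscalar(lam) else [float(x) for x in lam]
    coeffs_init, pi0 = init
    coeffs = [c.copy() for c in coeffs_init]
    pi = np.maximum(np.asarray(pi0, dtype=np.float64), 1e-12)
    pi = pi / pi.sum()

    joint_idx = np.indices(sizes).reshape(D, -1)  # (D, n_joint)
    bits = [enumerate_profiles(spec.widths[d]).astype(np.float64) for d in range(1, D + 1)]
    X_profs = [
        fitting_basis(spec.layer_specs[d - 1].measurement_model, spec.widths[d])
        .design_matrix(enumerate_profiles(spec.widths[d]))
        for d in range(1, D + 1)
    ]
    penalized = [np.ones(X.shape[1], dtype=bool) for X in X_profs]
    for p in penalized:
        p[0] = False
    support = [np.ones(X.shape[1], dtype=bool) for X in X_profs]

    def _log_prior():
        with np.errstate(divide="ignore"):
            lp = np.log(pi)[joint_idx[D - 1]]
        for d in range(2, D + 1):
            T = layer_transition_matrix(coeffs[d - 1], spec.layer_specs[d - 1].link)
            with np.errstate(divide="ignore"):
                lp = lp + np.log(np.maximum(T, 1e-300))[joint_idx[d - 2], joint_idx[d - 1]]
        return lp

    trace: list = []
    converged = False
    final_ll = -np.inf
    for it in range(max_iter):
        theta1 = conditional_prob_table(coeffs[0], spec.layer_specs[0].link)
        ll1 = _bernoulli_logpmf_matrix(data, theta1)  # (N, 2^{K_1})
        log_joint = ll1[:, joint_idx[0]] + _log_prior()[None, :]
        norm = logsumexp(log_joint, axis=1)
        final_ll = float(norm.sum())
        penalty = sum(
            _penalty_value(coeffs[d].values, lams[d], False) for d in range(D)
        )
        obj = final_ll - penalty
        trace.append(obj)
        if len(trace) >= 2 and abs(obj - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
            converged = True
            break
        P = np.exp(log_joint - norm[:, None])  # (N, n_joint)
        total = P.sum(axis=0)  # joint-state weights summed over persons

        new_coeffs = []
        for d in range(1, D + 1):
            Pd = sizes[d - 1]
            if d == 1:
                # per-person marginal over layer-1 profiles
                W1 = np.zeros((N, Pd))
                np.add.at(W1.T, joint_idx[0], P.T)
                n = W1.sum(axis=0)
                s = W1.T @ data
                outcome_units = data.shape[1]
            else:
                Pprev = sizes[d - 2]
                pair_col = joint_idx[d - 2] * Pd + joint_idx[d - 1]
                Mpair = np.bincount(pair_col, weights=total,
                                    minlength=Pprev * Pd).reshape(Pprev, Pd)
                n = Mpair.sum(axis=0)
                s = Mpair.T @ bits[d - 2]  # (Pd, K_{d-1})
                outcome_units = spec.widths[d - 1]
            X = X_profs[d - 1]
            old = coeffs[d - 1].values
            sup = np.broadcast_to(support[d - 1], (outcome_units, X.shape[1]))
            new_vals = _fit_units_logistic(X, n, s[:, :outcome_units],
                                           lams[d - 1], old.copy(),
                                           penalized[d - 1], sup)
            new_coeffs.append(
                LayerCoefficients(coeffs[d - 1].model, spec.widths[d], new_vals)
            )
        pi_new = np.bincount(joint_idx[D - 1], weights=total, minlength=sizes[D - 1]) / N
        coeffs = new_coeffs
        pi = pi_new / pi_new.sum()
    return FullEMResult(spec, coeffs, pi, trace, len(trace), converged, final_ll)
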