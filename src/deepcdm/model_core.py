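"""Core generative model for multi-layer cognitive diagnostic models.

A model with ``D`` latent layers stacks binary attribute vectors
``A^(D) -> A^(D-1) -> ... -> A^(1) -> X`` where each arrow is a one-layer
diagnostic measurement model (main-effect, all-effect, or DINA) and the
deepest layer follows a saturated categorical distribution over its
``2^{K_D}`` attribute profiles.  This module provides the profile space,
effect design matrices, layerwise conditional probabilities, recursive
marginalization, and exact (small-scale) likelihood computations that the
estimators and the simulator build on.

Profile indexing convention: profiles of ``K`` binary attributes are indexed
by the integers ``0 .. 2^K - 1`` with attribute 1 stored in the *least
significant* bit, i.e. profile ``m`` has attribute ``k`` (0-based) equal to
``(m >> k) & 1``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MEASUREMENT_MODELS",
    "LINKS",
    "MAX_PROFILE_BITS",
    "CapacityError",
    "ModelValidityError",
    "LayerSpec",
    "DeepCDMSpec",
    "EffectBasis",
    "LayerCoefficients",
    "DeepCDMParams",
    "LadderReport",
    "enumerate_profiles",
    "profiles_to_indices",
    "effect_design_row",
    "effect_design_matrix",
    "layer_conditional_prob",
    "conditional_prob_table",
    "layer_transition_matrix",
    "marginalize_down",
    "marginal_loglik",
    "complete_data_loglik",
    "check_ladder_structure",
]

MEASUREMENT_MODELS = ("main_effect", "all_effect", "dina")
LINKS = ("identity", "inverse_logit")

#: Guard on the size of any enumerated profile space.
MAX_PROFILE_BITS = 20

#: Guard on the total number of joint latent states in brute-force sums.
MAX_JOINT_STATES = 2**20


class CapacityError(ValueError):
    """An enumeration would exceed the configured capacity guard."""


class ModelValidityError(ValueError):
    """Parameters produce invalid probabilities (identity link outside [0,1])."""


# ---------------------------------------------------------------------------
# profile space
# ---------------------------------------------------------------------------

def enumerate_profiles(K: int) -> np.ndarray:
    """Return the ``(2^K, K)`` array of all binary attribute profiles.

    Profile ``m`` has attribute ``k`` equal to bit ``k`` of the integer ``m``
    (attribute 1 = least significant bit), so the map index -> profile is a
    bijection with the integers ``0 .. 2^K - 1``.
    """
    if K < 1 or K > MAX_PROFILE_BITS:
        raise CapacityError(f"K must be in [1, {MAX_PROFILE_BITS}], got {K}")
    m = np.arange(2**K, dtype=np.int64)
    return ((m[:, None] >> np.arange(K)) & 1).astype(np.int8)


def profiles_to_indices(profiles: np.ndarray, K: int) -> np.ndarray:
    """Encode binary profile rows to canonical integer indices."""
    profiles = np.asarray(profiles)
    if profiles.shape[-1] != K:
        raise ValueError(f"expected {K} columns, got {profiles.shape[-1]}")
    return profiles.astype(np.int64) @ (1 << np.arange(K, dtype=np.int64))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Width, measurement model, and link of one latent layer."""

    width: int
    measurement_model: str = "main_effect"
    link: str = "inverse_logit"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("layer width must be >= 1")
        if self.measurement_model not in MEASUREMENT_MODELS:
            raise ValueError(f"unknown measurement model {self.measurement_model!r}")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")


@dataclass(frozen=True)
class DeepCDMSpec:
    """Architecture of a deep CDM: item count plus one :class:`LayerSpec` per layer.

    ``widths`` is the tuple ``(J, K_1, ..., K_D)``: the number of observed
    items followed by the latent layer widths, shallow to deep.
    """

    widths: tuple
    layer_specs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "widths", tuple(int(w) for w in self.widths))
        object.__setattr__(self, "layer_specs", tuple(self.layer_specs))
        if len(self.layer_specs) < 1:
            raise ValueError("need at least one latent layer")
        if len(self.widths) != len(self.layer_specs) + 1:
            raise ValueError("widths must have length D + 1 (items + latent layers)")
        if any(w < 1 for w in self.widths):
            raise ValueError("all widths must be positive")
        for d, ls in enumerate(self.layer_specs, start=1):
            if ls.width != self.widths[d]:
                raise ValueError(f"layer {d} spec width {ls.width} != widths[{d}]={self.widths[d]}")
        if any(self.widths[d + 1] > self.widths[d] for d in range(len(self.widths) - 1)):
            warnings.warn(
                "layer widths are not non-increasing with depth; a shrinking "
                "ladder shape is recommended for identifiability",
                UserWarning,
                stacklevel=2,
            )

    @property
    def D(self) -> int:
        return len(self.layer_specs)

    @property
    def n_items(self) -> int:
        return self.widths[0]

    @classmethod
    def build(cls, widths, models, links=None) -> "DeepCDMSpec":
        """Convenience constructor from parallel lists of models/links."""
        widths = tuple(widths)
        D = len(widths) - 1
        if isinstance(models, str):
            models = [models] * D
        if links is None:
            links = ["inverse_logit"] * D
        elif isinstance(links, str):
            links = [links] * D
        specs = tuple(
            LayerSpec(widths[d + 1], models[d], links[d]) for d in range(D)
        )
        return cls(widths=widths, layer_specs=specs)


# ---------------------------------------------------------------------------
# effect bases
# ---------------------------------------------------------------------------

def _all_subsets(K: int):
    """All nonempty subsets of {0..K-1}, ordered by (size, lexicographic)."""
    out = []
    for size in range(1, K + 1):
        out.extend(itertools.combinations(range(K), size))
    return out


@dataclass(frozen=True)
class EffectBasis:
    """Ordered effect columns for one measurement model.

    ``columns`` is a tuple of attribute index tuples: ``()`` is the
    intercept, a singleton ``(k,)`` a main effect, and a longer tuple an
    interaction.  The ordering is intercept first, then subsets by
    (size, lexicographic).  For DINA the basis is per-unit: intercept plus
    the single required-set interaction.
    """

    model: str
    K: int
    columns: tuple

    @classmethod
    def main_effect(cls, K: int) -> "EffectBasis":
        return cls("main_effect", K, ((),) + tuple((k,) for k in range(K)))

    @classmethod
    def all_effect(cls, K: int) -> "EffectBasis":
        return cls("all_effect", K, ((),) + tuple(_all_subsets(K)))

    @classmethod
    def dina(cls, K: int, required_set) -> "EffectBasis":
        req = tuple(sorted(required_set))
        if not req:
            raise ValueError("DINA requires a nonempty required attribute set")
        return cls("dina", K, ((), req))

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def design_matrix(self, profiles: np.ndarray) -> np.ndarray:
        """Design rows for an ``(n, K)`` array of profiles: column ``S`` is
        ``prod_{k in S} alpha_k`` (1 for the intercept)."""
        profiles = np.asarray(profiles, dtype=np.float64)
        if profiles.ndim == 1:
            profiles = profiles[None, :]
        if profiles.shape[1] != self.K:
            raise ValueError(f"profile length {profiles.shape[1]} != K={self.K}")
        cols = [np.ones(profiles.shape[0])]
        for S in self.columns[1:]:
            cols.append(profiles[:, list(S)].prod(axis=1))
        return np.column_stack(cols)


def effect_design_row(profile, basis: EffectBasis) -> np.ndarray:
    """Design vector of a single profile under ``basis``."""
    return basis.design_matrix(np.asarray(profile))[0]


def effect_design_matrix(K: int, basis: EffectBasis) -> np.ndarray:
    """Design matrix over the full canonical profile space (``2^K`` rows)."""
    return basis.design_matrix(enumerate_profiles(K))


# ---------------------------------------------------------------------------
# coefficients and conditional probabilities
# ---------------------------------------------------------------------------

def _apply_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "inverse_logit":
        from scipy.special import expit

        return expit(eta)
    # identity: must already be a probability
    if np.any(eta < -1e-12) or np.any(eta > 1 + 1e-12):
        raise ModelValidityError(
            "identity-link linear predictor outside [0, 1]: "
            f"range [{eta.min():.6g}, {eta.max():.6g}]"
        )
    return np.clip(eta, 0.0, 1.0)


@dataclass
class LayerCoefficients:
    """Coefficient set ``B`` mapping ``K`` parent attributes to ``n_units`` outputs.

    ``values`` has shape ``(n_units, n_columns)`` in the effect basis of
    ``model`` (``K+1`` columns for main-effect, ``2^K`` for all-effect, 2 for
    DINA).  For DINA, ``required_sets`` holds each unit's required attribute
    tuple.
    """

    model: str
    K: int
    values: np.ndarray
    required_sets: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (units x effect columns)")
        if self.model == "dina":
            if self.required_sets is None or len(self.required_sets) != self.values.shape[0]:
                raise ValueError("DINA coefficients need one required set per unit")
            if self.values.shape[1] != 2:
                raise ValueError("DINA coefficients have 2 columns (intercept, interaction)")
            self.required_sets = [tuple(sorted(s)) for s in self.required_sets]
        else:
            expected = self.basis().n_columns
            if self.values.shape[1] != expected:
                raise ValueError(
                    f"{self.model} basis with K={self.K} has {expected} columns, "
                    f"got {self.values.shape[1]}"
                )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def basis(self, unit: int | None = None) -> EffectBasis:
        if self.model == "main_effect":
            return EffectBasis.main_effect(self.K)
        if self.model == "all_effect":
            return EffectBasis.all_effect(self.K)
        if unit is None:
            raise ValueError("DINA basis is per-unit; pass a unit index")
        return EffectBasis.dina(self.K, self.required_sets[unit])

    def copy(self) -> "LayerCoefficients":
        return LayerCoefficients(
            self.model,
            self.K,
            self.values.copy(),
            None if self.required_sets is None else list(self.required_sets),
        )


def layer_conditional_prob(coeffs: LayerCoefficients, unit: int, profile, link: str) -> float:
    """``P(unit output = 1 | parent profile)`` for a single unit and profile."""
    basis = coeffs.basis(unit if coeffs.model == "dina" else None)
    eta = effect_design_row(profile, basis) @ coeffs.values[unit]
    return float(_apply_link(np.asarray([eta]), link)[0])


def conditional_prob_table(coeffs: LayerCoefficients, link: str) -> np.ndarray:
    """``(n_units, 2^K)`` table of ``P(output_j = 1 | profile m)``."""
    profiles = enumerate_profiles(coeffs.K)
    if coeffs.model == "dina":
        # ideal response: all required attributes mastered
        xi = np.stack(
            [profiles[:, list(req)].all(axis=1) for req in coeffs.required_sets]
        ).astype(np.float64)
        eta = coeffs.values[:, [0]] + coeffs.values[:, [1]] * xi
    else:
        X = coeffs.basis().design_matrix(profiles)  # (2^K, ncols)
        eta = coeffs.values @ X.T
    return _apply_link(eta, link)


def layer_transition_matrix(coeffs: LayerCoefficients, link: str) -> np.ndarray:
    """Transition matrix ``T`` with ``T[m', m] = P(A^(d-1) = m' | A^(d) = m)``.

    Shape ``(2^{n_units}, 2^K)``; every column sums to 1 because the units of
    layer ``d-1`` are conditionally independent Bernoullis given the layer-``d``
    profile.
    """
    theta = conditional_prob_table(coeffs, link)  # (n_units, 2^K)
    n_units = coeffs.n_units
    if n_units > MAX_PROFILE_BITS:
        raise CapacityError(f"cannot enumerate 2^{n_units} output profiles")
    bits = enumerate_profiles(n_units).astype(np.float64)  # (2^{n_units}, n_units)
    with np.errstate(divide="ignore"):
        log_theta = np.log(theta)
        log_1m = np.log1p(-theta)
    log_T = bits @ log_theta + (1.0 - bits) @ log_1m
    log_T = np.where(np.isnan(log_T), -np.inf, log_T)  # 0 * -inf cases
    return np.exp(log_T)


def marginalize_down(p: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Push a profile distribution one layer shallower: ``p^(d-1) = T p^(d)``."""
    p = np.asarray(p, dtype=np.float64)
    if T.shape[1] != p.shape[0]:
        raise ValueError(f"T has {T.shape[1]} columns but p has {p.shape[0]} entries")
    out = T @ p
    if abs(out.sum() - 1.0) > 1e-8:
        raise ValueError(f"marginalized distribution sums to {out.sum()!r}")
    return out


# ---------------------------------------------------------------------------
# full parameter sets and likelihoods
# ---------------------------------------------------------------------------

@dataclass
class DeepCDMParams:
    """Full generating parameters: per-layer coefficients plus deepest proportions.

    ``coefficients[d-1]`` maps layer-``d`` profiles (``K = K_d``) to the
    ``K_{d-1}`` units of the layer below (items when ``d = 1``).
    """

    spec: DeepCDMSpec
    coefficients: list
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        D = self.spec.D
        if len(self.coefficients) != D:
            raise ValueError(f"need {D} coefficient sets, got {len(self.coefficients)}")
        for d in range(1, D + 1):
            B = self.coefficients[d - 1]
            if B.K != self.spec.widths[d] or B.n_units != self.spec.widths[d - 1]:
                raise ValueError(f"coefficient set {d} has wrong shape")
        KD = self.spec.widths[D]
        if self.pi.shape != (2**KD,):
            raise ValueError(f"pi must have 2^{KD} entries")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector (sum 1 within 1e-12)")

    def transition_matrices(self) -> list:
        """``T^(d)`` for d = 1..D (``T^(1)`` maps layer-1 profiles to item response
        patterns and is only built on demand elsewhere; here d >= 2 matrices plus
        the layer-1 one are all returned)."""
        return [
            layer_transition_matrix(self.coefficients[d - 1], self.spec.layer_specs[d - 1].link)
            for d in range(1, self.spec.D + 1)
        ]

    def layer_marginals(self) -> list:
        """Marginal profile distributions ``p^(1) .. p^(D)`` by recursive
        marginalization from the deepest layer."""
        D = self.spec.D
        marginals = [None] * D
        marginals[D - 1] = self.pi.copy()
        for d in range(D - 1, 0, -1):
            T = layer_transition_matrix(
                self.coefficients[d], self.spec.layer_specs[d].link
            )  # T^(d+1): 2^{K_d} x 2^{K_{d+1}}
            marginals[d - 1] = marginalize_down(marginals[d], T)
        return marginals


def _bernoulli_logpmf_matrix(data: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """``(N, 2^K)`` matrix of ``log P(row_i | profile m)`` for independent
    Bernoulli units with success table ``theta`` (n_units x 2^K)."""
    data = np.asarray(data, dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_t = np.log(theta)
        log_1m = np.log1p(-theta)
    log_t = np.nan_to_num(log_t, nan=-np.inf, neginf=-1e300)
    log_1m = np.nan_to_num(log_1m, nan=-np.inf, neginf=-1e300)
    return data @ log_t + (1.0 - data) @ log_1m


def marginal_loglik(data: np.ndarray, params: DeepCDMParams, method: str = "factorized") -> float:
    """Observed-data log-likelihood, summed over persons.

    ``method='factorized'`` cascades the deepest proportions down through the
    transition matrices and mixes the layer-1 conditional over ``p^(1)``.
    ``method='bruteforce'`` enumerates every joint configuration of all latent
    layers (guarded at ``2^20`` states) and must agree with the factorized
    form; it exists as an internal cross-check and for small-scale testing.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.size == 0:
        return 0.0
    if data.ndim != 2 or data.shape[1] != params.spec.n_items:
        raise ValueError("data must be N x J")
    spec = params.spec
    theta1 = conditional_prob_table(params.coefficients[0], spec.layer_specs[0].link)
    if method == "factorized":
        p1 = params.layer_marginals()[0]
        ll = _bernoulli_logpmf_matrix(data, theta1)  # (N, 2^{K_1})
        with np.errstate(divide="ignore"):
            log_p1 = np.where(p1 > 0, np.log(np.maximum(p1, 1e-300)), -np.inf)
        return float(logsumexp(ll + log_p1[None, :], axis=1).sum())
    if method != "bruteforce":
        raise ValueError(f"unknown method {method!r}")

    sizes = [2 ** spec.widths[d] for d in range(1, spec.D + 1)]
    n_joint = int(np.prod(sizes))
    if n_joint > MAX_JOINT_STATES:
        raise CapacityError(f"{n_joint} joint latent states exceeds guard {MAX_JOINT_STATES}")
    thetas = [
        conditional_prob_table(params.coefficients[d - 1], spec.layer_specs[d - 1].link)
        for d in range(1, spec.D + 1)
    ]
    profiles = [enumerate_profiles(spec.widths[d]) for d in range(1, spec.D + 1)]
    N = data.shape[0]
    lik = np.zeros(N)
    for combo in itertools.product(*(range(s) for s in sizes)):
        # latent prior: pi at the deepest index times the between-layer terms
        prior = params.pi[combo[-1]]
        for d in range(2, spec.D + 1):
            th = thetas[d - 1][:, combo[d - 1]]  # P(unit=1 | layer-d profile)
            bits = profiles[d - 2][combo[d - 2]]
            prior *= np.prod(np.where(bits == 1, th, 1.0 - th))
        if prior == 0.0:
            continue
        th1 = theta1[:, combo[0]]
        resp = np.prod(np.where(data == 1.0, th1[None, :], 1.0 - th1[None, :]), axis=1)
        lik += prior * resp
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(lik)))


def complete_data_loglik(data: np.ndarray, latents: list, params: DeepCDMParams) -> float:
    """Log-likelihood of responses *and* all latent layers jointly.

    ``latents[d-1]`` is the ``N x K_d`` binary matrix of layer-``d`` profiles.
    Returns ``-inf`` (with a warning) when a degenerate conditional
    probability contradicts an observed outcome.
    """
    data = np.asarray(data, dtype=np.float64)
    spec = params.spec
    if len(latents) != spec.D:
        raise ValueError(f"need {spec.D} latent matrices")
    N = data.shape[0]
    total = 0.0
    outcome = data
    for d in range(1, spec.D + 1):
        A = np.asarray(latents[d - 1])
        idx = profiles_to_indices(A, spec.widths[d])
        theta = conditional_prob_table(params.coefficients[d - 1], spec.layer_specs[d - 1].link)
        probs = theta[:, idx].T  # (N, n_units)
        term = np.where(outcome == 1.0, probs, 1.0 - probs)
        if np.any(term <= 0.0):
            warnings.warn("degenerate conditional probability contradicts an outcome", UserWarning)
            return float("-inf")
        total += float(np.log(term).sum())
        outcome = np.asarray(latents[d - 1], dtype=np.float64)
    deep_idx = profiles_to_indices(np.asarray(latents[-1]), spec.widths[spec.D])
    pvals = params.pi[deep_idx]
    if np.any(pvals <= 0.0):
        warnings.warn("deepest-layer profile has zero prior mass", UserWarning)
        return float("-inf")
    total += float(np.log(pvals).sum())
    return total


# ---------------------------------------------------------------------------
# ladder-structure checks (advisory)
# ---------------------------------------------------------------------------

@dataclass
class LadderReport:
    """Advisory structural report; never blocks fitting."""

    widths_nonincreasing: bool
    two_identity_blocks: list  # per latent layer d = 1..D
    sparse_columns: list  # per layer: column indices with < 3 ones
    zero_columns: list  # per layer: all-zero column indices

    @property
    def ok(self) -> bool:
        return (
            self.widths_nonincreasing
            and all(self.two_identity_blocks)
            and not any(self.zero_columns)
        )


def _count_identity_blocks(Q: np.ndarray) -> int:
    """Number of disjoint K x K identity submatrices extractable by row
    selection: the minimum over attributes of the count of rows exactly equal
    to that attribute's standard basis vector."""
    K = Q.shape[1]
    eye = np.eye(K, dtype=Q.dtype)
    counts = [(np.all(Q == eye[k], axis=1)).sum() for k in range(K)]
    return int(min(counts)) if counts else 0


def check_ladder_structure(spec: DeepCDMSpec, q_matrices: list) -> LadderReport:
    """Heuristic structural screen for the shrinking-ladder shape.

    Reports (i) non-increasing widths, (ii) whether each Q-matrix contains two
    disjoint identity submatrices after row permutation, and (iii) columns
    measured by fewer than 3 units.  Advisory only.
    """
    widths_ok = all(
        spec.widths[d + 1] <= spec.widths[d] for d in range(len(spec.widths) - 1)
    )
    two_blocks, sparse_cols, zero_cols = [], [], []
    for d, Q in enumerate(q_matrices, start=1):
        Q = np.asarray(Q)
        if Q.shape != (spec.widths[d - 1], spec.widths[d]):
            raise ValueError(f"Q^({d}) has shape {Q.shape}, expected "
                             f"{(spec.widths[d - 1], spec.widths[d])}")
        two_blocks.append(_count_identity_blocks(Q) >= 2)
        col_sums = Q.sum(axis=0)
        sparse_cols.append([int(k) for k in np.where(col_sums < 3)[0]])
        zero_cols.append([int(k) for k in np.where(col_sums == 0)[0]])
    return LadderReport(widths_ok, two_blocks, sparse_cols, zero_cols)
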