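"""Forward simulation of deep CDMs and a configurable three-layer study design.

The default design mirrors the shape of the simulation study the estimators
are evaluated on: a three-latent-layer ladder ``(J, K_1, K_2, K_3) =
(30, 7, 4, 2)``, stacked-identity Q-matrices, a choice of main-effect /
all-effect / DINA measurement at the first layer with main-effect models
deeper, coefficient magnitudes decreasing with depth, and a mildly
non-uniform categorical distribution on the deepest layer.  Every constant is
overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import (
    DeepCDMParams,
    DeepCDMSpec,
    EffectBasis,
    LayerCoefficients,
    conditional_prob_table,
    enumerate_profiles,
    profiles_to_indices,
)

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "DEFAULT_WIDTHS",
    "DEFAULT_SLOPES",
    "make_design",
    "build_coefficients",
    "sample",
    "empirical_profile_distribution",
]

DEFAULT_WIDTHS = (30, 7, 4, 2)
#: Per-layer slope magnitudes; the first layer is strongest so the signal
#: weakens with depth.
DEFAULT_SLOPES = (3.0, 2.2, 1.8)

CASES = ("main_effect", "all_effect", "dina")


@dataclass
class SimulationDesign:
    """Generating model plus sample size and seed."""

    spec: DeepCDMSpec
    Q_true: list
    B_true: list
    pi_true: np.ndarray
    N: int
    seed: int

    def params(self) -> DeepCDMParams:
        return DeepCDMParams(self.spec, self.B_true, self.pi_true)


@dataclass
class SimulationTruth:
    """A sampled dataset together with its generating design and latents."""

    design: SimulationDesign
    latents: list  # per layer d = 1..D: (N, K_d) int8
    responses: np.ndarray  # (N, J) int8


# ---------------------------------------------------------------------------
# Q-matrix and coefficient factories
# ---------------------------------------------------------------------------

def _stacked_identity_q(n_rows: int, K: int, rng: np.random.Generator,
                        max_extra_card: int = 3) -> np.ndarray:
    """``[I_K; I_K; extra]`` (as many full identity blocks as fit, up to two),
    extra rows drawn from nonzero low-cardinality patterns, then patched so
    every column has at least ``min(3, n_rows)`` ones where achievable."""
    if n_rows < K:
        raise ValueError(f"cannot build a {n_rows} x {K} Q-matrix with an identity block")
    n_blocks = min(2, n_rows // K)
    blocks = [np.eye(K, dtype=np.int8) for _ in range(n_blocks)]
    n_extra = n_rows - n_blocks * K
    max_card = min(max_extra_card, K)
    extra = np.zeros((n_extra, K), dtype=np.int8)
    for r in range(n_extra):
        card = int(rng.integers(1, max_card + 1))
        cols = rng.choice(K, size=card, replace=False)
        extra[r, cols] = 1
    Q = np.vstack(blocks + [extra]) if n_extra else np.vstack(blocks)
    # patch deficient columns using the sparsest extra rows first
    target = min(3, n_rows)
    if n_extra:
        for k in range(K):
            while Q[:, k].sum() < target:
                candidates = [
                    n_blocks * K + r for r in range(n_extra) if extra[r, k] == 0
                ]
                if not candidates:
                    break
                r = min(candidates, key=lambda i: Q[i].sum())
                Q[r, k] = 1
                extra[r - n_blocks * K, k] = 1
    return Q


def build_coefficients(Q: np.ndarray, model: str, slope: float) -> LayerCoefficients:
    """Generating coefficients whose support matches ``Q`` under ``model``.

    Main-effect: each required attribute gets slope ``c`` and the intercept is
    ``-c/2``.  All-effect: the intercept is ``-c/2``; main effects share
    ``0.4 c`` equally and the top-order interaction gets ``0.6 c`` (a single
    required attribute gets the full ``c``).  DINA: intercept ``-c/2`` and
    interaction ``c`` (guessing/slipping of ``expit(-c/2)``).
    """
    Q = np.asarray(Q, dtype=np.int8)
    n_units, K = Q.shape
    if np.any(Q.sum(axis=1) == 0):
        raise ValueError("generating Q-matrices may not contain all-zero rows")
    if model == "main_effect":
        values = np.zeros((n_units, K + 1))
        values[:, 0] = -slope / 2.0
        values[:, 1:] = slope * Q
        return LayerCoefficients("main_effect", K, values)
    if model == "all_effect":
        basis = EffectBasis.all_effect(K)
        col_of = {S: c for c, S in enumerate(basis.columns)}
        values = np.zeros((n_units, basis.n_columns))
        values[:, 0] = -slope / 2.0
        for j in range(n_units):
            req = tuple(int(k) for k in np.where(Q[j] == 1)[0])
            if len(req) == 1:
                values[j, col_of[req]] = slope
            else:
                for k in req:
                    values[j, col_of[(k,)]] = 0.4 * slope / len(req)
                values[j, col_of[req]] = 0.6 * slope
        return LayerCoefficients("all_effect", K, values)
    if model == "dina":
        values = np.zeros((n_units, 2))
        values[:, 0] = -slope / 2.0
        values[:, 1] = slope
        required = [tuple(int(k) for k in np.where(Q[j] == 1)[0]) for j in range(n_units)]
        return LayerCoefficients("dina", K, values, required_sets=required)
    raise ValueError(f"unknown measurement model {model!r}")


def make_design(case: str, N: int, seed: int, *, widths=DEFAULT_WIDTHS,
                slopes=DEFAULT_SLOPES, pi_concentration: float = 5.0,
                Q_override=None, B_override=None, pi_override=None) -> SimulationDesign:
    """Three-layer study design: ``case`` picks the first-layer measurement
    model; deeper layers are always main-effect.  Deterministic in
    ``(case, N, seed)``."""
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}")
    widths = tuple(int(w) for w in widths)
    D = len(widths) - 1
    if len(slopes) != D:
        raise ValueError(f"need {D} slope magnitudes")
    if D > 1 and not all(slopes[0] > s for s in slopes[1:]):
        warnings.warn("first-layer slope should dominate the deeper layers", UserWarning)
    models = [case] + ["main_effect"] * (D - 1)
    spec = DeepCDMSpec.build(widths, models)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xD0,))
    rng_q, rng_pi = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(2)]

    if Q_override is not None:
        Q_true = [np.asarray(Q, dtype=np.int8) for Q in Q_override]
        for d, Q in enumerate(Q_true, start=1):
            if Q.shape != (widths[d - 1], widths[d]):
                raise ValueError(f"override Q^({d}) has wrong shape {Q.shape}")
    else:
        Q_true = [
            _stacked_identity_q(widths[d - 1], widths[d], rng_q) for d in range(1, D + 1)
        ]
    if B_override is not None:
        B_true = [b.copy() for b in B_override]
        for d, B in enumerate(B_true, start=1):
            _check_support(B, Q_true[d - 1])
    else:
        B_true = [
            build_coefficients(Q_true[d - 1], models[d - 1], slopes[d - 1])
            for d in range(1, D + 1)
        ]
    if pi_override is not None:
        pi_true = np.asarray(pi_override, dtype=np.float64)
    else:
        pi_true = rng_pi.dirichlet(np.full(2 ** widths[D], pi_concentration))
    pi_true = pi_true / pi_true.sum()
    return SimulationDesign(spec, Q_true, B_true, pi_true, int(N), int(seed))


def _check_support(B: LayerCoefficients, Q: np.ndarray) -> None:
    """Every nonzero effect must involve only attributes required by Q."""
    Q = np.asarray(Q)
    if B.model == "dina":
        for j, req in enumerate(B.required_sets):
            if not all(Q[j, k] == 1 for k in req):
                raise ValueError(f"unit {j}: DINA required set disagrees with Q")
        return
    basis = B.basis()
    for j in range(B.n_units):
        for c, S in enumerate(basis.columns[1:], start=1):
            if B.values[j, c] != 0 and not all(Q[j, k] == 1 for k in S):
                raise ValueError(f"unit {j}: coefficient on {S} outside Q support")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(design: SimulationDesign) -> SimulationTruth:
    """Draw a dataset top-down from the generative model.

    One seeded stream per layer (deepest categorical first), so shallower
    draws are unchanged when deeper-layer settings vary.
    """
    spec = design.spec
    D = spec.D
    N = design.N
    ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(0xA1,))
    streams = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(D + 1)]

    deep_idx = streams[0].choice(len(design.pi_true), size=N, p=design.pi_true)
    profiles_D = enumerate_profiles(spec.widths[D])
    latents = [None] * D
    latents[D - 1] = profiles_D[deep_idx].copy()
    parent_idx = deep_idx
    responses = None
    for d in range(D, 0, -1):
        B = design.B_true[d - 1]
        link = spec.layer_specs[d - 1].link
        theta = conditional_prob_table(B, link)  # (K_{d-1} units, 2^{K_d})
        probs = theta[:, parent_idx].T  # (N, n_units)
        draws = (streams[d].random(probs.shape) < probs).astype(np.int8)
        if d == 1:
            responses = draws
        else:
            latents[d - 2] = draws
            parent_idx = profiles_to_indices(draws, spec.widths[d - 1])
    return SimulationTruth(design, latents, responses)


def empirical_profile_distribution(latent: np.ndarray, K: int) -> np.ndarray:
    """Relative frequencies of the ``2^K`` profiles in canonical order."""
    latent = np.asarray(latent)
    if latent.ndim != 2 or latent.shape[1] != K:
        raise ValueError(f"latent matrix must be N x {K}")
    if not np.isin(latent, (0, 1)).all():
        raise ValueError("latent matrix must be binary")
    idx = profiles_to_indices(latent, K)
    counts = np.bincount(idx, minlength=2**K).astype(np.float64)
    return counts / counts.sum()
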