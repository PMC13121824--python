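"""Recovery metrics for simulation studies.

Exploratory fits are identified only up to relabeling of each latent layer's
attributes (column permutation) and, without sign conventions, up to
complementing an attribute (0/1 reflection).  :func:`align` resolves both
before computing RMSE / absolute-bias metrics for the latent class proportion
distributions ``p^(d)`` and the correct-response probability tables
``theta^(d)``, and row/entry recovery proportions for the Q-matrices.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import conditional_prob_table, enumerate_profiles
from .layerwise_driver import DeepFitResult, fit_exploratory
from .synthetic_data import SimulationDesign, make_design, sample

__all__ = [
    "AlignmentMap",
    "AlignedEstimate",
    "RecoveryReport",
    "align",
    "apply_alignment",
    "p_theta_metrics",
    "q_accuracy",
    "evaluate_fit",
    "run_replication_study",
]

_EXHAUSTIVE_K = 8
_TIE_CAP = 50


@dataclass
class AlignmentMap:
    """Per-layer column permutation plus per-column 0/1 reflection flags.

    Aligned attribute ``k`` of layer ``d`` corresponds to estimated attribute
    ``perms[d-1][k]``, complemented when ``refls[d-1][k]`` is set.
    """

    perms: list
    refls: list

    def is_identity(self) -> bool:
        return all(
            np.array_equal(p, np.arange(len(p))) and not r.any()
            for p, r in zip(self.perms, self.refls)
        )


@dataclass
class AlignedEstimate:
    """Estimate quantities re-expressed in the truth's attribute labels."""

    q_hats: list
    thetas: list  # per layer: (n_units, 2^{K_d})
    ps: list  # per layer: fitted marginal profile distribution


def _profile_index_map(K: int, perm: np.ndarray, refl: np.ndarray) -> np.ndarray:
    """``aligned_index[m_est]`` for the canonical profile order: aligned bit
    ``k`` equals estimated bit ``perm[k]`` XOR ``refl[k]``."""
    bits = enumerate_profiles(K)
    aligned_bits = bits[:, perm] ^ refl.astype(np.int8)[None, :]
    return aligned_bits.astype(np.int64) @ (1 << np.arange(K, dtype=np.int64))


def _map_columns(theta: np.ndarray, K: int, perm, refl) -> np.ndarray:
    idx = _profile_index_map(K, np.asarray(perm), np.asarray(refl))
    out = np.empty_like(theta)
    out[..., idx] = theta
    return out


def _map_vector(p: np.ndarray, K: int, perm, refl) -> np.ndarray:
    idx = _profile_index_map(K, np.asarray(perm), np.asarray(refl))
    out = np.empty_like(p)
    out[idx] = p
    return out


def _adjust_rows(theta: np.ndarray, perm: np.ndarray, refl: np.ndarray) -> np.ndarray:
    """Relabel a layer's *outcome units* by the previous layer's map: permute
    rows and flip complemented units' probabilities."""
    out = theta[perm].copy()
    out[refl] = 1.0 - out[refl]
    return out


def _candidate_perms(agreement: np.ndarray) -> list:
    """Permutations maximizing total per-column Q agreement."""
    K = agreement.shape[0]
    if K <= _EXHAUSTIVE_K:
        perms = np.array(list(itertools.permutations(range(K))), dtype=np.int64)
        scores = agreement[perms, np.arange(K)].sum(axis=1)
        best = scores.max()
        cands = perms[scores >= best - 1e-12]
        return [cands[i] for i in range(min(len(cands), _TIE_CAP))]
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-agreement)
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows
    return [perm]


def _estimate_tables(estimate: DeepFitResult):
    thetas = [
        conditional_prob_table(f.coeffs, estimate.spec.layer_specs[d].link)
        for d, f in enumerate(estimate.layer_fits)
    ]
    ps = [f.pi for f in estimate.layer_fits]
    return estimate.q_hats, thetas, ps


def _truth_tables(truth: SimulationDesign):
    spec = truth.spec
    thetas = [
        conditional_prob_table(truth.B_true[d - 1], spec.layer_specs[d - 1].link)
        for d in range(1, spec.D + 1)
    ]
    ps = truth.params().layer_marginals()
    return truth.Q_true, thetas, ps


def align(estimate: DeepFitResult, truth: SimulationDesign) -> AlignmentMap:
    """Resolve label switching layer by layer, bottom up.

    For each layer the column permutation maximizes Q-matrix entry agreement
    (exhaustive for ``K <= 8``, assignment matching beyond); permutation ties
    and the reflection flags are resolved by minimizing the layer's theta
    RMSE.  A layer's map also relabels the next layer's Q rows and theta rows.
    """
    if estimate.spec.widths != truth.spec.widths:
        raise ValueError("estimate and truth have different architectures")
    q_est, th_est, _ = _estimate_tables(estimate)
    q_true, th_true, _ = _truth_tables(truth)
    D = estimate.spec.D
    perms, refls = [], []
    prev_perm = prev_refl = None
    for d in range(D):
        K = estimate.spec.widths[d + 1]
        Qe = np.asarray(q_est[d])
        Te = np.asarray(th_est[d], dtype=np.float64)
        if d > 0:
            Qe = Qe[prev_perm]
            Te = _adjust_rows(Te, prev_perm, prev_refl)
        Qt = np.asarray(q_true[d])
        Tt = np.asarray(th_true[d], dtype=np.float64)
        agreement = np.empty((K, K))
        for e in range(K):
            for t in range(K):
                agreement[e, t] = np.mean(Qe[:, e] == Qt[:, t])
        best = None
        for perm in _candidate_perms(agreement):
            for bitsr in itertools.product((False, True), repeat=K):
                refl = np.array(bitsr, dtype=bool)
                Ta = _map_columns(Te, K, perm, refl)
                rmse = float(np.sqrt(np.mean((Ta - Tt) ** 2)))
                if best is None or rmse < best[0]:
                    best = (rmse, perm, refl)
        _, perm, refl = best
        perms.append(np.asarray(perm, dtype=np.int64))
        refls.append(refl)
        prev_perm, prev_refl = perms[-1], refls[-1]
    return AlignmentMap(perms, refls)


def apply_alignment(estimate: DeepFitResult, amap: AlignmentMap) -> AlignedEstimate:
    """Re-express the estimate's Q-matrices, theta tables, and profile
    distributions in the aligned attribute labels."""
    q_est, th_est, ps = _estimate_tables(estimate)
    D = estimate.spec.D
    out_q, out_t, out_p = [], [], []
    for d in range(D):
        K = estimate.spec.widths[d + 1]
        Qe = np.asarray(q_est[d]).copy()
        Te = np.asarray(th_est[d], dtype=np.float64)
        if d > 0:
            Qe = Qe[amap.perms[d - 1]]
            Te = _adjust_rows(Te, amap.perms[d - 1], amap.refls[d - 1])
        out_q.append(Qe[:, amap.perms[d]])
        out_t.append(_map_columns(Te, K, amap.perms[d], amap.refls[d]))
        out_p.append(_map_vector(np.asarray(ps[d], dtype=np.float64), K,
                                 amap.perms[d], amap.refls[d]))
    return AlignedEstimate(out_q, out_t, out_p)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def _abias(a, b) -> float:
    return float(np.mean(np.abs(np.asarray(a, float) - np.asarray(b, float))))


@dataclass
class RecoveryReport:
    """Per-layer recovery metrics (lists indexed by layer ``d - 1``)."""

    p_rmse: list
    p_abias: list
    theta_rmse: list
    theta_abias: list
    q_row_accuracy: list
    q_entry_accuracy: list

    def to_frame(self) -> pd.DataFrame:
        D = len(self.p_rmse)
        return pd.DataFrame({
            "layer": np.arange(1, D + 1),
            "p_rmse": self.p_rmse,
            "p_abias": self.p_abias,
            "theta_rmse": self.theta_rmse,
            "theta_abias": self.theta_abias,
            "q_row_accuracy": self.q_row_accuracy,
            "q_entry_accuracy": self.q_entry_accuracy,
        })


def p_theta_metrics(aligned: AlignedEstimate, truth: SimulationDesign):
    """RMSE and absolute bias for ``p^(d)`` (profile distributions) and
    ``theta^(d)`` (per-unit correct-response probability tables)."""
    _, th_true, p_true = _truth_tables(truth)
    p_rmse = [_rmse(a, b) for a, b in zip(aligned.ps, p_true)]
    p_abias = [_abias(a, b) for a, b in zip(aligned.ps, p_true)]
    t_rmse = [_rmse(a, b) for a, b in zip(aligned.thetas, th_true)]
    t_abias = [_abias(a, b) for a, b in zip(aligned.thetas, th_true)]
    return p_rmse, p_abias, t_rmse, t_abias


def q_accuracy(Q_est: np.ndarray, Q_true: np.ndarray):
    """``(row proportion, entry proportion)`` of exact agreement."""
    Q_est = np.asarray(Q_est)
    Q_true = np.asarray(Q_true)
    if Q_est.shape != Q_true.shape:
        raise ValueError(f"shape mismatch {Q_est.shape} vs {Q_true.shape}")
    entry = float(np.mean(Q_est == Q_true))
    row = float(np.mean(np.all(Q_est == Q_true, axis=1)))
    return row, entry


def evaluate_fit(estimate: DeepFitResult, truth: SimulationDesign) -> RecoveryReport:
    """Align then compute the full recovery report."""
    amap = align(estimate, truth)
    aligned = apply_alignment(estimate, amap)
    p_rmse, p_abias, t_rmse, t_abias = p_theta_metrics(aligned, truth)
    rows, entries = [], []
    for Qa, Qt in zip(aligned.q_hats, truth.Q_true):
        r, e = q_accuracy(Qa, Qt)
        rows.append(r)
        entries.append(e)
    return RecoveryReport(p_rmse, p_abias, t_rmse, t_abias, rows, entries)


# ---------------------------------------------------------------------------
# replication study
# ---------------------------------------------------------------------------

def run_replication_study(case: str, N_list, replications: int, base_seed: int = 0,
                          design_kwargs=None, fit_kwargs=None):
    """Repeated simulate -> fit -> align -> metrics runs.

    The generating truth is built once per case from ``base_seed``; each
    replication re-samples data with its own seed.  Returns a dict with
    ``per_rep`` (long DataFrame), ``summary`` (means over replications), and
    ``n_failed`` per (case, N).
    """
    design_kwargs = dict(design_kwargs or {})
    fit_kwargs = dict(fit_kwargs or {})
    records = []
    failures = {}
    for N in N_list:
        base_design = make_design(case, int(N), base_seed, **design_kwargs)
        failures[int(N)] = 0
        for rep in range(replications):
            rep_seed = base_seed + 1000 * (rep + 1)
            design = dataclasses.replace(base_design, seed=rep_seed)
            truth = sample(design)
            try:
                fit = fit_exploratory(truth.responses, design.spec,
                                      seed=rep_seed, **fit_kwargs)
                report = evaluate_fit(fit, design)
            except Exception:  # noqa: BLE001 - replication robustness
                failures[int(N)] += 1
                continue
            frame = report.to_frame()
            frame.insert(0, "case", case)
            frame.insert(1, "N", int(N))
            frame.insert(2, "rep", rep)
            records.append(frame)
    per_rep = (pd.concat(records, ignore_index=True) if records
               else pd.DataFrame())
    if len(per_rep):
        summary = (per_rep.drop(columns=["rep"])
                   .groupby(["case", "N", "layer"], as_index=False).mean())
    else:
        summary = pd.DataFrame()
    return {"per_rep": per_rep, "summary": summary, "n_failed": failures}
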