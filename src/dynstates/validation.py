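"""Ground-truth recovery studies on synthetic cohorts.

Each study simulates data with known structure, runs the corresponding part
of the pipeline, and measures how well the truth is recovered. They are used
by the acceptance script and the analysis drivers; problem sizes are chosen
so each study runs in minutes on one CPU (the methods note records them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .dcc import dcc_correlation_path, dynamic_connectome, fit_dcc, fit_garch11
from .graph import nodal_strength, threshold_positive
from .hubmeta import extract_hubs, fit_strength_distribution, sample_truncated_power_law
from .states import (
    elbow_select_k,
    group_state_matrix,
    subject_state_medians,
    vectorize_frames,
)
from .stats import nbs_correct, partial_corr
from .synthetic import (
    default_cohort_spec,
    empirical_state_matrices,
    make_state_templates,
    simulate_cohort,
    simulate_state_matrix_cohort,
    simulate_subject,
)

logger = logging.getLogger(__name__)


def _child_seed(root: int, k: int) -> int:
    return (root * 1009 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# state-count and frame-label recovery
# ---------------------------------------------------------------------------

@dataclass
class StateRecoveryResult:
    k_star: int
    ari: float
    accuracy: float
    elbow_curve: dict[int, float]
    hub_sizes: dict[int, int]
    best_family: dict[int, str]
    n_frames: int


def state_recovery_study(
    seed: int = 1,
    n_subjects: int = 10,
    n_init: int = 3,
    max_iter: int = 80,
    k_range: range = range(2, 9),
    burnin: int = 5,
    n_hubs: int = 20,
    r_min: float = 0.2,
) -> StateRecoveryResult:
    """Full pipeline recovery on the default 4-template cohort.

    Simulates ``n_subjects`` control subjects (6 runs x 118 frames, 104
    nodes), estimates framewise networks, pools frames, elbow-selects k, and
    compares recovered frame labels at k = 4 with the latent state path
    (adjusted Rand index; permutation-invariant, so no explicit state
    matching is needed). Also extracts per-state hubs and strength-
    distribution fits from the recovered group state matrices.
    """
    spec = default_cohort_spec(n_controls=n_subjects, n_patients=0, seed=seed)
    conns, trues = [], []
    for i in range(n_subjects):
        ts, labels = simulate_subject(spec, "control", i)
        conn, _, _ = dynamic_connectome(ts)
        conns.append(conn.drop_burnin(burnin))
        trues.append(np.concatenate([labels[r][burnin:] for r in ts.run_ids]))
    frames = vectorize_frames(conns)
    true = np.concatenate(trues)
    logger.info("state recovery: %d pooled frames", frames.n_frames)

    k_star, curve, parts = elbow_select_k(
        frames, k_range, n_init=n_init, max_iter=max_iter, seed=seed
    )
    part4 = parts.get(4) or parts[k_star]
    ari = float(adjusted_rand_score(true, part4.labels))

    # frame accuracy under the optimal state matching (for diagnostics)
    k = part4.k
    confusion = np.zeros((spec.k, k))
    for t_lab, p_lab in zip(true, part4.labels):
        confusion[t_lab, p_lab] += 1
    rows, cols = linear_sum_assignment(-confusion)
    accuracy = float(confusion[rows, cols].sum() / true.size)

    mats = subject_state_medians(frames, part4)
    hub_sizes, best_family = {}, {}
    for state in range(k):
        gmat = group_state_matrix(mats, state)
        strengths = nodal_strength(threshold_positive(gmat, r_min=r_min))
        hubs = extract_hubs(strengths, n_hubs=n_hubs, state_id=state)
        hub_sizes[state] = hubs.n_hubs
        if np.count_nonzero(strengths > 0) >= 5:
            best_family[state] = fit_strength_distribution(strengths).best_family
    return StateRecoveryResult(
        k_star=k_star, ari=ari, accuracy=accuracy, elbow_curve=curve,
        hub_sizes=hub_sizes, best_family=best_family, n_frames=frames.n_frames,
    )


# ---------------------------------------------------------------------------
# GARCH / DCC estimator recovery
# ---------------------------------------------------------------------------

@dataclass
class EstimatorRecoveryResult:
    mae_omega: float
    mae_alpha: float
    mae_beta: float
    dcc_corr_error: float
    n_seeds: int
    series_length: int


def simulate_garch11_series(
    omega: float, alpha: float, beta: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    x = np.empty(n)
    s = omega / (1 - alpha - beta)
    for t in range(n):
        x[t] = np.sqrt(s) * rng.standard_normal()
        s = omega + alpha * x[t] ** 2 + beta * s
    return x


def estimator_recovery_study(
    seed: int = 1,
    n_seeds: int = 20,
    series_length: int = 4000,
    true_params: tuple[float, float, float] = (0.1, 0.1, 0.8),
    rho: float = 0.6,
    dcc_length: int = 2000,
) -> EstimatorRecoveryResult:
    """Parameter recovery for the univariate GARCH(1,1) QML fit and
    time-mean correlation recovery for the pairwise DCC fit on
    constant-correlation data."""
    omega, alpha, beta = true_params
    errs = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_child_seed(seed, i))
        x = simulate_garch11_series(omega, alpha, beta, series_length, rng)
        fit = fit_garch11(x)
        errs.append([abs(fit.omega - omega), abs(fit.alpha - alpha), abs(fit.beta - beta)])
    mae = np.mean(errs, axis=0)

    rng = np.random.default_rng(_child_seed(seed, n_seeds))
    z1 = rng.standard_normal(dcc_length)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(dcc_length)
    Z = np.column_stack([z1, z2])
    fit = fit_dcc(Z, mode="pairwise")
    R = dcc_correlation_path(Z, fit)
    dcc_err = float(abs(R[:, 0, 1].mean() - rho))
    return EstimatorRecoveryResult(
        mae_omega=float(mae[0]), mae_alpha=float(mae[1]), mae_beta=float(mae[2]),
        dcc_corr_error=dcc_err, n_seeds=n_seeds, series_length=series_length,
    )


# ---------------------------------------------------------------------------
# distribution-family selection
# ---------------------------------------------------------------------------

def family_selection_study(
    seed: int = 1, n_reps: int = 50, n_samples: int = 200,
    alpha: float = 1.5, x_cutoff: float = 10.0,
) -> dict:
    """Fraction of truncated-power-law samples whose CCDF fit selects the
    generating family, plus exact noise-free recovery error."""
    hits = 0
    for i in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, i))
        s = sample_truncated_power_law(alpha, x_cutoff, n_samples, rng)
        if fit_strength_distribution(s).best_family == "truncated_power_law":
            hits += 1
    # noise-free model curves must be recovered exactly (OLS in log space)
    from .hubmeta import fit_families

    x = np.linspace(1, 40, 60)
    worst = 0.0
    for p in [x ** (alpha - 1), np.exp(-x / x_cutoff),
              x ** (alpha - 1) * np.exp(-x / x_cutoff)]:
        fit = fit_families(x, p / p[0])
        worst = max(worst, 1.0 - max(f.r2 for f in fit.fits.values()))
    return dict(selection_rate=hits / n_reps, n_reps=n_reps, exact_r2_gap=worst)


# ---------------------------------------------------------------------------
# NBS calibration and power
# ---------------------------------------------------------------------------

def nbs_calibration_study(
    seed: int = 1, n_reps: int = 200, n_perm: int = 1000,
    n_nodes: int = 68, n_per_group: int = 20, noise_sd: float = 0.1,
    comp_alpha: float = 0.05,
) -> dict:
    """Family-wise error of the NBS permutation test under the null."""
    template = make_state_templates(n_nodes, 4)[0]
    false_pos = 0
    for i in range(n_reps):
        a, b = simulate_state_matrix_cohort(
            template, n_per_group, n_per_group, noise_sd=noise_sd,
            seed=_child_seed(seed, i),
        )
        res = nbs_correct(a, b, n_perm=n_perm, seed=_child_seed(seed, 10_000 + i))
        if res.significant(comp_alpha):
            false_pos += 1
    fwer = false_pos / n_reps
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
    return dict(fwer=fwer, n_reps=n_reps, ci_low=0.05 - half, ci_high=0.05 + half)


def nbs_power_study(
    seed: int = 1, n_nodes: int = 68, n_per_group: int = 20,
    n_edges: int = 10, delta: float = 0.3, noise_sd: float = 0.1,
    n_perm: int = 1000,
) -> dict:
    """Recovery of a planted connected hypo-connectivity path (large effect)."""
    template = make_state_templates(n_nodes, 4)[0]
    planted = [(i, i + 1, -delta) for i in range(n_edges)]
    a, b = simulate_state_matrix_cohort(
        template, n_per_group, n_per_group, effect_edges=planted,
        noise_sd=noise_sd, seed=_child_seed(seed, 1),
    )
    res = nbs_correct(a, b, n_perm=n_perm, seed=_child_seed(seed, 2))
    planted_set = {(i, i + 1) for i in range(n_edges)}
    best_recovered, best_p = 0, 1.0
    for comp in res.significant():
        rec = len(planted_set & set(comp.edges))
        if rec > best_recovered:
            best_recovered, best_p = rec, comp.p_value
    return dict(recovered_edges=best_recovered, n_planted=n_edges, p_value=best_p)


# ---------------------------------------------------------------------------
# dual-effect recovery (hypo/hyper connectivity + behavior coupling)
# ---------------------------------------------------------------------------

@dataclass
class DualEffectResult:
    nbs_hypo_rate: float
    nbs_hyper_rate: float
    partial_hypo_positive_rate: float
    partial_hyper_negative_rate: float
    mean_recovered_hypo: float
    mean_recovered_hyper: float
    n_reps: int
    details: list[dict] = field(repr=False, default_factory=list)


def dual_effect_study(
    seed: int = 1, n_reps: int = 20, n_perm: int = 1000,
    edge_alpha: float = 0.001, min_recovered: int = 8,
) -> DualEffectResult:
    """Recovery of planted hypo-/hyper-connectivity and behavior coupling.

    Each replicate simulates the default cohort (20 controls + 20 patients),
    forms each subject's within-state correlation matrices from the latent
    state labels, contrasts groups with NBS per affected state, and
    partially correlates the behavioral score with the realized strength of
    the planted edges (covariates regressed out). Hypo-connectivity should
    correlate positively and hyper-connectivity negatively with the score.
    NBS uses a strict primary threshold (0.001): the planted effects are
    compact, and at lenient thresholds chance suprathreshold edges form
    giant components that mask focal effects.
    """
    covariate_cols = ["age", "sex", "lesion_type", "race", "education"]
    details = []
    for rep in range(n_reps):
        spec = default_cohort_spec(seed=_child_seed(seed, rep))
        subjects, truth, behavior, covariates = simulate_cohort(spec)
        mats = []
        for ts in subjects:
            mats.extend(empirical_state_matrices(ts, truth.labels[ts.subject_id]).values())
        con = [m for m in mats if m.subject_id.startswith("con")]
        pat = [m for m in mats if m.subject_id.startswith("pat")]
        hypo = {(i, j) for s, i, j, d in spec.effect_edges if d < 0}
        hyper = {(i, j) for s, i, j, d in spec.effect_edges if d > 0}

        entry = {}
        # hypo: patients reduced => controls > patients => sign +1
        # hyper: patients elevated => sign -1
        for name, state, planted, want_sign in [
            ("hypo", 0, hypo, +1), ("hyper", 1, hyper, -1),
        ]:
            res = nbs_correct(
                con, pat, edge_alpha=edge_alpha, n_perm=n_perm,
                seed=_child_seed(seed, 500 + rep), state_id=state,
            )
            rec = max(
                (len(planted & set(c.edges)) for c in res.significant()
                 if c.sign == want_sign),
                default=0,
            )
            entry[f"nbs_{name}_recovered"] = rec
            entry[f"nbs_{name}_ok"] = rec >= min_recovered

        pat_beh = behavior[behavior.group == "patient"].reset_index(drop=True)
        pat_cov = covariates[covariates.group == "patient"][covariate_cols].reset_index(drop=True)
        ids = pat_beh.subject_id.tolist()

        def realized(planted, state):
            vals = {
                m.subject_id: np.mean([m.matrix[i, j] for i, j in planted])
                for m in pat if m.state_id == state
            }
            return np.array([vals[s] for s in ids])

        r_hypo, _ = partial_corr(pat_beh.latent_score, realized(hypo, 0), pat_cov)
        r_hyper, _ = partial_corr(pat_beh.latent_score, realized(hyper, 1), pat_cov)
        entry["r_hypo"], entry["r_hyper"] = r_hypo, r_hyper
        details.append(entry)

    return DualEffectResult(
        nbs_hypo_rate=float(np.mean([d["nbs_hypo_ok"] for d in details])),
        nbs_hyper_rate=float(np.mean([d["nbs_hyper_ok"] for d in details])),
        partial_hypo_positive_rate=float(np.mean([d["r_hypo"] > 0 for d in details])),
        partial_hyper_negative_rate=float(np.mean([d["r_hyper"] < 0 for d in details])),
        mean_recovered_hypo=float(np.mean([d["nbs_hypo_recovered"] for d in details])),
        mean_recovered_hyper=float(np.mean([d["nbs_hyper_recovered"] for d in details])),
        n_reps=n_reps,
        details=details,
    )
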