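"""Synthetic regime-switching cohort generator.

Emulates the study conditions every downstream stage is validated against:
a 104-node parcellation (68 cortical + 36 subcortical), 6 runs of 118
retained frames at TR = 2 s per subject, a semi-Markov latent state process
over 4 correlation templates (one of them an overall-weak state), GARCH(1,1)
conditional-variance dynamics on every node signal, planted group-level
hypo-/hyper-connectivity on chosen edges, and behavioral scores linearly
coupled to the realized strength of the affected edges.

All randomness flows from one root seed: subject streams are spawned as
``default_rng(SeedSequence((root_seed, subject_seed)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CohortSpec,
    GroundTruth,
    RoiTimeSeriesSet,
    StateMatrix,
    StateTemplate,
    upper_indices,
)

WEAK_STATE_MAX_OFFDIAG = 0.1

# Behavioral subtest analogues (naming-test battery style); each loads on the
# single latent language-performance factor.
SUBTEST_NAMES = [
    "word_raw", "commands_raw", "complex_raw", "boston_raw", "reading_raw",
    "reading_complex_raw", "nonword", "stem", "animal_raw",
]
_SUBTEST_LOADINGS = np.array([0.8, 0.75, 0.85, 0.7, 0.8, 0.75, 0.6, 0.7, 0.65])
_SUBTEST_NOISE_SD = 0.5


@dataclass
class TemplatePlan:
    """Blueprint for one state template: correlated blocks over a background.

    ``blocks`` are (node list, within-correlation) pairs; ``couplings`` are
    (nodes A, nodes B, between-correlation) triples for cross-module
    structure (e.g. the negative prefrontal-temporal coupling seen in
    empirical state patterns).
    """

    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    couplings: list[tuple[list[int], list[int], float]] = field(default_factory=list)
    background: float = 0.0
    description: str = ""


def default_block_plan(n_nodes: int, k: int) -> list[TemplatePlan]:
    """Module-structured plans: per non-weak state one strong positive module
    plus a moderate negative coupling from that module to another, over a
    weak positive background; the last state is overall weak.

    The modules loosely imitate frontal / temporal / sensorimotor groupings of
    a language network but make no anatomical claim. Negative couplings are
    attached to the strong module (a correlation matrix cannot sustain
    sizeable negative correlation between two weakly coherent modules and
    stay positive definite).
    """
    n_groups = max(k - 1, 1) + 1
    groups = [g.tolist() for g in np.array_split(np.arange(n_nodes), n_groups)]
    names = ["frontal", "temporal", "sensorimotor", "parietal", "occipital"]
    plans = []
    for s in range(k - 1):
        strong = groups[s % n_groups]
        anti = groups[(s + 1) % n_groups]
        plans.append(
            TemplatePlan(
                blocks=[(strong, 0.55)],
                couplings=[(strong, anti, -0.12)],
                background=0.05,
                description=(
                    f"strong {names[s % len(names)]}-analogue module with negative "
                    f"{names[(s + 1) % len(names)]}-analogue coupling"
                ),
            )
        )
    plans.append(TemplatePlan(blocks=[], background=0.05, description="overall weak state"))
    return plans


def make_state_templates(
    n_nodes: int,
    k: int,
    block_plan: list[TemplatePlan] | None = None,
    seed: int = 0,
) -> list[StateTemplate]:
    """Build ``k`` positive-definite correlation templates from block plans.

    A plan whose levels yield a non-positive-definite matrix is rejected with
    a diagnostic; no nearest-PD repair is applied silently.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if block_plan is None:
        block_plan = default_block_plan(n_nodes, k)
    if len(block_plan) != k:
        raise ValueError(f"block_plan has {len(block_plan)} entries, expected k={k}")
    templates = []
    for s, plan in enumerate(block_plan):
        if not -1 < plan.background < 1:
            raise ValueError("correlation levels must lie in (-1, 1)")
        C = np.full((n_nodes, n_nodes), plan.background, dtype=float)
        for nodes, level in plan.blocks:
            if not -1 < level < 1:
                raise ValueError("correlation levels must lie in (-1, 1)")
            idx = np.asarray(nodes, dtype=int)
            C[np.ix_(idx, idx)] = level
        for nodes_a, nodes_b, level in plan.couplings:
            if not -1 < level < 1:
                raise ValueError("correlation levels must lie in (-1, 1)")
            ia = np.asarray(nodes_a, dtype=int)
            ib = np.asarray(nodes_b, dtype=int)
            C[np.ix_(ia, ib)] = level
            C[np.ix_(ib, ia)] = level
        np.fill_diagonal(C, 1.0)
        try:
            templates.append(StateTemplate(template_id=s, corr=C, description=plan.description))
        except ValueError as err:
            raise ValueError(
                f"block plan for template {s} yields an invalid correlation matrix: {err}"
            ) from err
    return templates


def is_weak_template(template: StateTemplate) -> bool:
    off = template.corr[~np.eye(template.n_nodes, dtype=bool)]
    return bool(np.all(np.abs(off) <= WEAK_STATE_MAX_OFFDIAG))


def apply_effect_edges(
    templates: list[StateTemplate],
    effect_edges: list[tuple[int, int, int, float]],
) -> list[StateTemplate]:
    """Patient templates: population-level deltas added to chosen edges.

    Raises if any perturbed template loses positive definiteness, naming the
    offending state's edges.
    """
    mats = [t.corr.copy() for t in templates]
    touched: dict[int, list[tuple[int, int, float]]] = {}
    for state_id, i, j, delta in effect_edges:
        if not 0 <= state_id < len(templates):
            raise ValueError(f"effect edge references unknown state {state_id}")
        if i == j:
            raise ValueError("effect edges must be off-diagonal")
        mats[state_id][i, j] += delta
        mats[state_id][j, i] += delta
        touched.setdefault(state_id, []).append((i, j, delta))
    out = []
    for s, (t, M) in enumerate(zip(templates, mats)):
        try:
            out.append(StateTemplate(template_id=s, corr=M, description=t.description))
        except ValueError as err:
            raise ValueError(
                f"perturbed template {s} is invalid after applying effect edges "
                f"{touched.get(s, [])}: {err}"
            ) from err
    return out


def default_effect_edges(
    n_nodes: int = 104, k: int = 4, n_edges: int = 10, delta: float = 0.2
) -> list[tuple[int, int, int, float]]:
    """Planted dual effect: a hypo-connected path on state 0's strong block and
    a hyper-connected path on background edges of state 1.

    Paths (rather than stars) keep the min-eigenvalue shift within what the
    default templates absorb, so the perturbed templates stay positive definite.
    A dual effect needs two states; with k < 2 no edges are planted.
    """
    if k < 2:
        return []
    groups = [g.tolist() for g in np.array_split(np.arange(n_nodes), max(k - 1, 1) + 1)]
    hypo_nodes = groups[0][: n_edges + 1]
    hyper_nodes = groups[2 % len(groups)][: n_edges + 1]
    if len(hypo_nodes) < n_edges + 1 or len(hyper_nodes) < n_edges + 1:
        raise ValueError("not enough nodes per module for the requested effect paths")
    edges = [(0, hypo_nodes[i], hypo_nodes[i + 1], -delta) for i in range(n_edges)]
    edges += [(1, hyper_nodes[i], hyper_nodes[i + 1], +delta) for i in range(n_edges)]
    return edges


def default_cohort_spec(
    n_controls: int = 20,
    n_patients: int = 20,
    n_nodes: int = 104,
    k: int = 4,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """The default study conditions: 4 templates (one weak), 6 x 118 frames at
    TR = 2 s, shared GARCH(1,1) marginals, 10+10 planted effect edges."""
    templates = make_state_templates(n_nodes, k, seed=seed)
    if "effect_edges" not in overrides:
        group_size = n_nodes // (max(k - 1, 1) + 1)
        overrides["effect_edges"] = default_effect_edges(
            n_nodes, k, n_edges=min(10, group_size - 1)
        )
    spec = CohortSpec(
        n_controls=n_controls,
        n_patients=n_patients,
        n_nodes=n_nodes,
        templates=templates,
        seed=seed,
        **overrides,
    )
    # reject unconditionally invalid planted effects up front
    apply_effect_edges(templates, spec.effect_edges)
    return spec


def _subject_rng(root_seed: int, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((root_seed, subject_seed)))


def _sample_state_path(
    rng: np.random.Generator, n_frames: int, k: int, dwell_mean: float
) -> np.ndarray:
    """Semi-Markov path: geometric dwell (mean ``dwell_mean``), uniform moves."""
    labels = np.empty(n_frames, dtype=int)
    p = 1.0 / dwell_mean
    t = 0
    state = int(rng.integers(k))
    while t < n_frames:
        dwell = int(rng.geometric(p)) if k > 1 else n_frames
        end = min(t + dwell, n_frames)
        labels[t:end] = state
        t = end
        if k > 1:
            move = int(rng.integers(k - 1))
            state = move if move < state else move + 1
    return labels


def _garch_scale(
    rng_z: np.ndarray, omega: float, alpha: float, beta: float
) -> np.ndarray:
    """Scale i.i.d.-in-time rows z_t by per-node GARCH(1,1) conditional SDs."""
    T, N = rng_z.shape
    x = np.empty_like(rng_z)
    if alpha == 0 and beta == 0:
        return np.sqrt(omega) * rng_z
    sigma2 = np.full(N, omega / (1.0 - alpha - beta))
    for t in range(T):
        x[t] = np.sqrt(sigma2) * rng_z[t]
        sigma2 = omega + alpha * x[t] ** 2 + beta * sigma2
    return x


def simulate_subject(
    spec: CohortSpec, group: str, subject_seed: int
) -> tuple[RoiTimeSeriesSet, dict[str, np.ndarray]]:
    """Simulate one subject: regime-switching correlated Gaussians with
    GARCH(1,1) marginal variance dynamics.

    Returns the time-series set and the per-run latent state labels.
    """
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    templates = spec.templates
    if group == "patient" and spec.effect_edges:
        templates = apply_effect_edges(templates, spec.effect_edges)
    chols = [np.linalg.cholesky(t.corr) for t in templates]

    rng = _subject_rng(spec.seed, subject_seed)
    omega, alpha, beta = spec.garch_params
    runs, run_ids, labels = [], [], {}
    for r in range(spec.runs_per_subject):
        path = _sample_state_path(rng, spec.frames_per_run, spec.k, spec.dwell_mean)
        z = rng.standard_normal((spec.frames_per_run, spec.n_nodes))
        for s in range(spec.k):
            sel = path == s
            if np.any(sel):
                z[sel] = z[sel] @ chols[s].T
        x = _garch_scale(z, omega, alpha, beta)
        run_id = f"run{r:02d}"
        runs.append(x)
        run_ids.append(run_id)
        labels[run_id] = path
    prefix = "con" if group == "control" else "pat"
    ts = RoiTimeSeriesSet(
        subject_id=f"{prefix}{subject_seed:03d}",
        runs=runs,
        run_ids=run_ids,
        tr=spec.tr,
        node_ids=np.arange(spec.n_nodes),
    )
    return ts, labels


def empirical_state_matrices(
    ts: RoiTimeSeriesSet, labels: dict[str, np.ndarray]
) -> dict[int, StateMatrix]:
    """Within-state sample correlation matrices given per-run frame labels.

    Frames are demeaned per run, pooled across runs by label, and correlated.
    States with fewer than 3 frames are omitted (absent, not zero-filled).
    """
    all_labels = np.concatenate([labels[rid] for rid in ts.run_ids])
    data = ts.concatenated(demean_per_run=True)
    out: dict[int, StateMatrix] = {}
    for s in np.unique(all_labels):
        sel = all_labels == s
        if sel.sum() < 3:
            continue
        C = np.corrcoef(data[sel].T)
        np.fill_diagonal(C, 1.0)
        out[int(s)] = StateMatrix(
            subject_id=ts.subject_id, state_id=int(s), matrix=C, n_frames=int(sel.sum())
        )
    return out


def _mean_effect_strength(
    state_mats: dict[int, StateMatrix],
    templates: list[StateTemplate],
    edges: list[tuple[int, int, int, float]],
) -> float:
    """Mean realized correlation over effect edges; template value if a state is absent."""
    vals = []
    for state_id, i, j, _delta in edges:
        if state_id in state_mats:
            vals.append(state_mats[state_id].matrix[i, j])
        else:
            vals.append(templates[state_id].corr[i, j])
    return float(np.mean(vals)) if vals else 0.0


def _draw_covariates(rng: np.random.Generator, subject_id: str, group: str) -> dict:
    return dict(
        subject_id=subject_id,
        group=group,
        age=float(np.round(rng.normal(54.0, 10.5), 1)),
        sex=("F" if rng.random() < 0.5 else "M"),
        lesion_type=(
            ("ischemic" if rng.random() < 0.75 else "hemorrhagic")
            if group == "patient"
            else "none"
        ),
        race=("white" if rng.random() < 0.4 else "black"),
        education=float(np.round(rng.normal(13.5, 2.6), 1)),
    )


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[RoiTimeSeriesSet], GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort.

    Behavioral scores follow the planted coupling: the latent score is the
    coupling intercept plus ``slope_hypo`` times the subject's realized mean
    hypo-edge strength minus ``slope_hyper`` times the realized mean
    hyper-edge strength, plus Gaussian noise. Subtest columns load linearly on
    the latent score. Covariates are drawn independently of the score, so the
    partial correlation equals the marginal correlation by construction.
    """
    subjects: list[RoiTimeSeriesSet] = []
    label_map: dict[str, dict[str, np.ndarray]] = {}
    behavior_rows, covariate_rows = [], []
    coup = spec.behavior_coupling
    hypo, hyper = spec.hypo_edges(), spec.hyper_edges()
    patient_templates = (
        apply_effect_edges(spec.templates, spec.effect_edges)
        if spec.effect_edges
        else spec.templates
    )

    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    for subject_seed, group in enumerate(groups):
        ts, labels = simulate_subject(spec, group, subject_seed)
        subjects.append(ts)
        label_map[ts.subject_id] = labels

        rng = _subject_rng(spec.seed, 10_000 + subject_seed)  # behavior/covariate stream
        templates = patient_templates if group == "patient" else spec.templates
        state_mats = empirical_state_matrices(ts, labels)
        s_hypo = _mean_effect_strength(state_mats, templates, hypo)
        s_hyper = _mean_effect_strength(state_mats, templates, hyper)
        score = (
            coup.intercept
            + coup.slope_hypo * s_hypo
            - coup.slope_hyper * s_hyper
            + rng.normal(0.0, coup.noise_sd)
        )
        subtests = _SUBTEST_LOADINGS * score + rng.normal(
            0.0, _SUBTEST_NOISE_SD, size=len(SUBTEST_NAMES)
        )
        row = dict(subject_id=ts.subject_id, group=group, latent_score=float(score))
        row.update({name: float(v) for name, v in zip(SUBTEST_NAMES, subtests)})
        behavior_rows.append(row)
        covariate_rows.append(_draw_covariates(rng, ts.subject_id, group))

    truth = GroundTruth(labels=label_map, effect_edges=list(spec.effect_edges), coupling=coup)
    return subjects, truth, pd.DataFrame(behavior_rows), pd.DataFrame(covariate_rows)


def simulate_state_matrix_cohort(
    template: StateTemplate | np.ndarray,
    n_a: int,
    n_b: int,
    effect_edges: list[tuple[int, int, float]] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    state_id: int = 0,
) -> tuple[list[StateMatrix], list[StateMatrix]]:
    """Light-weight cohort of subject-level state matrices for statistical
    calibration studies: template + symmetric edge noise per subject, with
    ``(i, j, delta)`` deltas added for group B.
    """
    C = template.corr if isinstance(template, StateTemplate) else np.asarray(template, float)
    n = C.shape[0]
    iu = upper_indices(n)
    delta = np.zeros_like(C)
    for i, j, d in effect_edges or []:
        delta[i, j] += d
        delta[j, i] += d
    rng = np.random.default_rng(seed)

    def draw(base: np.ndarray, group: str, idx: int) -> StateMatrix:
        noise = np.zeros_like(base)
        noise[iu] = rng.normal(0.0, noise_sd, size=iu[0].size)
        noise += noise.T
        M = base + noise
        np.fill_diagonal(M, 1.0)
        return StateMatrix(
            subject_id=f"{group}{idx:03d}", state_id=state_id, matrix=M, n_frames=1
        )

    group_a = [draw(C, "a", i) for i in range(n_a)]
    group_b = [draw(C + delta, "b", i) for i in range(n_b)]
    return group_a, group_b
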