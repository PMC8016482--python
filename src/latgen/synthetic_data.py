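"""Synthetic behavioral cohorts and multichannel pattern datasets.

These generators produce data with the statistical structure the analyses
assume, so the whole pipeline can be exercised without any downloads.
Behavioral agents produce generalization RTs from one of the four
spreading-activation models (plus Gaussian noise on the standardized scale,
mapped affinely to seconds) and accuracy from a lapse process; training-phase
accuracy follows a saturating within-mini-block curve and training RTs a
noisy power decay. Pattern datasets plant orthonormal factor codes (latent
state, context, category, value) in condition means and add channel-
correlated Gaussian noise, yielding a known ground truth for the RSA
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activation_models import (
    ActivationParams,
    build_network_spec,
    condition_indices,
    predict_raw,
    zscore_predictions,
)
from .rsa import PatternDataset, rsa_condition_labels
from .task_design import (
    TaskDesign,
    TrialSequence,
    build_design,
    generate_blocked_generalization,
    generate_initial_training,
    generate_new_category_training,
    generate_randomized_generalization_runs,
    sample_outcome,
)

__all__ = [
    "AgentConfig",
    "PatternSpec",
    "simulate_subject_behavior",
    "simulate_cohort",
    "generate_pattern_dataset",
    "generate_pattern_cohort",
    "generate_visual_similarity_coords",
]

RT_FLOOR = 0.2  # seconds


@dataclass(frozen=True)
class AgentConfig:
    """Generative settings for one simulated participant.

    ``rt_affine = (s, o)`` maps standardized model RTs to seconds as
    ``s * (z + noise) + o`` with a 0.2 s floor; the defaults put
    post-first-trial generalization RTs near 1.1 s and the first
    generalization trial near 4 s, the regime observed in well-trained
    participants. The default lapse rate of 0.04 yields ~96% correct
    generalization choices.
    """

    generative_model: str = "HLS"
    params: ActivationParams = field(
        default_factory=lambda: ActivationParams(0.9, 0.5, 0.1)
    )
    rt_noise_sd: float = 0.5
    rt_affine: tuple[float, float] = (0.33, 1.1)
    lapse_rate: float = 0.04
    training_learning_rate: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be a probability")
        if self.rt_affine[0] <= 0:
            raise ValueError("RT scale must be positive")


def _training_accuracy(pos: np.ndarray, rate: float, lapse: float) -> np.ndarray:
    """Saturating accuracy curve: chance (0.5) at position 1 rising toward
    the lapse-limited ceiling."""
    p_max = 1.0 - lapse
    return p_max - (p_max - 0.5) * (1.0 - rate) ** (pos - 1)


def _fill_training_behavior(
    design: TaskDesign,
    df: pd.DataFrame,
    agent: AgentConfig,
    rng: np.random.Generator,
) -> None:
    pos = df["trial_in_miniblock"].to_numpy(dtype=float)
    p_correct = _training_accuracy(
        pos, agent.training_learning_rate, agent.lapse_rate
    )
    correct = rng.random(len(df)) < p_correct
    best = np.where(df["value"].to_numpy() > 0, "sell", "pass")
    other = np.where(best == "sell", "pass", "sell")
    choice = np.where(correct, best, other)
    # training RTs: power decay over mini-block position with lognormal noise
    rts = 1.6 * pos ** (-0.25) * np.exp(rng.normal(0.0, 0.25, size=len(df)))
    df["choice"] = choice
    df["correct"] = correct
    df["rt"] = np.maximum(rts, RT_FLOOR)
    outcomes = [
        sample_outcome(design, row, row["choice"], rng).gold
        for _, row in df.iterrows()
    ]
    df["outcome"] = outcomes


def _fill_generalization_behavior(
    design: TaskDesign,
    df: pd.DataFrame,
    agent: AgentConfig,
    rng: np.random.Generator,
    z_groups: pd.Series,
    raw_rt: np.ndarray,
) -> None:
    correct = rng.random(len(df)) >= agent.lapse_rate
    best = np.where(df["value"].to_numpy() > 0, "sell", "pass")
    other = np.where(best == "sell", "pass", "sell")
    df["choice"] = np.where(correct, best, other)
    df["correct"] = correct
    s, o = agent.rt_affine
    z = np.empty(len(df))
    for _, idx in pd.Series(range(len(df))).groupby(z_groups.to_numpy()):
        seg = raw_rt[idx.to_numpy()]
        z[idx.to_numpy()], _ = zscore_predictions(seg)
    noise = rng.normal(0.0, agent.rt_noise_sd, size=len(df))
    df["rt"] = np.maximum(s * (z + noise) + o, RT_FLOOR)


def simulate_subject_behavior(
    design: TaskDesign, agent: AgentConfig, n_runs: int = 6
) -> TrialSequence:
    """Simulate one subject through all phases of the experiment.

    Training phases (initial + reminder, new-category) get lapse-limited
    saturating accuracy and power-decay RTs with feedback sampled from the
    design's reward probabilities. Generalization phases (blocked then the
    pseudo-randomized runs) get RTs from the agent's generative activation
    model. Retrieval dynamics restart at the beginning of each generalization
    segment (the blocked phase and every scanner run, which are separated by
    breaks): a fresh memory network steps through the segment, its raw
    predictions are z-scored within segment and mapped affinely to seconds.
    Without the restarts the Rescorla-Wagner activations would sit at their
    asymptote throughout the scanner runs and the runs would carry no
    retrieval structure at all.
    """
    rng = np.random.default_rng(agent.seed)
    training = generate_initial_training(design, int(rng.integers(2**31)))
    new_training = generate_new_category_training(design, int(rng.integers(2**31)))
    blocked = generate_blocked_generalization(design, int(rng.integers(2**31)))
    runs = generate_randomized_generalization_runs(
        design, int(rng.integers(2**31)), n_runs=n_runs
    )

    train_df = pd.concat(
        [training.trials, new_training.trials], ignore_index=True
    )
    _fill_training_behavior(design, train_df, agent, rng)

    segments = [blocked.trials] + [r.trials for r in runs]
    gen_df = pd.concat(segments, ignore_index=True)
    spec = build_network_spec(agent.generative_model, design)
    raw = np.concatenate(
        [
            predict_raw(spec, condition_indices(design, seg), agent.params)
            for seg in segments
        ]
    )
    z_groups = gen_df["phase"].astype(str) + "/" + gen_df["run"].astype(str)
    _fill_generalization_behavior(design, gen_df, agent, rng, z_groups, raw)

    full = pd.concat([train_df, gen_df], ignore_index=True)
    return TrialSequence(full, design)


def simulate_cohort(
    design_seed: int,
    agent: AgentConfig,
    n_subjects: int,
    seed: int | None = None,
    n_runs: int = 6,
) -> list[TrialSequence]:
    """Independent subjects with per-subject randomized designs (context ->
    latent-state and value assignments are re-drawn per subject, as in the
    experiment) and per-subject agent seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.default_rng(design_seed if seed is None else seed)
    out = []
    for _ in range(n_subjects):
        design = build_design(int(root.integers(2**31)))
        subject_agent = replace(agent, seed=int(root.integers(2**31)))
        out.append(simulate_subject_behavior(design, subject_agent, n_runs=n_runs))
    return out


# ---------------------------------------------------------------------------
# pattern datasets


@dataclass(frozen=True)
class PatternSpec:
    """Settings for synthetic multichannel condition patterns."""

    n_channels: int = 60
    effect_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"ls": 1.0, "context": 0.0, "category": 0.0, "value": 0.0}
    )
    noise_sd: float = 1.0
    noise_channel_corr: float = 0.2
    n_runs: int = 6
    n_residual_samples: int = 120
    n_subjects: int = 16
    seed: int = 0

    def __post_init__(self):
        if any(a < 0 for a in self.effect_amplitudes.values()):
            raise ValueError("effect amplitudes must be non-negative")
        v = self.n_channels
        if not -1.0 / (v - 1) < self.noise_channel_corr < 1.0:
            raise ValueError("noise_channel_corr gives a non-PD covariance")


_FACTOR_LEVELS = {
    "ls": lambda design, c, k: design.state_of(c),
    "context": lambda design, c, k: c,
    "category": lambda design, c, k: k,
    "value": lambda design, c, k: design.value(
        "generalization_blocked", design.state_of(c), k
    ),
}


def _noise_chol(v: int, sd: float, rho: float) -> np.ndarray:
    cov = sd**2 * ((1.0 - rho) * np.eye(v) + rho * np.ones((v, v)))
    return np.linalg.cholesky(cov)


def generate_pattern_dataset(
    design: TaskDesign,
    spec: PatternSpec,
    rng: np.random.Generator | int | None = None,
) -> PatternDataset:
    """One subject's pattern dataset with planted factor codes.

    Each requested factor contributes ``amplitude * code(level)`` to the
    condition means, with all level code vectors drawn jointly orthonormal
    across channels (so planted effects are exactly separable — a convenience
    real data do not offer). Per-run estimates and the residual array share
    one compound-symmetric channel noise covariance.
    """
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(spec.seed if rng is None else rng)
    )
    conds = rsa_condition_labels(design)
    factors = [f for f, a in spec.effect_amplitudes.items() if f in _FACTOR_LEVELS]
    levels: list[tuple[str, object]] = []
    for f in factors:
        seen = []
        for c, k in conds:
            lv = _FACTOR_LEVELS[f](design, c, k)
            if lv not in seen:
                seen.append(lv)
        levels.extend((f, lv) for lv in seen)
    if spec.n_channels < len(levels):
        raise ValueError(
            f"{spec.n_channels} channels cannot orthogonalize {len(levels)} "
            "factor levels"
        )
    q, _ = np.linalg.qr(rng.standard_normal((spec.n_channels, len(levels))))
    codes = {lev: q[:, i] for i, lev in enumerate(levels)}
    mu = np.zeros((len(conds), spec.n_channels))
    for ci, (c, k) in enumerate(conds):
        for f in factors:
            amp = spec.effect_amplitudes[f]
            if amp > 0:
                mu[ci] += amp * codes[(f, _FACTOR_LEVELS[f](design, c, k))]
    chol = _noise_chol(spec.n_channels, spec.noise_sd, spec.noise_channel_corr)
    estimates = mu[None, :, :] + (
        rng.standard_normal((spec.n_runs, len(conds), spec.n_channels)) @ chol.T
    )
    residuals = (
        rng.standard_normal(
            (spec.n_runs, spec.n_residual_samples, spec.n_channels)
        )
        @ chol.T
    )
    return PatternDataset(estimates, residuals, list(conds))


def generate_pattern_cohort(
    spec: PatternSpec, seed: int | None = None
) -> list[tuple[TaskDesign, PatternDataset]]:
    """Pattern datasets for ``spec.n_subjects`` subjects, each with its own
    randomized design and code vectors."""
    root = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for _ in range(spec.n_subjects):
        design = build_design(int(root.integers(2**31)))
        out.append((design, generate_pattern_dataset(design, spec, root)))
    return out


def generate_visual_similarity_coords(
    design: TaskDesign, seed: int
) -> dict[str, np.ndarray]:
    """2-D placement coordinates for the nine context scenes, drawn
    independently of the latent-state assignment (participants judged purely
    visual similarity), so the visual RDM is uncorrelated with the LS RDM in
    expectation."""
    rng = np.random.default_rng(seed)
    return {c: rng.standard_normal(2) for c in design.contexts}
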