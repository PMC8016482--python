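"""Maximum-likelihood fitting and recovery of the activation models.

Each model's three retrieval rates are fit by minimizing the negative
log-likelihood of a Gaussian linear regression of observed z-scored RTs on
the model's z-scored predictions; slope, intercept, and residual variance
are profiled out analytically, leaving only the alphas to the bounded
optimizer. Fits are restarted from multiple uniform random starting points
to avoid local minima (30 by default). Cross-model and parameter recovery
simulate RT data from known generating models and refit, the standard check
that the four models make distinguishable predictions and that their
parameters are identifiable at realistic noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .activation_models import (
    MODEL_KINDS,
    ActivationParams,
    NetworkSpec,
    build_network_spec,
    condition_indices,
    predict_raw,
    zscore_predictions,
)
from .task_design import (
    GENERALIZATION_PHASES,
    TaskDesign,
    TrialSequence,
    generate_randomized_generalization_runs,
)

__all__ = [
    "FitResult",
    "RecoveryMatrix",
    "gaussian_linear_nll",
    "fit_model",
    "fit_conditions",
    "simulate_rts",
    "recovery_sequence",
    "cross_model_recovery",
    "cross_model_recovery_from_reference",
    "parameter_recovery",
    "label_trial_types",
    "rmsd_by_trial_type",
]

SIGMA2_FLOOR = 1e-6
_DEGENERATE_PENALTY = 1e12


@dataclass
class FitResult:
    """Best-of-restarts maximum-likelihood fit of one model to one dataset."""

    model_kind: str
    params: ActivationParams
    nll: float
    n_trials: int
    restart_nlls: list[float] = field(default_factory=list)
    converged: bool = True


def gaussian_linear_nll(predicted_z: np.ndarray, observed_z: np.ndarray) -> float:
    """Negative log-likelihood of a simple linear model observed ~ predicted.

    Ordinary least squares with free slope and intercept; the residual
    variance takes its maximum-likelihood value RSS/n, floored at 1e-6 to
    keep the likelihood bounded on degenerate fits. A constant predictor
    falls back to the intercept-only model.
    """
    pred = np.asarray(predicted_z, dtype=float)
    obs = np.asarray(observed_z, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed vectors differ in length")
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 trials")
    if np.std(pred) < 1e-12:
        resid = obs - obs.mean()
    else:
        slope, intercept = np.polyfit(pred, obs, 1)
        resid = obs - (intercept + slope * pred)
    sigma2 = max(float(resid @ resid) / n, SIGMA2_FLOOR)
    return n / 2.0 * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _objective(spec: NetworkSpec, cond_seq: np.ndarray, observed_z: np.ndarray):
    def fun(alpha: np.ndarray) -> float:
        raw = predict_raw(spec, cond_seq, np.clip(alpha, 0.0, 1.0))
        pred_z, degenerate = zscore_predictions(raw)
        if degenerate:
            return _DEGENERATE_PENALTY
        return gaussian_linear_nll(pred_z, observed_z)

    return fun


def fit_conditions(
    model_kind: str,
    design: TaskDesign,
    cond_seq: np.ndarray,
    observed_z: np.ndarray,
    n_restarts: int = 30,
    seed: int | np.random.Generator | None = None,
) -> FitResult:
    """Fit one model to an observed z-RT vector on a known condition sequence."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spec = build_network_spec(model_kind, design)
    fun = _objective(spec, cond_seq, np.asarray(observed_z, dtype=float))
    starts = rng.uniform(0.0, 1.0, size=(n_restarts, 3))
    best = None
    restart_nlls = []
    any_success = False
    for x0 in starts:
        res = minimize(
            fun, x0, method="L-BFGS-B", bounds=[(0.0, 1.0)] * 3
        )
        restart_nlls.append(float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = ActivationParams(*np.clip(best.x, 0.0, 1.0))
    return FitResult(
        model_kind=model_kind,
        params=params,
        nll=float(best.fun),
        n_trials=len(observed_z),
        restart_nlls=restart_nlls,
        converged=any_success,
    )


def _usable_trials(df: pd.DataFrame) -> pd.DataFrame:
    mask = (
        df["phase"].isin(GENERALIZATION_PHASES)
        & (df["correct"] == True)  # noqa: E712 - NaN-safe comparison
        & df["rt"].notna()
    )
    return df.loc[mask]


def fit_model(
    model_kind: str,
    trial_data: TrialSequence,
    n_restarts: int = 30,
    seed: int | None = None,
) -> FitResult:
    """Fit a model to a subject's correct generalization RTs (in seconds).

    Error and missed trials are dropped, the remaining RTs z-scored, and the
    alphas optimized in [0, 1]^3 by L-BFGS-B from ``n_restarts`` uniform
    random starting points.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    df = _usable_trials(trial_data.trials)
    if len(df) < 10:
        raise ValueError(f"only {len(df)} usable trials (< 10)")
    rts = df["rt"].to_numpy(dtype=float)
    observed_z = (rts - rts.mean()) / rts.std()
    cond_seq = condition_indices(trial_data.design, df)
    return fit_conditions(
        model_kind, trial_data.design, cond_seq, observed_z, n_restarts, seed
    )


def simulate_rts(
    model_kind: str,
    params: ActivationParams,
    sequence: TrialSequence,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Model-generated z-RTs: prediction plus Gaussian noise, re-z-scored."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spec = build_network_spec(model_kind, sequence.design)
    cond_seq = condition_indices(sequence.design, sequence.trials)
    pred_z, _ = zscore_predictions(predict_raw(spec, cond_seq, params))
    noisy = pred_z + rng.normal(0.0, noise_sd, size=len(pred_z)) if noise_sd > 0 else pred_z
    sd = noisy.std()
    if sd < 1e-12:
        return np.zeros_like(noisy)
    return (noisy - noisy.mean()) / sd


def recovery_sequence(
    design: TaskDesign, seed: int, n_trials: int = 540
) -> TrialSequence:
    """Pseudo-randomized generalization trials for recovery simulations.

    As many 180-trial randomized runs as needed are concatenated (one
    continuous network run), truncated to ``n_trials``. Randomized orders
    decorrelate condition identity from network state, which is what makes
    the four models' predictions distinguishable: on purely mini-blocked
    sequences their best-fit predictions correlate above 0.999.
    """
    n_runs = int(np.ceil(n_trials / 180))
    runs = generate_randomized_generalization_runs(design, seed, n_runs=n_runs)
    df = (
        pd.concat([r.trials for r in runs], ignore_index=True)
        .iloc[:n_trials]
        .reset_index(drop=True)
    )
    return TrialSequence(df, design)


@dataclass
class RecoveryMatrix:
    """Mean NLL of each fitting model on data from each generating model."""

    models: tuple[str, ...]
    nlls: np.ndarray  # (generator, fitter, replicate)

    @property
    def mean_nll(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.nlls.mean(axis=2), index=self.models, columns=self.models
        )

    def diagonal_dominant(self) -> bool:
        """True if every generator is best fit (lowest mean NLL) by itself."""
        m = self.nlls.mean(axis=2)
        return bool(np.all(np.argmin(m, axis=1) == np.arange(len(self.models))))


def cross_model_recovery(
    design: TaskDesign,
    params_per_model: dict[str, ActivationParams],
    noise_sd: float = 0.5,
    n_replicates: int = 20,
    n_trials: int = 540,
    n_restarts: int = 10,
    seed: int | None = None,
) -> RecoveryMatrix:
    """Simulate RTs from each model and refit all four.

    For each generating model and replicate, a fresh mini-blocked sequence is
    simulated with ``noise_sd`` z-units of Gaussian RT noise at the supplied
    generating parameters, and every candidate model is fit to it. Diagonal
    dominance of the resulting mean-NLL matrix shows the models make
    distinguishably different predictions.
    """
    models = tuple(params_per_model)
    rng = np.random.default_rng(seed)
    nlls = np.zeros((len(models), len(models), n_replicates))
    for rep in range(n_replicates):
        seq = recovery_sequence(design, int(rng.integers(2**31)), n_trials)
        cond_seq = condition_indices(design, seq.trials)
        for gi, gen in enumerate(models):
            obs = simulate_rts(gen, params_per_model[gen], seq, noise_sd, rng)
            for fi, fit_kind in enumerate(models):
                res = fit_conditions(
                    fit_kind, design, cond_seq, obs, n_restarts, rng
                )
                nlls[gi, fi, rep] = res.nll
    return RecoveryMatrix(models=models, nlls=nlls)


def cross_model_recovery_from_reference(
    design: TaskDesign,
    reference_model: str = "HLS",
    reference_params: ActivationParams | None = None,
    noise_sd: float = 0.5,
    n_replicates: int = 20,
    n_trials: int = 540,
    reference_restarts: int = 15,
    n_restarts: int = 10,
    seed: int | None = None,
) -> RecoveryMatrix:
    """Cross-model recovery with generator parameters fit to reference data.

    Mirrors the experimental procedure: each replicate plays the role of one
    participant whose behavior comes from the reference model (HLS, the
    model that accounts for participants best); all four models are first
    fit to that reference data, and each model then generates data from its
    *own* best-fit parameters, which every model is fit to in turn. Using
    per-model best-fit generators keeps the comparison honest: a single
    shared parameter vector can sit where two models' predictions are
    near-collinear.
    """
    if reference_params is None:
        reference_params = ActivationParams(0.9, 0.5, 0.1)
    models = MODEL_KINDS
    rng = np.random.default_rng(seed)
    nlls = np.zeros((len(models), len(models), n_replicates))
    for rep in range(n_replicates):
        seq = recovery_sequence(design, int(rng.integers(2**31)), n_trials)
        cond_seq = condition_indices(design, seq.trials)
        reference = simulate_rts(
            reference_model, reference_params, seq, noise_sd, rng
        )
        fitted = {
            m: fit_conditions(
                m, design, cond_seq, reference, reference_restarts, rng
            ).params
            for m in models
        }
        for gi, gen in enumerate(models):
            obs = simulate_rts(gen, fitted[gen], seq, noise_sd, rng)
            for fi, fit_kind in enumerate(models):
                nlls[gi, fi, rep] = fit_conditions(
                    fit_kind, design, cond_seq, obs, n_restarts, rng
                ).nll
    return RecoveryMatrix(models=models, nlls=nlls)


def parameter_recovery(
    design: TaskDesign,
    model_kind: str,
    params: ActivationParams,
    noise_sd: float = 0.5,
    n_replicates: int = 20,
    n_trials: int = 540,
    n_restarts: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeatedly simulate and refit one model; rows are replicates with the
    recovered alphas and the fit NLL."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        seq = recovery_sequence(design, int(rng.integers(2**31)), n_trials)
        cond_seq = condition_indices(design, seq.trials)
        obs = simulate_rts(model_kind, params, seq, noise_sd, rng)
        res = fit_conditions(model_kind, design, cond_seq, obs, n_restarts, rng)
        rows.append(
            {
                "replicate": rep,
                "alpha1": res.params.alpha1,
                "alpha2": res.params.alpha2,
                "alpha3": res.params.alpha3,
                "nll": res.nll,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-type taxonomy (mini-blocked generalization)


def label_trial_types(sequence: TrialSequence | pd.DataFrame) -> np.ndarray:
    """Label every mini-blocked generalization trial with its trial type.

    First trials of a context's first mini-block are labeled by the
    presentation order of its latent state (1-3) and of the context within
    the state (1-2), e.g. ``first_ls2_ctx1``; first trials of later
    mini-blocks of a context are ``category_switch``; everything else is
    ``within_miniblock``.
    """
    df = sequence.trials if isinstance(sequence, TrialSequence) else sequence
    labels = np.empty(len(df), dtype=object)
    pos = 0
    for _, block in df.groupby("block", sort=False):
        ls_order: dict[str, int] = {}
        ctx_rank: dict[str, int] = {}
        per_ls_count: dict[str, int] = {}
        prev_ctx = None
        prev_cat = None
        first_of_context: dict[str, bool] = {}
        for i, (_, row) in enumerate(block.iterrows()):
            ctx, cat, ls = row["context"], row["category"], row["latent_state"]
            new_miniblock = ctx != prev_ctx or cat != prev_cat
            if ctx not in ctx_rank:
                if ls not in ls_order:
                    ls_order[ls] = len(ls_order) + 1
                per_ls_count[ls] = per_ls_count.get(ls, 0) + 1
                ctx_rank[ctx] = per_ls_count[ls]
                first_of_context[ctx] = True
            if new_miniblock:
                if first_of_context[ctx]:
                    labels[pos + i] = f"first_ls{ls_order[ls]}_ctx{ctx_rank[ctx]}"
                    first_of_context[ctx] = False
                else:
                    labels[pos + i] = "category_switch"
            else:
                labels[pos + i] = "within_miniblock"
            prev_ctx, prev_cat = ctx, cat
        pos += len(block)
    return labels


def rmsd_by_trial_type(
    observed_z: np.ndarray, predicted_z: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Root-mean-square deviation of predictions from data per trial type."""
    obs = np.asarray(observed_z, dtype=float)
    pred = np.asarray(predicted_z, dtype=float)
    labels = np.asarray(labels)
    if not (len(obs) == len(pred) == len(labels)):
        raise ValueError("vectors and labels must be aligned")
    out: dict[str, float] = {}
    for lab in pd.unique(labels):
        m = labels == lab
        if not m.any():  # pragma: no cover - unique() guarantees nonempty
            warnings.warn(f"empty trial-type class {lab!r}")
            continue
        out[str(lab)] = float(np.sqrt(np.mean((obs[m] - pred[m]) ** 2)))
    return out
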