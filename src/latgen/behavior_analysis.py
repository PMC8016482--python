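"""Behavioral analyses: learning-curve rates, switch costs, LS repetition.

Learning within mini-blocks is summarized by fitting a power function
``y = a * t**x`` to the position-wise mean accuracy or RT curve, where ``t``
is the trial number within a mini-block; ``x`` is the rate of change and is
the quantity compared across phases (fast improvement during training vs a
flat curve during generalization indicates inference rather than learning).
Switch costs on the pseudo-randomized generalization trials compare
log-transformed, within-session z-scored RTs between trials where the latent
state switched vs stayed, restricted to context-switch trials so context and
latent-state changes are not conflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .task_design import TrialSequence

__all__ = [
    "PowerCurveFit",
    "SwitchCostTable",
    "fit_power_curve",
    "learning_curve_rates",
    "switch_cost_analysis",
    "switch_cost_cells",
    "ls_repetition_curves",
    "paired_ttest",
    "wilcoxon_signed_rank",
    "bonferroni",
]

SWITCH_CELLS = ("ls_switch_ctx_switch", "ls_stay_ctx_switch", "ls_stay_ctx_stay")


@dataclass
class PowerCurveFit:
    """Least-squares fit of y = a * t**x over trial positions t = 1..n."""

    a: float
    x: float
    sse: float


def fit_power_curve(
    y: np.ndarray, n_starts: int = 10, seed: int | np.random.Generator | None = None
) -> PowerCurveFit:
    """Best-of-``n_starts`` least-squares fit of a power curve to ``y``.

    Starting points for (a, x) are drawn from a standard normal; the fit is
    unconstrained, and the lowest-SSE solution across starts is returned.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("y must be a vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    t = np.arange(1, len(y) + 1, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def resid(p):
        return p[0] * t ** p[1] - y

    best = None
    for _ in range(n_starts):
        x0 = rng.standard_normal(2)
        try:
            res = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - pathological start
            continue
        sse = float(res.fun @ res.fun)
        if best is None or sse < best[0]:
            best = (sse, res.x)
    sse, (a, x) = best
    return PowerCurveFit(a=float(a), x=float(x), sse=sse)


def _miniblock_groups(df: pd.DataFrame) -> list[pd.DataFrame]:
    """Mini-blocks in order of appearance (maximal runs of one condition)."""
    cond = df["context"].astype(str) + "|" + df["category"].astype(str)
    change = (cond != cond.shift()).cumsum()
    return [g for _, g in df.groupby(change, sort=False)]


def learning_curve_rates(
    sequence: TrialSequence,
    phase: str,
    measure: str = "accuracy",
    window: int = 6,
    max_miniblocks: int | None = None,
    first_context_only: bool = False,
    n_starts: int = 10,
    seed: int | None = None,
) -> PowerCurveFit:
    """Power-curve rate of the position-wise mean learning curve of a phase.

    Mini-blocks of the given phase are aligned on within-mini-block position
    1..``window`` and averaged position-wise; accuracy curves use the mean of
    the correct indicator, RT curves the geometric mean RT (means taken on
    the log scale, matching the log-domain summary of RTs). With
    ``first_context_only`` the curve is restricted to the first mini-block of
    each of the first three contexts in presentation order.
    """
    df = sequence.trials[sequence.trials["phase"] == phase]
    if df.empty:
        raise ValueError(f"no trials for phase {phase!r}")
    blocks = _miniblock_groups(df)
    if first_context_only:
        chosen, seen_ctx = [], []
        for g in blocks:
            ctx = g["context"].iloc[0]
            if ctx not in seen_ctx:
                if len(seen_ctx) < 3:
                    chosen.append(g)
                seen_ctx.append(ctx)
        blocks = chosen
    elif max_miniblocks is not None:
        blocks = blocks[:max_miniblocks]
    if not blocks:
        raise ValueError("no mini-blocks available")
    curves = []
    for g in blocks:
        g = g.iloc[:window]
        if measure == "accuracy":
            vals = g["correct"].to_numpy(dtype=float)
        elif measure == "rt":
            vals = np.log(g["rt"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown measure {measure!r}")
        padded = np.full(window, np.nan)
        padded[: len(vals)] = vals
        curves.append(padded)
    mean_curve = np.nanmean(np.vstack(curves), axis=0)
    if measure == "rt":
        mean_curve = np.exp(mean_curve)
    return fit_power_curve(mean_curve, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# switch costs


def _standardized_log_rt(df: pd.DataFrame) -> pd.Series:
    logrt = np.log(df["rt"].astype(float))
    return logrt.groupby(df["session"]).transform(
        lambda s: (s - s.mean()) / s.std()
    )


def switch_cost_cells(sequence: TrialSequence) -> pd.Series:
    """One subject's mean standardized log-RT per switch cell.

    RTs from correct pseudo-randomized generalization trials are
    log-transformed and z-scored within session. Each trial with a defined
    previous trial in the same run is assigned to one of three cells by
    whether the latent state and context switched from the previous trial
    (a context stay implies a latent-state stay).
    """
    df = sequence.trials[
        sequence.trials["phase"] == "generalization_randomized"
    ].copy()
    if df.empty:
        raise ValueError("no pseudo-randomized generalization trials")
    correct_mask = (df["correct"] == True) & df["rt"].notna()  # noqa: E712
    z = pd.Series(np.nan, index=df.index)
    z.loc[correct_mask] = _standardized_log_rt(df.loc[correct_mask])
    cells: dict[str, list[float]] = {c: [] for c in SWITCH_CELLS}
    for (_, _), run in df.groupby(["session", "run"], sort=False):
        prev_ls = run["latent_state"].shift()
        prev_ctx = run["context"].shift()
        for idx in run.index[1:]:  # run-initial trial has no previous trial
            if not correct_mask.loc[idx]:
                continue
            ctx_stay = run.at[idx, "context"] == prev_ctx.loc[idx]
            ls_stay = run.at[idx, "latent_state"] == prev_ls.loc[idx]
            if ctx_stay:
                cells["ls_stay_ctx_stay"].append(z.loc[idx])
            elif ls_stay:
                cells["ls_stay_ctx_switch"].append(z.loc[idx])
            else:
                cells["ls_switch_ctx_switch"].append(z.loc[idx])
    return pd.Series(
        {c: float(np.mean(v)) if v else np.nan for c, v in cells.items()}
    )


@dataclass
class SwitchCostTable:
    """Per-subject switch-cell means and the latent-state switch contrast."""

    cell_means: pd.DataFrame  # subjects x SWITCH_CELLS
    ls_switch_cost: pd.Series  # ls_switch - ls_stay, context-switch trials only
    t_statistic: float
    p_value: float

    @property
    def mean_switch_cost(self) -> float:
        return float(self.ls_switch_cost.mean())


def switch_cost_analysis(
    sequences: TrialSequence | list[TrialSequence],
) -> SwitchCostTable:
    """Latent-state switch cost across a cohort (or a single subject).

    The contrast of interest is computed only among context-switch trials:
    mean z-log-RT when the latent state also switched minus when it stayed.
    Group significance is a paired (one-sample on the difference) t-test.
    """
    if isinstance(sequences, TrialSequence):
        sequences = [sequences]
    rows = [switch_cost_cells(s) for s in sequences]
    cell_means = pd.DataFrame(rows).reset_index(drop=True)
    diff = cell_means["ls_switch_ctx_switch"] - cell_means["ls_stay_ctx_switch"]
    if len(diff.dropna()) >= 2 and diff.std() > 0:
        t, p = stats.ttest_1samp(diff.dropna(), 0.0)
    else:
        t, p = np.nan, np.nan
    return SwitchCostTable(
        cell_means=cell_means,
        ls_switch_cost=diff,
        t_statistic=float(t),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# LS repetition structure in the mini-blocked generalization phase


@dataclass
class LsRepetitionResult:
    """Per-cell RT curves and rates organized by latent-state presentation
    order (1-3) and context order within state (first or second)."""

    curves: pd.DataFrame  # columns: ls_order, ctx_order, position, rt
    fits: dict[tuple[int, int], PowerCurveFit]
    first_trial_rt: dict[tuple[int, int], float]


def ls_repetition_curves(
    sequence: TrialSequence, n_starts: int = 10, seed: int | None = None
) -> LsRepetitionResult:
    """RT curves for the first mini-block of each context during blocked
    generalization, organized by LS and context presentation order."""
    df = sequence.trials[
        sequence.trials["phase"] == "generalization_blocked"
    ]
    if df.empty:
        raise ValueError("no blocked generalization trials")
    ls_order: dict[str, int] = {}
    ctx_rank: dict[str, int] = {}
    per_ls: dict[str, int] = {}
    rows = []
    fits: dict[tuple[int, int], PowerCurveFit] = {}
    first_rt: dict[tuple[int, int], float] = {}
    rng = np.random.default_rng(seed)
    for g in _miniblock_groups(df):
        ctx = g["context"].iloc[0]
        ls = g["latent_state"].iloc[0]
        if ctx in ctx_rank:
            continue  # only the first mini-block of each context
        if ls not in ls_order:
            ls_order[ls] = len(ls_order) + 1
        per_ls[ls] = per_ls.get(ls, 0) + 1
        ctx_rank[ctx] = per_ls[ls]
        cell = (ls_order[ls], ctx_rank[ctx])
        rts = g["rt"].to_numpy(dtype=float)
        for pos, rt in enumerate(rts, start=1):
            rows.append(
                {
                    "ls_order": cell[0],
                    "ctx_order": cell[1],
                    "position": pos,
                    "rt": rt,
                }
            )
        finite = rts[np.isfinite(rts)]
        if len(finite) >= 3:
            fits[cell] = fit_power_curve(finite, n_starts=n_starts, seed=rng)
        first_rt[cell] = float(rts[0]) if np.isfinite(rts[0]) else np.nan
    if len(fits) and set(first_rt) != {(m, n) for m in (1, 2, 3) for n in (1, 2)}:
        raise ValueError("incomplete design coverage in blocked generalization")
    return LsRepetitionResult(
        curves=pd.DataFrame(rows), fits=fits, first_trial_rt=first_rt
    )


# ---------------------------------------------------------------------------
# group statistics


def paired_ttest(a, b) -> tuple[float, float]:
    t, p = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    res = stats.wilcoxon(np.asarray(a, float), None if b is None else np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    return np.minimum(p * len(p), 1.0)
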