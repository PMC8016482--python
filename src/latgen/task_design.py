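"""Three-phase latent-state generalization task: design and trial sequences.

The task is an acquired-equivalence paradigm. Nine scene contexts are
partitioned into three latent states (LSs), three contexts per state; all
contexts within a state share the same category -> value mapping. In the
initial training phase participants learn values of three "old" item
categories (hands, foods, leaves) across the nine contexts. In a second phase
three "new" categories (faces, animals, objects) are trained in a single
context per LS. The final generalization phase probes the six held-out
contexts with the new categories and gives no feedback: correct responding
requires transferring the new category values across contexts via the shared
latent state.

Trial sequences are returned as :class:`TrialSequence` objects wrapping a
pandas DataFrame with one row per trial (see :data:`TRIAL_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "OLD_CATEGORIES",
    "NEW_CATEGORIES",
    "LATENT_STATES",
    "TRIAL_COLUMNS",
    "TaskDesign",
    "TrialSequence",
    "Outcome",
    "build_design",
    "generate_initial_training",
    "generate_new_category_training",
    "generate_blocked_generalization",
    "generate_randomized_generalization_runs",
    "sample_outcome",
    "transition_rates",
    "chance_transition_rates",
]

OLD_CATEGORIES = ("hands", "foods", "leaves")
NEW_CATEGORIES = ("faces", "animals", "objects")
LATENT_STATES = ("A", "B", "C")

#: Column schema for trial tables (CSV round-trips through :mod:`latgen.io`).
TRIAL_COLUMNS = [
    "phase",
    "session",
    "run",
    "block",
    "miniblock",
    "trial_in_miniblock",
    "context",
    "latent_state",
    "category",
    "value",
    "iti",
    "choice",
    "outcome",
    "correct",
    "rt",
]

TRAINING_PHASES = ("initial", "reminder", "new_training")
GENERALIZATION_PHASES = ("generalization_blocked", "generalization_randomized")

# Reward probabilities and gold payoffs (gain, loss) per phase, as used in the
# experiment; the generalization payoffs are doubled from new-category
# training to incentivize the feedback-free phase.
REWARD_PROB_HIGH = 0.9
REWARD_PROB_LOW = 0.1
PAYOFFS_BY_PHASE = {
    "initial": (50, 25),
    "reminder": (50, 25),
    "new_training": (50, 100),
    "generalization_blocked": (100, 200),
    "generalization_randomized": (100, 200),
}


@dataclass(frozen=True)
class TaskDesign:
    """Full specification of one participant's task randomization.

    Parameters
    ----------
    contexts_by_state
        Latent state -> the three scene contexts assigned to it, in
        introduction order (index 0 appears in training blocks 1-2, etc.).
    preferred_old_category
        Latent state -> the single old category with the high reward
        probability during initial training (the other two are low).
    low_value_new_category
        Latent state -> the single new category with the low reward
        probability in the new-category and generalization phases (the other
        two are high: two categories per state are rewarded in these phases).
    trained_set_index
        Which context (by introduction order, 0..2) of each latent state is
        used for new-category training; the remaining six contexts are held
        out for generalization.
    rng_seed
        Seed the design was drawn from; all assignments are functions of it.
    """

    contexts_by_state: dict[str, tuple[str, str, str]]
    preferred_old_category: dict[str, str]
    low_value_new_category: dict[str, str]
    trained_set_index: int
    rng_seed: int
    reward_prob_high: float = REWARD_PROB_HIGH
    reward_prob_low: float = REWARD_PROB_LOW
    payoffs_by_phase: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(PAYOFFS_BY_PHASE)
    )

    # -- structure ---------------------------------------------------------
    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(
            c for ls in LATENT_STATES for c in self.contexts_by_state[ls]
        )

    @property
    def context_to_state(self) -> dict[str, str]:
        return {
            c: ls for ls in LATENT_STATES for c in self.contexts_by_state[ls]
        }

    @property
    def trained_contexts(self) -> tuple[str, ...]:
        """One context per latent state used in new-category training."""
        return tuple(
            self.contexts_by_state[ls][self.trained_set_index]
            for ls in LATENT_STATES
        )

    @property
    def heldout_contexts(self) -> tuple[str, ...]:
        """The six contexts probed in the generalization phases."""
        return tuple(
            c
            for ls in LATENT_STATES
            for i, c in enumerate(self.contexts_by_state[ls])
            if i != self.trained_set_index
        )

    def state_of(self, context: str) -> str:
        return self.context_to_state[context]

    def sibling_heldout(self, context: str) -> str:
        """The other held-out context of ``context``'s latent state."""
        ls = self.state_of(context)
        others = [
            c
            for c in self.contexts_by_state[ls]
            if c != context and c in self.heldout_contexts
        ]
        if context not in self.heldout_contexts or len(others) != 1:
            raise ValueError(f"{context!r} is not a held-out context")
        return others[0]

    # -- values ------------------------------------------------------------
    def value(self, phase: str, latent_state: str, category: str) -> int:
        """Value sign (+1 / -1) of a category in a latent state for a phase."""
        if category in OLD_CATEGORIES:
            if phase not in ("initial", "reminder"):
                raise ValueError(
                    f"old category {category!r} does not occur in {phase!r}"
                )
            return 1 if category == self.preferred_old_category[latent_state] else -1
        if category in NEW_CATEGORIES:
            if phase in ("initial", "reminder"):
                raise ValueError(
                    f"new category {category!r} does not occur in {phase!r}"
                )
            return -1 if category == self.low_value_new_category[latent_state] else 1
        raise ValueError(f"unknown category {category!r}")

    def reward_probability(self, phase: str, context: str, category: str) -> float:
        sign = self.value(phase, self.state_of(context), category)
        return self.reward_prob_high if sign > 0 else self.reward_prob_low

    def to_dict(self) -> dict:
        return {
            "contexts_by_state": {
                ls: list(v) for ls, v in self.contexts_by_state.items()
            },
            "preferred_old_category": dict(self.preferred_old_category),
            "low_value_new_category": dict(self.low_value_new_category),
            "trained_set_index": self.trained_set_index,
            "rng_seed": self.rng_seed,
            "reward_prob_high": self.reward_prob_high,
            "reward_prob_low": self.reward_prob_low,
            "payoffs_by_phase": {
                k: list(v) for k, v in self.payoffs_by_phase.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            contexts_by_state={
                ls: tuple(v) for ls, v in d["contexts_by_state"].items()
            },
            preferred_old_category=dict(d["preferred_old_category"]),
            low_value_new_category=dict(d["low_value_new_category"]),
            trained_set_index=int(d["trained_set_index"]),
            rng_seed=int(d["rng_seed"]),
            reward_prob_high=float(d.get("reward_prob_high", REWARD_PROB_HIGH)),
            reward_prob_low=float(d.get("reward_prob_low", REWARD_PROB_LOW)),
            payoffs_by_phase={
                k: tuple(v)
                for k, v in d.get("payoffs_by_phase", PAYOFFS_BY_PHASE).items()
            },
        )


@dataclass
class TrialSequence:
    """Ordered trial records plus the design they were generated from."""

    trials: pd.DataFrame
    design: TaskDesign

    def __len__(self) -> int:
        return len(self.trials)

    def concat(self, other: "TrialSequence") -> "TrialSequence":
        if other.design is not self.design and other.design != self.design:
            raise ValueError("cannot concatenate sequences from different designs")
        return TrialSequence(
            pd.concat([self.trials, other.trials], ignore_index=True), self.design
        )


def build_design(seed: int) -> TaskDesign:
    """Draw a participant-level task randomization.

    Independent draws (all functions of ``seed``): partition of the nine
    scene contexts into latent states, the preferred old category of each
    state (a permutation, so each state prefers a distinct category), the
    low-value new category of each state (independent per state, as the new
    assignments were randomized with respect to the initial training), and
    which context set is used for new-category training.
    """
    rng = np.random.default_rng(seed)
    scenes = [f"s{i + 1}" for i in range(9)]
    perm = rng.permutation(9)
    contexts_by_state = {
        ls: tuple(scenes[j] for j in perm[3 * i : 3 * i + 3])
        for i, ls in enumerate(LATENT_STATES)
    }
    old_perm = rng.permutation(3)
    preferred_old = {
        ls: OLD_CATEGORIES[old_perm[i]] for i, ls in enumerate(LATENT_STATES)
    }
    low_new = {
        ls: NEW_CATEGORIES[rng.integers(3)] for ls in LATENT_STATES
    }
    trained_set_index = int(rng.integers(3))
    return TaskDesign(
        contexts_by_state=contexts_by_state,
        preferred_old_category=preferred_old,
        low_value_new_category=low_new,
        trained_set_index=trained_set_index,
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# inter-trial intervals


@lru_cache(maxsize=8)
def _lognormal_mu_for_clipped_mean(
    target_mean: float, sigma: float, lo: float, hi: float
) -> float:
    """Log-scale location so that the [lo, hi]-clipped lognormal mean matches."""

    def clipped_mean(mu: float) -> float:
        za, zb = (np.log(lo) - mu) / sigma, (np.log(hi) - mu) / sigma
        body = np.exp(mu + sigma**2 / 2) * (
            norm.cdf(zb - sigma) - norm.cdf(za - sigma)
        )
        return lo * norm.cdf(za) + body + hi * norm.sf(zb)

    return brentq(lambda m: clipped_mean(m) - target_mean, np.log(lo), np.log(hi))


def _training_itis(rng: np.random.Generator, n: int, sigma: float = 0.5) -> np.ndarray:
    """Lognormal ITIs with mean 1 s after clipping to [0.5, 4] s."""
    mu = _lognormal_mu_for_clipped_mean(1.0, sigma, 0.5, 4.0)
    return np.clip(rng.lognormal(mu, sigma, size=n), 0.5, 4.0)


# ---------------------------------------------------------------------------
# sequence generators


def _empty_frame(n: int) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n), columns=TRIAL_COLUMNS)
    df["choice"] = pd.array([pd.NA] * n, dtype="string")
    return df


def _emit_miniblocks(
    design: TaskDesign,
    phase: str,
    session: int,
    run: int,
    blocks: Iterable[tuple[int, list[tuple[str, str]], int]],
    rng: np.random.Generator,
    iti_sampler,
) -> TrialSequence:
    """Assemble trials from (block index, ordered conditions, length) specs."""
    rows: list[dict] = []
    for block_idx, conditions, mb_len in blocks:
        for mb_idx, (context, category) in enumerate(conditions):
            ls = design.state_of(context)
            sign = design.value(phase, ls, category)
            for t in range(mb_len):
                rows.append(
                    {
                        "phase": phase,
                        "session": session,
                        "run": run,
                        "block": block_idx,
                        "miniblock": mb_idx,
                        "trial_in_miniblock": t + 1,
                        "context": context,
                        "latent_state": ls,
                        "category": category,
                        "value": sign,
                    }
                )
    df = pd.DataFrame(rows)
    df["iti"] = iti_sampler(rng, len(df))
    for col in ("choice", "outcome", "correct", "rt"):
        df[col] = np.nan
    df["choice"] = df["choice"].astype(object)
    return TrialSequence(df[TRIAL_COLUMNS], design)


def _nested_block_conditions(
    contexts: list[str],
    categories: tuple[str, ...],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Mini-block order nested by context: contexts shuffled, categories
    shuffled independently within each context."""
    out: list[tuple[str, str]] = []
    for context in rng.permutation(contexts):
        for category in rng.permutation(categories):
            out.append((str(context), str(category)))
    return out


def generate_initial_training(
    design: TaskDesign, seed: int, session: int = 2
) -> TrialSequence:
    """Initial training: six 54-trial blocks plus a 216-trial reminder block.

    Blocks 1-2 use the first-introduced context of each latent state, 3-4 the
    second, 5-6 the third ("roadwork" introduces each new context set). Each
    block covers its 3 contexts x 3 old categories in 6-trial mini-blocks
    nested by context. The reminder block covers all nine contexts x three
    categories in 8-trial mini-blocks (216 trials).
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for block in range(6):
        set_idx = block // 2
        ctxs = [design.contexts_by_state[ls][set_idx] for ls in LATENT_STATES]
        blocks.append(
            (block, _nested_block_conditions(ctxs, OLD_CATEGORIES, rng), 6)
        )
    seq = _emit_miniblocks(
        design, "initial", session, 0, blocks, rng, _training_itis
    )
    reminder = _emit_miniblocks(
        design,
        "reminder",
        session,
        0,
        [(6, _nested_block_conditions(list(design.contexts), OLD_CATEGORIES, rng), 8)],
        rng,
        _training_itis,
    )
    return seq.concat(reminder)


def generate_new_category_training(
    design: TaskDesign, seed: int, session: int = 2
) -> TrialSequence:
    """New-category training: one 90-trial block, 3 trained contexts x 3 new
    categories in 10-trial mini-blocks, mini-block order randomized."""
    rng = np.random.default_rng(seed)
    conditions = [
        (c, k) for c in design.trained_contexts for k in NEW_CATEGORIES
    ]
    order = [conditions[i] for i in rng.permutation(len(conditions))]
    return _emit_miniblocks(
        design, "new_training", session, 0, [(0, order, 10)], rng, _training_itis
    )


def generate_blocked_generalization(
    design: TaskDesign, seed: int, session: int = 2
) -> TrialSequence:
    """Mini-blocked generalization: 18 held-out conditions x 10-trial
    mini-blocks (180 trials), nested by context, no feedback."""
    rng = np.random.default_rng(seed)
    order = _nested_block_conditions(
        list(design.heldout_contexts), NEW_CATEGORIES, rng
    )
    return _emit_miniblocks(
        design,
        "generalization_blocked",
        session,
        0,
        [(0, order, 10)],
        rng,
        _training_itis,
    )


def generate_randomized_generalization_runs(
    design: TaskDesign,
    seed: int,
    n_runs: int = 6,
    transition_tolerance: float = 0.05,
    max_attempts: int = 2000,
) -> list[TrialSequence]:
    """Pseudo-randomized generalization runs for the scanner sessions.

    Each run presents 10 trials of each of the 18 held-out conditions in an
    order whose same-LS and same-context transition rates fall within
    ``transition_tolerance`` of chance (6/18 and 3/18), found by rejection
    sampling of balanced permutations. ITIs are uniform on [1, 9] s. The
    default six runs split as three per scanner session (sessions 2 and 3),
    1080 trials in total.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = [
        (c, k) for c in design.heldout_contexts for k in NEW_CATEGORIES
    ]
    states = np.array([ord(design.state_of(c)) for c, _ in conditions])
    ctx_ids = np.array(
        [design.heldout_contexts.index(c) for c, _ in conditions]
    )
    base = np.repeat(np.arange(18), 10)
    runs: list[TrialSequence] = []
    for run in range(n_runs):
        for attempt in range(max_attempts):
            order = rng.permutation(base)
            ls_rate = np.mean(states[order[1:]] == states[order[:-1]])
            ctx_rate = np.mean(ctx_ids[order[1:]] == ctx_ids[order[:-1]])
            if (
                abs(ls_rate - 6 / 18) <= transition_tolerance
                and abs(ctx_rate - 3 / 18) <= transition_tolerance
            ):
                break
        else:
            raise RuntimeError(
                "could not satisfy transition-rate tolerance "
                f"{transition_tolerance} in {max_attempts} attempts"
            )
        rows = []
        session = 2 if run < (n_runs + 1) // 2 else 3
        for t, idx in enumerate(order):
            context, category = conditions[idx]
            ls = design.state_of(context)
            rows.append(
                {
                    "phase": "generalization_randomized",
                    "session": session,
                    "run": run,
                    "block": 0,
                    "miniblock": -1,
                    "trial_in_miniblock": t + 1,
                    "context": context,
                    "latent_state": ls,
                    "category": category,
                    "value": design.value("generalization_randomized", ls, category),
                }
            )
        df = pd.DataFrame(rows)
        df["iti"] = rng.uniform(1.0, 9.0, size=len(df))
        for col in ("choice", "outcome", "correct", "rt"):
            df[col] = np.nan
        df["choice"] = df["choice"].astype(object)
        runs.append(TrialSequence(df[TRIAL_COLUMNS], design))
    return runs


# ---------------------------------------------------------------------------
# outcomes and diagnostics


class Outcome(NamedTuple):
    """Feedback for one trial: realized gold change, the (counterfactual)
    sell outcome shown regardless of choice, and whether the draw rewarded."""

    gold: int
    counterfactual: int
    rewarded: bool


def sample_outcome(
    design: TaskDesign, trial: pd.Series, choice: str, rng: np.random.Generator | int
) -> Outcome:
    """Draw the probabilistic outcome of a feedback-phase trial.

    Selling yields +gain with the condition's reward probability and -loss
    otherwise; passing changes nothing but the would-be sell outcome is still
    reported as feedback. Generalization trials give no feedback and raise.
    """
    phase = trial["phase"]
    if phase in GENERALIZATION_PHASES:
        raise ValueError("generalization trials provide no feedback")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = design.reward_probability(phase, trial["context"], trial["category"])
    gain, loss = design.payoffs_by_phase[phase]
    rewarded = bool(rng.random() < p)
    sell_outcome = gain if rewarded else -loss
    if choice == "sell":
        return Outcome(sell_outcome, sell_outcome, rewarded)
    if choice == "pass":
        return Outcome(0, sell_outcome, rewarded)
    raise ValueError(f"unknown choice {choice!r}")


def transition_rates(sequence: TrialSequence | pd.DataFrame) -> dict[str, float]:
    """Fraction of consecutive trial pairs sharing latent state / context."""
    df = sequence.trials if isinstance(sequence, TrialSequence) else sequence
    if len(df) < 2:
        raise ValueError("sequence must contain at least two trials")
    ls = df["latent_state"].to_numpy()
    ctx = df["context"].to_numpy()
    return {
        "ls_rate": float(np.mean(ls[1:] == ls[:-1])),
        "context_rate": float(np.mean(ctx[1:] == ctx[:-1])),
    }


def chance_transition_rates(design: TaskDesign) -> dict[str, float]:
    """Analytic chance rates of feature repetition under i.i.d. uniform
    draws over the 18 generalization conditions (6/18 same-LS, 3/18
    same-context), computed by enumerating ordered condition pairs."""
    conds = [(c, k) for c in design.heldout_contexts for k in NEW_CATEGORIES]
    n = len(conds)
    same_ls = sum(
        design.state_of(a) == design.state_of(b)
        for a, _ in conds
        for b, _ in conds
    )
    same_ctx = sum(a == b for a, _ in conds for b, _ in conds)
    return {"ls_rate": same_ls / n**2, "context_rate": same_ctx / n**2}
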