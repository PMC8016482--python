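"""Task structure: design randomization, trial layouts, outcome sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latgen.task_design import (
    LATENT_STATES,
    NEW_CATEGORIES,
    OLD_CATEGORIES,
    build_design,
    chance_transition_rates,
    generate_blocked_generalization,
    generate_initial_training,
    generate_new_category_training,
    generate_randomized_generalization_runs,
    sample_outcome,
    transition_rates,
)


def miniblocks(df):
    cond = df["context"].astype(str) + "|" + df["category"].astype(str)
    return [g for _, g in df.groupby((cond != cond.shift()).cumsum(), sort=False)]


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_design_invariants(seed):
    d = build_design(seed)
    assert len(d.contexts) == 9
    for ls in LATENT_STATES:
        assert len(d.contexts_by_state[ls]) == 3
    # trained + held-out partition the nine contexts
    assert sorted(d.trained_contexts + d.heldout_contexts) == sorted(d.contexts)
    # each LS prefers exactly one old category, distinct across LSs
    assert sorted(d.preferred_old_category.values()) == sorted(OLD_CATEGORIES)
    # one low-value new category per LS => two rewarded new categories
    for ls in LATENT_STATES:
        signs = [d.value("new_training", ls, k) for k in NEW_CATEGORIES]
        assert signs.count(1) == 2 and signs.count(-1) == 1
        old_signs = [d.value("initial", ls, k) for k in OLD_CATEGORIES]
        assert old_signs.count(1) == 1 and old_signs.count(-1) == 2


def test_design_deterministic():
    assert build_design(7) == build_design(7)
    assert build_design(7) != build_design(8)


def test_old_category_preference_covers_all_permutations():
    # brute-force enumeration over seeds reaches all 3! assignments
    seen = {
        tuple(build_design(s).preferred_old_category[ls] for ls in LATENT_STATES)
        for s in range(100)
    }
    assert seen == set(itertools.permutations(OLD_CATEGORIES))


def test_initial_training_layout(design):
    seq = generate_initial_training(design, 1)
    df = seq.trials
    initial = df[df["phase"] == "initial"]
    reminder = df[df["phase"] == "reminder"]
    assert initial.groupby("block").size().tolist() == [54] * 6
    assert len(reminder) == 216
    # blocks 1-2 use the first-introduced context of each LS, and so on
    for block in range(6):
        expected = {
            design.contexts_by_state[ls][block // 2] for ls in LATENT_STATES
        }
        b = initial[initial["block"] == block]
        assert set(b["context"]) == expected
        assert b.groupby(["context", "category"]).size().eq(6).all()
    # mini-blocks are contiguous constant-condition runs of the right length
    for g in miniblocks(initial):
        assert len(g) == 6
    for g in miniblocks(reminder):
        assert len(g) == 8
    assert len(miniblocks(reminder)) == 27
    itis = df["iti"].to_numpy(dtype=float)
    assert ((itis >= 0.5) & (itis <= 4.0)).all()
    assert abs(itis.mean() - 1.0) < 0.1


def test_new_category_training_layout(design):
    seq = generate_new_category_training(design, 2)
    df = seq.trials
    assert len(df) == 90
    assert set(df["context"]) == set(design.trained_contexts)
    groups = miniblocks(df)
    assert len(groups) == 9
    assert all(len(g) == 10 for g in groups)
    assert df.groupby(["context", "category"]).size().eq(10).all()


def test_blocked_generalization_layout(design, blocked_seq):
    df = blocked_seq.trials
    assert len(df) == 180
    conds = df.groupby(["context", "category"]).size()
    assert len(conds) == 18 and conds.eq(10).all()
    assert set(df["context"]) == set(design.heldout_contexts)
    assert set(df["category"]) == set(NEW_CATEGORIES)
    groups = miniblocks(df)
    assert all(len(g) == 10 for g in groups)
    per_ctx = pd.Series([g["context"].iloc[0] for g in groups]).value_counts()
    assert per_ctx.eq(3).all()


def test_randomized_runs(design):
    runs = generate_randomized_generalization_runs(design, 4)
    assert len(runs) == 6
    assert sum(len(r) for r in runs) == 1080
    assert {r.trials["session"].iloc[0] for r in runs} == {2, 3}
    se_ls = 3 * np.sqrt((6 / 18) * (12 / 18) / 179)
    se_ctx = 3 * np.sqrt((3 / 18) * (15 / 18) / 179)
    for r in runs:
        df = r.trials
        assert df.groupby(["context", "category"]).size().eq(10).all()
        itis = df["iti"].to_numpy(dtype=float)
        assert ((itis >= 1.0) & (itis <= 9.0)).all()
        rates = transition_rates(r)
        assert abs(rates["ls_rate"] - 6 / 18) < max(se_ls, 0.05 + 1e-9)
        assert abs(rates["context_rate"] - 3 / 18) < max(se_ctx, 0.05 + 1e-9)


def test_randomized_runs_overtight_tolerance_raises(design):
    with pytest.raises(RuntimeError):
        generate_randomized_generalization_runs(
            design, 4, n_runs=1, transition_tolerance=1e-6, max_attempts=20
        )


def test_sequences_reproducible(design):
    a = generate_blocked_generalization(design, 11).trials
    b = generate_blocked_generalization(design, 11).trials
    pd.testing.assert_frame_equal(a, b)
    c = generate_blocked_generalization(design, 12).trials
    assert not a["context"].equals(c["context"])


def test_sample_outcome_probabilities(design, rng):
    df = generate_new_category_training(design, 2).trials
    high = df[df["value"] > 0].iloc[0]
    low = df[df["value"] < 0].iloc[0]
    n = 20_000
    rewards = np.mean(
        [sample_outcome(design, high, "sell", rng).gold > 0 for _ in range(n)]
    )
    assert abs(rewards - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)
    rewards_low = np.mean(
        [sample_outcome(design, low, "sell", rng).gold > 0 for _ in range(n)]
    )
    assert abs(rewards_low - 0.1) < 3 * np.sqrt(0.9 * 0.1 / n)
    out = sample_outcome(design, high, "pass", rng)
    assert out.gold == 0 and out.counterfactual in (50, -100)


def test_sample_outcome_generalization_raises(design, blocked_seq):
    with pytest.raises(ValueError):
        sample_outcome(design, blocked_seq.trials.iloc[0], "sell", 0)


def test_transition_rates_edge_cases(design, blocked_seq):
    df = blocked_seq.trials
    repeated = pd.concat([df.iloc[[0]]] * 5, ignore_index=True)
    assert transition_rates(repeated) == {"ls_rate": 1.0, "context_rate": 1.0}
    # alternate two conditions from different latent states
    other = df[df["latent_state"] != df["latent_state"].iloc[0]].iloc[[0]]
    alt = pd.concat([df.iloc[[0]], other] * 3, ignore_index=True)
    assert transition_rates(alt) == {"ls_rate": 0.0, "context_rate": 0.0}


def test_chance_transition_rates(design):
    rates = chance_transition_rates(design)
    assert rates["ls_rate"] == pytest.approx(1 / 3)
    assert rates["context_rate"] == pytest.approx(1 / 6)
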