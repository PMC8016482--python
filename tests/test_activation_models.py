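"""Spreading-activation models: rate tables, dynamics, predictions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from latgen.activation_models import (
    MODEL_KINDS,
    ActivationParams,
    build_network,
    condition_list,
    predict_sequence,
    rw_update,
    zscore_predictions,
)
from latgen.task_design import (
    NEW_CATEGORIES,
    OLD_CATEGORIES,
    generate_randomized_generalization_runs,
)


@pytest.mark.parametrize(
    "a, r, expected",
    [(0.0, 0.5, 0.5), (1.0, 0.9, 1.0), (0.5, 0.5, 0.75), (0.3, 0.0, 0.3)],
)
def test_rw_update_closed_form(a, r, expected):
    assert rw_update(a, r) == pytest.approx(expected)


@pytest.mark.parametrize("a, r", [(-0.1, 0.5), (0.5, 1.2), (1.1, 0.0)])
def test_rw_update_rejects_out_of_range(a, r):
    with pytest.raises(ValueError):
        rw_update(a, r)


def test_node_inventories(design):
    car = build_network("CAR", design)
    assert len(car.nodes) == 54  # 27 initial + 9 new-training + 18 probe conjunctions
    ls = build_network("LS", design)
    assert sum(n[0] == "ls" for n in ls.nodes) == 3
    assert len(ls.nodes) == 21
    hls = build_network("HLS", design)
    assert len(hls.nodes) == 66
    # every context node has exactly one parent latent state
    for node in hls.nodes:
        if node[0] == "ctx":
            assert design.state_of(node[1]) in "ABC"
    # IAR: 9 contexts + the category-value pairs actually experienced
    iar = build_network("IAR", design)
    experienced = set()
    for lstate in "ABC":
        for cat in OLD_CATEGORIES:
            experienced.add((cat, design.value("initial", lstate, cat)))
        for cat in NEW_CATEGORIES:
            experienced.add((cat, design.value("new_training", lstate, cat)))
    assert len(iar.nodes) == 9 + len(experienced)


def test_unknown_model_kind_rejected(design):
    with pytest.raises(ValueError):
        build_network("XYZ", design)


def test_rate_table_examples(design, mid_params):
    """Hand-checkable retrieval rates for one probe at alphas (0.5, 0.2, 0.1)."""
    ctx, cat = condition_list(design)[0]
    sign = design.value("new_training", design.state_of(ctx), cat)
    sibling = design.sibling_heldout(ctx)

    hls = build_network("HLS", design).rates_for((ctx, cat), mid_params)
    assert hls[("ctx", ctx)] == pytest.approx(0.25)  # a1^2
    assert hls[("ctxcat", ctx, cat)] == pytest.approx(0.125)  # a1^3
    assert hls[("ctx", sibling)] == pytest.approx(0.1)  # a1*a2
    assert hls[("ctxcat", sibling, cat)] == pytest.approx(0.02)  # a1*a2^2

    iar = build_network("IAR", design).rates_for((ctx, cat), mid_params)
    assert iar[("catval", cat, sign)] == pytest.approx(0.0625)  # a1^4
    assert iar[("ctx", ctx)] == pytest.approx(0.5)  # a1

    ls_net = build_network("LS", design).rates_for((ctx, cat), mid_params)
    other_ls = next(s for s in "ABC" if s != design.state_of(ctx))
    assert ls_net[("lscat", other_ls, cat)] == pytest.approx(0.01)  # a3^2

    car = build_network("CAR", design).rates_for((ctx, cat), mid_params)
    assert car[(ctx, cat)] == pytest.approx(0.5**2 * 0.2**2)  # a1^2*a2^2
    assert car[(sibling, cat)] == pytest.approx(0.5**2 * 0.2**3)  # a1^2*a2^3


def test_step_trial_fresh_and_repeat(design, mid_params):
    cond = condition_list(design)[0]
    for kind, fresh_rt in [("HLS", 2.0), ("IAR", 2.0), ("LS", 2.0), ("CAR", 1.0)]:
        net = build_network(kind, design)
        assert net.step_trial(cond, mid_params) == pytest.approx(fresh_rt)
    net = build_network("HLS", design)
    net.step_trial(cond, mid_params)
    # second identical probe: 2 - (0.25 + 0.125), hand-simulated
    assert net.step_trial(cond, mid_params) == pytest.approx(1.625)


def _oracle_hls(design, conds, a1, a2, a3):
    """Independent dict-based HLS simulation (no shared code with the
    package's vectorized engine)."""
    act = {}
    for s in "ABC":
        act[("ls", s)] = 0.0
    for c in design.contexts:
        act[("ctx", c)] = 0.0
        for k in OLD_CATEGORIES + NEW_CATEGORIES:
            act[("ctxcat", c, k)] = 0.0
    out = []
    for ctx, cat in conds:
        ls = design.state_of(ctx)
        out.append(2.0 - act[("ctx", ctx)] - act[("ctxcat", ctx, cat)])
        rates = {}
        for node in act:
            if node[0] == "ls":
                rates[node] = a1 if node[1] == ls else a3
            elif node[0] == "ctx":
                if node[1] == ctx:
                    rates[node] = a1**2
                elif design.state_of(node[1]) == ls:
                    rates[node] = a1 * a2
                else:
                    rates[node] = a3**2
            else:
                _, c, k = node
                if c == ctx and k == cat:
                    rates[node] = a1**3
                elif design.state_of(c) == ls:
                    rates[node] = a1 * a2**2
                else:
                    rates[node] = a3**3
        for node, r in rates.items():
            act[node] = act[node] + r * (1 - act[node])
    return np.array(out)


def test_predict_sequence_matches_bruteforce_oracle(design, mid_params):
    conds = condition_list(design)
    toy = [conds[i % 18] for i in (0, 0, 3, 1, 7, 0, 12, 12, 5, 3,
                                   9, 0, 17, 2, 2, 8, 15, 3, 0, 6)]
    df = pd.DataFrame(
        {
            "phase": "generalization_blocked",
            "context": [c for c, _ in toy],
            "category": [k for _, k in toy],
        }
    )
    z, flag = predict_sequence("HLS", mid_params, df, design=design)
    raw = _oracle_hls(design, toy, 0.5, 0.2, 0.1)
    expected = (raw - raw.mean()) / raw.std()
    assert not flag
    np.testing.assert_allclose(z, expected, atol=1e-12)


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_activations_bounded_and_monotone(design, kind, rng, blocked_seq):
    params = ActivationParams(*rng.uniform(0, 1, 3))
    net = build_network(kind, design)
    prev = net.activation.copy()
    prev_rt_by_cond = {}
    for _, row in blocked_seq.trials.iloc[:90].iterrows():
        cond = (row["context"], row["category"])
        rt = net.step_trial(cond, params)
        assert np.all(net.activation >= prev - 1e-12)
        assert np.all((net.activation >= 0) & (net.activation <= 1 + 1e-12))
        if cond in prev_rt_by_cond:
            assert rt <= prev_rt_by_cond[cond] + 1e-12
        prev_rt_by_cond[cond] = rt
        prev = net.activation.copy()


def test_zscore_affine_invariance(design, mid_params, blocked_seq):
    z, _ = predict_sequence("CAR", mid_params, blocked_seq)
    # any affine read-out choice yields identical standardized predictions
    from latgen.activation_models import build_network_spec, condition_indices, predict_raw

    raw = predict_raw(
        build_network_spec("CAR", design),
        condition_indices(design, blocked_seq.trials),
        mid_params,
    )
    z2, _ = zscore_predictions(3.7 * raw - 1.2)
    np.testing.assert_allclose(z, z2, atol=1e-9)


@pytest.mark.parametrize("kind", ["LS", "HLS"])
def test_no_cross_ls_leakage_without_mediated_rates(design, kind):
    """With a2 = a3 = 0 a condition's first-presentation RT ignores
    other-LS history."""
    params = ActivationParams(0.8, 0.0, 0.0)
    conds = condition_list(design)
    target = conds[0]
    other_ls = [
        c for c in conds if design.state_of(c[0]) != design.state_of(target[0])
    ]
    net_a = build_network(kind, design)
    rt_a = net_a.step_trial(target, params)
    net_b = build_network(kind, design)
    for c in other_ls[:6]:
        net_b.step_trial(c, params)
    rt_b = net_b.step_trial(target, params)
    assert rt_a == pytest.approx(rt_b)


def test_models_make_distinct_predictions(design, canonical_params):
    run = generate_randomized_generalization_runs(design, 21, n_runs=1)[0]
    preds = {
        kind: predict_sequence(kind, canonical_params, run)[0]
        for kind in MODEL_KINDS
    }
    for a, b in itertools.combinations(MODEL_KINDS, 2):
        assert np.corrcoef(preds[a], preds[b])[0, 1] < 1.0 - 1e-6


def test_hls_switch_cost_in_predictions(design, canonical_params):
    """Decreasing rates produce slower predicted RTs on latent-state
    switches than stays, among context-switch trials."""
    runs = generate_randomized_generalization_runs(design, 22, n_runs=3)
    sw, st = [], []
    for run in runs:
        z, _ = predict_sequence("HLS", canonical_params, run)
        ctx = run.trials["context"].to_numpy()
        ls = run.trials["latent_state"].to_numpy()
        for t in range(1, len(z)):
            if ctx[t] == ctx[t - 1]:
                continue
            (sw if ls[t] != ls[t - 1] else st).append(z[t])
    assert np.mean(sw) > np.mean(st)


def test_degenerate_prediction_flagged(design, blocked_seq):
    z, flag = predict_sequence(
        "HLS", ActivationParams(0.0, 0.0, 0.0), blocked_seq
    )
    assert flag and np.all(z == 0)


def test_predict_sequence_rejects_tiny_input(design, blocked_seq):
    with pytest.raises(ValueError):
        predict_sequence(
            "HLS", ActivationParams(0.5, 0.2, 0.1), blocked_seq.trials.iloc[:1],
            design=design,
        )
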