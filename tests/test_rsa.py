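"""RSA: hypothesis RDM geometry, crossnobis estimator, regression, group tests."""

import numpy as np
import pandas as pd
import pytest

from latgen.rsa import (
    RDM,
    PatternDataset,
    build_hypothesis_rdm,
    crossnobis_rdm,
    group_test,
    interaction_rdm,
    rdm_regression,
    rsa_condition_labels,
    shrinkage_covariance,
)
from latgen.synthetic_data import (
    PatternSpec,
    generate_pattern_dataset,
    generate_visual_similarity_coords,
)


def test_lower_triangle_has_153_entries(design):
    rdm = build_hypothesis_rdm("ls", design)
    assert len(rdm.ltv) == 153
    assert rdm.matrix.shape == (18, 18)


def test_ls_rdm_block_structure(design):
    rdm = build_hypothesis_rdm("ls", design)
    conds = rsa_condition_labels(design)
    # independent enumeration: 6 conditions per LS -> C(6,2)=15 close pairs per LS
    n_close = sum(
        design.state_of(conds[i][0]) == design.state_of(conds[j][0])
        for i in range(18)
        for j in range(i)
    )
    assert n_close == 45
    assert (rdm.ltv == 1).sum() == n_close
    assert (rdm.ltv == 2).sum() == 153 - n_close


def test_category_rdm_ordinal_distances(design):
    rdm = build_hypothesis_rdm("category", design)
    conds = rsa_condition_labels(design)
    lookup = {}
    for i in range(18):
        for j in range(i):
            lookup[frozenset((conds[i][1], conds[j][1]))] = rdm.matrix[i, j]
    assert lookup[frozenset(("faces",))] == 1
    assert lookup[frozenset(("faces", "animals"))] == 2
    assert lookup[frozenset(("animals", "objects"))] == 3
    assert lookup[frozenset(("faces", "objects"))] == 4
    # animacy ordering: objects closer to animals than to faces
    assert (
        lookup[frozenset(("faces", "objects"))]
        > lookup[frozenset(("animals", "objects"))]
        > lookup[frozenset(("objects",))]
    )


def test_value_and_context_rdms_are_binary(design):
    for factor in ("value", "context"):
        rdm = build_hypothesis_rdm(factor, design)
        assert set(np.unique(rdm.ltv)) == {1.0, 2.0}


def test_visual_rdm_requires_and_uses_coords(design):
    with pytest.raises(ValueError):
        build_hypothesis_rdm("visual", design)
    coords = generate_visual_similarity_coords(design, 3)
    rdm = build_hypothesis_rdm("visual", design, coords)
    conds = rsa_condition_labels(design)
    i, j = 5, 2
    expected = np.linalg.norm(coords[conds[i][0]] - coords[conds[j][0]])
    assert rdm.matrix[i, j] == pytest.approx(expected)


def test_interaction_rdm_products(design):
    a = build_hypothesis_rdm("ls", design)
    b = build_hypothesis_rdm("category", design)
    self_product = interaction_rdm(a, a)
    assert (self_product.ltv >= 0).all()
    inter = interaction_rdm(a, b)
    # mean of the z-scored product equals the Pearson correlation
    assert inter.ltv.mean() == pytest.approx(
        np.corrcoef(a.ltv, b.ltv)[0, 1], abs=1e-12
    )
    const = RDM.from_ltv(np.full(153, 2.0), a.conditions)
    with pytest.warns(UserWarning):
        zero = interaction_rdm(a, const)
    assert np.all(zero.ltv == 0)


def test_crossnobis_null_mean_near_zero(design):
    spec = PatternSpec(
        n_channels=30,
        effect_amplitudes={"ls": 0.0},
        n_runs=4,
        n_residual_samples=80,
    )
    means = [
        crossnobis_rdm(generate_pattern_dataset(design, spec, s)).ltv.mean()
        for s in range(40)
    ]
    se = np.std(means) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 3 * se + 1e-4


def test_crossnobis_recovers_true_distance(design, rng):
    """Planted difference with identity noise: E[d_ij] = ||mu_i - mu_j||^2 / V."""
    v, r = 50, 8
    conds = rsa_condition_labels(design)
    mu = np.zeros((18, v))
    delta = np.zeros(v)
    delta[:10] = 0.8
    mu[0] += delta
    ds = []
    for _ in range(40):
        est = mu[None] + rng.standard_normal((r, 18, v))
        res = rng.standard_normal((r, 100, v))
        rdm = crossnobis_rdm(PatternDataset(est, res, conds))
        ds.append(rdm.matrix[0, 1])
    expected = float(delta @ delta) / v
    assert np.mean(ds) == pytest.approx(expected, abs=0.03)


def test_crossnobis_channel_permutation_invariance(design, rng):
    spec = PatternSpec(n_channels=25, effect_amplitudes={"ls": 1.0}, n_runs=3)
    pats = generate_pattern_dataset(design, spec, 7)
    perm = rng.permutation(spec.n_channels)
    permuted = PatternDataset(
        pats.estimates[:, :, perm], pats.residuals[:, :, perm], pats.conditions
    )
    np.testing.assert_allclose(
        crossnobis_rdm(pats).ltv, crossnobis_rdm(permuted).ltv, atol=1e-8
    )


def test_crossnobis_requires_two_runs(design):
    spec = PatternSpec(n_channels=20, n_runs=1)
    pats = generate_pattern_dataset(design, spec, 0)
    with pytest.raises(ValueError):
        crossnobis_rdm(pats)


def test_shrinkage_covariance_keeps_diagonal(rng):
    x = rng.standard_normal((50, 8)) @ np.diag(np.arange(1, 9) ** 0.5)
    s = shrinkage_covariance(x)
    sample = np.cov(x - x.mean(0), rowvar=False)
    np.testing.assert_allclose(np.diag(s), np.diag(sample), rtol=1e-8)
    # off-diagonals shrink toward zero
    off = ~np.eye(8, dtype=bool)
    assert np.all(np.abs(s[off]) <= np.abs(sample[off]) + 1e-12)


def test_rdm_regression_exact_on_orthogonal_predictors(design, rng):
    q, _ = np.linalg.qr(rng.standard_normal((153, 3)))
    preds = {f"p{i}": q[:, i] for i in range(3)}
    z0 = (q[:, 0] - q[:, 0].mean()) / q[:, 0].std()
    emp = RDM.from_ltv(2.5 * z0, rsa_condition_labels(design))
    res = rdm_regression(emp, preds)
    assert res.betas["p0"] == pytest.approx(2.5, abs=1e-6)
    assert abs(res.betas["p1"]) < 1e-6 and abs(res.betas["p2"]) < 1e-6
    assert not res.rank_deficient


def test_rdm_regression_flags_duplicates(design):
    ls = build_hypothesis_rdm("ls", design)
    emp = RDM.from_ltv(np.arange(153, dtype=float), ls.conditions)
    res = rdm_regression(emp, {"a": ls, "b": ls})
    assert res.rank_deficient


def test_group_test_calibration_and_signflip(rng):
    betas = pd.DataFrame({"x": rng.standard_normal(16) + 0.6})
    res = group_test(betas, n_permutations=4000, seed=1)
    assert res.loc["x", "p"] == pytest.approx(res.loc["x", "p_signflip"], abs=0.02)
    flat = pd.DataFrame({"x": np.ones(8)})
    with pytest.warns(UserWarning):
        res2 = group_test(flat)
    assert np.isnan(res2.loc["x", "t"])
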