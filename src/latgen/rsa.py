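"""Representational similarity analysis with crossnobis distances.

An empirical representational dissimilarity matrix (RDM) over the 18
generalization conditions (6 held-out contexts x 3 new categories) is
estimated from multivoxel (or any multichannel) pattern estimates by the
cross-validated Mahalanobis ("crossnobis") distance: pattern differences are
computed independently in pairs of runs, whitened by a shrinkage estimate of
the noise covariance, and their inner products averaged over run pairs.
Cross-validation makes the distance unbiased — zero in expectation for
conditions with identical true patterns, so small negative values are
legitimate.

Hypothesis RDMs encode the dissimilarity structure a pure representation of
one task factor would predict (same/different latent state, context, or
value; graded animacy-based distances for item category; measured visual
similarity of the context scenes). Their lower triangles are z-scored and
regressed simultaneously on the empirical RDM's lower triangle; per-subject
regression coefficients are then tested against zero at the group level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .task_design import NEW_CATEGORIES, TaskDesign

__all__ = [
    "RDM",
    "PatternDataset",
    "RdmRegressionResult",
    "rsa_condition_labels",
    "build_hypothesis_rdm",
    "interaction_rdm",
    "shrinkage_covariance",
    "crossnobis_rdm",
    "rdm_regression",
    "group_test",
]

N_CONDITIONS = 18
N_PAIRS = N_CONDITIONS * (N_CONDITIONS - 1) // 2

# graded category distances: animates (faces, animals) are more similar to
# each other than to inanimate objects, and objects more similar to animals
# than to faces
CATEGORY_DISTANCES = {
    ("faces", "faces"): 1,
    ("animals", "animals"): 1,
    ("objects", "objects"): 1,
    ("faces", "animals"): 2,
    ("animals", "objects"): 3,
    ("faces", "objects"): 4,
}


def rsa_condition_labels(design: TaskDesign) -> list[tuple[str, str]]:
    """Canonical condition order: held-out contexts (grouped by latent
    state) crossed with the new categories."""
    return [(c, k) for c in design.heldout_contexts for k in NEW_CATEGORIES]


@dataclass
class RDM:
    """18 x 18 condition dissimilarity matrix with a canonical 153-entry
    lower-triangle vector view (``ltv``)."""

    matrix: np.ndarray
    conditions: list[tuple[str, str]]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.conditions)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match condition count")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("RDM must be symmetric")

    @property
    def ltv(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.conditions), k=-1)
        return self.matrix[i, j]

    @classmethod
    def from_ltv(
        cls, ltv: np.ndarray, conditions: list[tuple[str, str]]
    ) -> "RDM":
        n = len(conditions)
        m = np.zeros((n, n))
        i, j = np.tril_indices(n, k=-1)
        m[i, j] = ltv
        m[j, i] = ltv
        return cls(m, conditions)


def build_hypothesis_rdm(
    factor: str,
    design: TaskDesign,
    coords: dict[str, np.ndarray] | None = None,
) -> RDM:
    """Hypothesis RDM for one task factor.

    ``ls``, ``context``, ``value``: ordinal distances, 1 when two conditions
    share the factor and 2 otherwise. ``category``: graded animacy distances
    (within-category 1; faces-animals 2; animals-objects 3; faces-objects 4).
    ``visual``: Euclidean distance between the two conditions' context
    coordinates from the similarity judgment task (required via ``coords``).
    """
    conds = rsa_condition_labels(design)
    n = len(conds)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ci, ki = conds[i]
            cj, kj = conds[j]
            if factor == "ls":
                m[i, j] = 1 if design.state_of(ci) == design.state_of(cj) else 2
            elif factor == "context":
                m[i, j] = 1 if ci == cj else 2
            elif factor == "value":
                vi = design.value("generalization_blocked", design.state_of(ci), ki)
                vj = design.value("generalization_blocked", design.state_of(cj), kj)
                m[i, j] = 1 if vi == vj else 2
            elif factor == "category":
                key = (ki, kj) if (ki, kj) in CATEGORY_DISTANCES else (kj, ki)
                m[i, j] = CATEGORY_DISTANCES[key]
            elif factor == "visual":
                if coords is None:
                    raise ValueError("visual RDM requires context coordinates")
                m[i, j] = float(
                    np.linalg.norm(np.asarray(coords[ci]) - np.asarray(coords[cj]))
                )
            else:
                raise ValueError(f"unknown factor {factor!r}")
    return RDM(m, conds)


def _zscore_ltv(v: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = v.std()
    if sd < 1e-12:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


def interaction_rdm(rdm_a: RDM, rdm_b: RDM) -> RDM:
    """Interaction predictor: elementwise product of the two z-scored lower
    triangles (defined on the lower triangle; symmetrized for storage)."""
    if rdm_a.conditions != rdm_b.conditions:
        raise ValueError("condition orders do not match")
    za, da = _zscore_ltv(rdm_a.ltv)
    zb, db = _zscore_ltv(rdm_b.ltv)
    if da or db:
        warnings.warn("constant RDM in interaction; returning zero vector")
        return RDM.from_ltv(np.zeros(len(za)), rdm_a.conditions)
    return RDM.from_ltv(za * zb, rdm_a.conditions)


# ---------------------------------------------------------------------------
# patterns and crossnobis


@dataclass
class PatternDataset:
    """Per-run condition pattern estimates plus residuals for noise
    covariance estimation.

    ``estimates``: (runs, conditions, channels); ``residuals``: (runs,
    samples, channels) drawn from the same noise process; ``conditions``:
    labels matching the design's canonical RSA ordering.
    """

    estimates: np.ndarray
    residuals: np.ndarray
    conditions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.estimates.ndim != 3 or self.residuals.ndim != 3:
            raise ValueError("estimates and residuals must be 3-D arrays")
        if self.estimates.shape[2] != self.residuals.shape[2]:
            raise ValueError("channel counts differ")
        if self.estimates.shape[2] < 2:
            raise ValueError("need at least 2 channels")

    @property
    def n_runs(self) -> int:
        return self.estimates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.estimates.shape[2]


def shrinkage_covariance(residuals: np.ndarray) -> np.ndarray:
    """Diagonal-target shrinkage estimate of the noise covariance.

    Residual samples from all runs are pooled and the off-diagonal entries
    of the sample covariance shrunk toward zero with the analytic intensity
    of Schafer & Strimmer: lambda* = sum Var(s_ij) / sum s_ij^2 over i != j,
    clipped to [0, 1]. Keeps the estimate well-conditioned when channels
    outnumber samples.
    """
    x = np.asarray(residuals, dtype=float)
    if x.ndim == 3:
        x = x.reshape(-1, x.shape[2])
    n, v = x.shape
    if n < 2:
        raise ValueError("need at least 2 residual samples")
    x = x - x.mean(axis=0)
    s = (x.T @ x) / (n - 1)
    w = np.einsum("ki,kj->kij", x, x)  # per-sample outer products
    var_s = w.var(axis=0, ddof=0) * n / (n - 1) ** 2
    off = ~np.eye(v, dtype=bool)
    denom = float((s[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    sigma = (1.0 - lam) * s
    np.fill_diagonal(sigma, np.diag(s))
    return sigma


def crossnobis_rdm(patterns: PatternDataset) -> RDM:
    """Cross-validated Mahalanobis RDM averaged over all run pairs.

    For each condition pair (i, j) and ordered run pair (A != B):
    ``(b_iA - b_jA)' Sigma^-1 (b_iB - b_jB) / V``, averaged over pairs, with
    ``Sigma`` the shrinkage noise covariance from the pooled residuals and
    ``V`` the channel count. Distances can be negative by design.
    """
    if patterns.n_runs < 2:
        raise ValueError("crossnobis needs at least 2 runs")
    sigma = shrinkage_covariance(patterns.residuals)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance singular after shrinkage") from err
    r, c, v = patterns.estimates.shape
    # whiten: u = L^-1 b' so that d' Sigma^-1 d'' = (L^-1 d).(L^-1 d'')
    white = np.stack(
        [
            solve_triangular(chol, patterns.estimates[a].T, lower=True).T
            for a in range(r)
        ]
    )
    i, j = np.tril_indices(c, k=-1)
    deltas = white[:, i, :] - white[:, j, :]  # (runs, pairs, channels)
    total = deltas.sum(axis=0)
    same = np.einsum("rpv,rpv->p", deltas, deltas)
    cross = np.einsum("pv,pv->p", total, total) - same
    ltv = cross / (r * (r - 1)) / v
    conds = patterns.conditions or [("?", str(k)) for k in range(c)]
    return RDM.from_ltv(ltv, list(conds))


# ---------------------------------------------------------------------------
# regression and group tests


@dataclass
class RdmRegressionResult:
    """OLS of an empirical RDM's lower triangle on z-scored hypothesis
    predictors plus an intercept."""

    betas: pd.Series
    intercept: float
    rank_deficient: bool


def rdm_regression(
    empirical: RDM, hypotheses: dict[str, RDM | np.ndarray]
) -> RdmRegressionResult:
    """Relate hypothesis RDMs to an empirical RDM by multiple regression.

    All predictors' lower triangles are z-scored and compete for variance
    simultaneously; the empirical vector is left on its native scale. A
    rank-deficient design matrix is flagged and solved by pseudo-inverse.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis RDM")
    y = empirical.ltv
    names = list(hypotheses)
    cols = []
    for name in names:
        h = hypotheses[name]
        v = h.ltv if isinstance(h, RDM) else np.asarray(h, dtype=float)
        if len(v) != len(y):
            raise ValueError(f"predictor {name!r} has wrong length")
        z, degenerate = _zscore_ltv(v)
        if degenerate:
            warnings.warn(f"constant hypothesis RDM {name!r}")
        cols.append(z)
    X = np.column_stack([np.ones(len(y))] + cols)
    rank = np.linalg.matrix_rank(X)
    rank_deficient = rank < X.shape[1]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return RdmRegressionResult(
        betas=pd.Series(coef[1:], index=names),
        intercept=float(coef[0]),
        rank_deficient=rank_deficient,
    )


def group_test(
    per_subject_betas: pd.DataFrame,
    n_permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-sample t-test of each predictor's betas against zero across
    subjects, optionally with a sign-flip permutation p-value.

    Returns a DataFrame indexed by predictor with mean beta, t, p (and
    ``p_signflip`` when permutations are requested). Predictors with zero
    variance across subjects get NaN statistics and a warning.
    """
    df = pd.DataFrame(per_subject_betas)
    if len(df) < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    rows = {}
    for name in df.columns:
        b = df[name].to_numpy(dtype=float)
        if b.std(ddof=1) < 1e-15:
            warnings.warn(f"zero variance in betas for {name!r}; t undefined")
            rows[name] = {"mean": float(b.mean()), "t": np.nan, "p": np.nan}
            continue
        t, p = stats.ttest_1samp(b, 0.0)
        row = {"mean": float(b.mean()), "t": float(t), "p": float(p)}
        if n_permutations > 0:
            signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(b)))
            null = np.abs((signs * b).mean(axis=1))
            row["p_signflip"] = float(
                (np.sum(null >= abs(b.mean())) + 1) / (n_permutations + 1)
            )
        rows[name] = row
    return pd.DataFrame(rows).T
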