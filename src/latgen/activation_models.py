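"""Spreading-activation memory-network models of generalization RTs.

Four model variants map a generalization trial sequence to predicted
reaction times. Each represents the task's memory content as a set of nodes
whose activation starts at 0 and grows toward an asymptote of 1 by a
Rescorla-Wagner update ``a <- a + r*(1 - a)`` each trial. The per-trial rate
``r`` of each node depends on the node's relation to the probed condition
and is a monomial in three rate parameters:

* ``alpha1`` - direct retrieval of the probed items,
* ``alpha2`` - mediated retrieval through associated nodes,
* ``alpha3`` - incidental retrieval of currently irrelevant nodes,

with multi-step retrieval paths multiplying the per-step rates (power-law
falloff with path length). The variants differ in network structure:

* ``CAR`` (conjunctive associative retrieval): one node per context x
  category-value conjunction; no latent-state representation.
* ``IAR`` (independent associative retrieval): separate context nodes and
  category-value nodes, linked by experience.
* ``LS`` (latent state): latent-state nodes with nested category-value
  nodes; no context representation at all.
* ``HLS`` (hierarchical latent state): latent-state nodes with contexts,
  and context x category nodes, nested underneath them.

Predicted raw RT on a trial is the asymptotic ceiling for the probed nodes
minus their summed activation *before* the trial's update (retrieval
difficulty reflects the memory state at probe time); predictions are then
z-scored across the modeled trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import run_sequence
from .task_design import (
    NEW_CATEGORIES,
    OLD_CATEGORIES,
    LATENT_STATES,
    GENERALIZATION_PHASES,
    TaskDesign,
    TrialSequence,
)

__all__ = [
    "MODEL_KINDS",
    "ActivationParams",
    "NetworkSpec",
    "MemoryNetwork",
    "build_network",
    "rw_update",
    "classify_and_rate",
    "step_trial",
    "predict_sequence",
    "condition_list",
    "condition_indices",
]

MODEL_KINDS = ("CAR", "IAR", "LS", "HLS")

# z-scores with raw-prediction SD below this are treated as degenerate
DEGENERATE_SD = 1e-10


@dataclass(frozen=True)
class ActivationParams:
    """Retrieval rate parameters, each bounded in [0, 1]."""

    alpha1: float
    alpha2: float
    alpha3: float

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "alpha3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3])


def rw_update(activation: float, rate: float) -> float:
    """One Rescorla-Wagner step toward the asymptote of 1."""
    if not 0.0 <= activation <= 1.0 or not 0.0 <= rate <= 1.0:
        raise ValueError("activation and rate must lie in [0, 1]")
    return activation + rate * (1.0 - activation)


def condition_list(design: TaskDesign) -> list[tuple[str, str]]:
    """Canonical ordering of the 18 generalization conditions: held-out
    contexts grouped by latent state (introduction order within state),
    crossed with the new categories in fixed order."""
    return [(c, k) for c in design.heldout_contexts for k in NEW_CATEGORIES]


def condition_indices(
    design: TaskDesign, sequence: TrialSequence | pd.DataFrame
) -> np.ndarray:
    """Map a generalization trial table to canonical condition indices."""
    df = sequence.trials if isinstance(sequence, TrialSequence) else sequence
    bad = ~df["phase"].isin(GENERALIZATION_PHASES)
    if bad.any():
        raise ValueError("sequence contains non-generalization trials")
    lookup = {cond: i for i, cond in enumerate(condition_list(design))}
    try:
        return np.array(
            [lookup[(c, k)] for c, k in zip(df["context"], df["category"])],
            dtype=np.int64,
        )
    except KeyError as err:  # pragma: no cover - defensive
        raise ValueError(f"condition {err} not representable in network") from err


# ---------------------------------------------------------------------------
# network construction: per-condition rate-exponent tables

_A1, _A2, _A3 = (1, 0, 0), (0, 1, 0), (0, 0, 1)


def _car_nodes(design: TaskDesign) -> list[tuple[str, str]]:
    nodes = [(c, k) for c in design.contexts for k in OLD_CATEGORIES]
    nodes += [(c, k) for c in design.trained_contexts for k in NEW_CATEGORIES]
    nodes += [(c, k) for c in design.heldout_contexts for k in NEW_CATEGORIES]
    return nodes


def _car_exponents(design, nodes, context, category):
    """Conjunctive associative retrieval rate classes for one probe."""
    ls = design.state_of(context)
    trained = design.contexts_by_state[ls][design.trained_set_index]
    sibling = design.sibling_heldout(context)
    heldout = set(design.heldout_contexts)
    trained_set = set(design.trained_contexts)
    exps = []
    for (cx, cat) in nodes:
        is_initial = cat in OLD_CATEGORIES
        is_new_training = cx in trained_set and cat in NEW_CATEGORIES
        is_generalization = cx in heldout and cat in NEW_CATEGORIES
        if is_generalization and cx == context and cat == category:
            e = (2, 2, 0)  # probed conjunction, via the linked trained context
        elif is_generalization and cx == sibling and cat == category:
            e = (2, 3, 0)  # sibling held-out context, one more mediated step
        elif is_initial and cx == context:
            e = _A1  # initial-training conjunctions of the probed context
        elif is_new_training and cat == category:
            e = _A1  # probed category retrieves its new-training conjunctions
        elif is_new_training and cx == trained:
            e = (0, 2, 0)  # other new categories of the linked trained context
        elif is_initial and design.value("initial", design.state_of(cx), cat) == (
            design.value("initial", ls, cat)
        ):
            e = _A2  # same category-value conjunctions in other contexts
        else:
            e = _A3
        exps.append(e)
    return exps


def _iar_nodes(design: TaskDesign) -> list[tuple]:
    nodes: list[tuple] = [("ctx", c) for c in design.contexts]
    seen = set()
    for ls in LATENT_STATES:
        for cat in OLD_CATEGORIES:
            seen.add((cat, design.value("initial", ls, cat)))
        for cat in NEW_CATEGORIES:
            seen.add((cat, design.value("new_training", ls, cat)))
    nodes += [("catval", cat, sign) for cat, sign in sorted(seen)]
    return nodes


def _iar_exponents(design, nodes, context, category):
    """Independent associative retrieval rate classes for one probe."""
    ls = design.state_of(context)
    trained = design.contexts_by_state[ls][design.trained_set_index]
    sibling = design.sibling_heldout(context)
    own_old = {
        (cat, design.value("initial", ls, cat)) for cat in OLD_CATEGORIES
    }
    own_new = {
        (cat, design.value("new_training", ls, cat)) for cat in NEW_CATEGORIES
    }
    probe = (category, design.value("new_training", ls, category))
    exps = []
    for node in nodes:
        if node[0] == "ctx":
            cx = node[1]
            if cx == context:
                e = _A1
            elif cx == trained:
                e = (3, 0, 0)  # shares the initial category-value associations
            elif cx == sibling:
                e = (2, 1, 0)  # mediated via the shared category-values
            else:
                e = _A3
        else:
            cv = (node[1], node[2])
            if cv == probe:
                e = (4, 0, 0)  # retrieved through the trained context
            elif cv in own_new:
                e = (3, 1, 0)  # other new category-values of that context
            elif cv in own_old:
                e = (2, 0, 0)  # initial associations of the probed context
            else:
                e = _A3
        exps.append(e)
    return exps


def _ls_nodes(design: TaskDesign) -> list[tuple]:
    nodes: list[tuple] = [("ls", ls) for ls in LATENT_STATES]
    nodes += [
        ("lscat", ls, cat)
        for ls in LATENT_STATES
        for cat in OLD_CATEGORIES + NEW_CATEGORIES
    ]
    return nodes


def _ls_exponents(design, nodes, context, category):
    """Latent-state model rate classes (no context representation)."""
    ls = design.state_of(context)
    exps = []
    for node in nodes:
        if node[0] == "ls":
            e = _A1 if node[1] == ls else _A3
        else:
            _, node_ls, cat = node
            if node_ls == ls:
                e = (2, 0, 0) if cat == category else _A2
            else:
                e = (0, 0, 2)
        exps.append(e)
    return exps


def _hls_nodes(design: TaskDesign) -> list[tuple]:
    nodes: list[tuple] = [("ls", ls) for ls in LATENT_STATES]
    nodes += [("ctx", c) for c in design.contexts]
    nodes += [
        ("ctxcat", c, cat)
        for c in design.contexts
        for cat in OLD_CATEGORIES + NEW_CATEGORIES
    ]
    return nodes


def _hls_exponents(design, nodes, context, category):
    """Hierarchical latent-state rate classes: contexts and context-category
    nodes inherit activation from their latent state."""
    ls = design.state_of(context)
    exps = []
    for node in nodes:
        if node[0] == "ls":
            e = _A1 if node[1] == ls else _A3
        elif node[0] == "ctx":
            cx = node[1]
            if cx == context:
                e = (2, 0, 0)
            elif design.state_of(cx) == ls:
                e = (1, 1, 0)  # siblings inherit mediated LS activation
            else:
                e = (0, 0, 2)
        else:
            _, cx, cat = node
            if cx == context and cat == category:
                e = (3, 0, 0)
            elif design.state_of(cx) == ls:
                # categories nested in the current LS's contexts, including
                # the non-probed categories of the current context
                e = (1, 2, 0)
            else:
                e = (0, 0, 3)
        exps.append(e)
    return exps


_BUILDERS = {
    "CAR": (_car_nodes, _car_exponents),
    "IAR": (_iar_nodes, _iar_exponents),
    "LS": (_ls_nodes, _ls_exponents),
    "HLS": (_hls_nodes, _hls_exponents),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Precompiled network: node inventory, per-condition rate classes (as
    exponent triples over the alphas), and the RT read-out nodes."""

    model_kind: str
    design: TaskDesign
    nodes: tuple
    class_exponents: np.ndarray  # (n_classes, 3) int
    class_idx: np.ndarray  # (18, n_nodes) int
    readout_idx: np.ndarray  # (18, m) int
    readout_const: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def class_rates(self, params: ActivationParams | np.ndarray) -> np.ndarray:
        alpha = (
            params.as_array()
            if isinstance(params, ActivationParams)
            else np.asarray(params, dtype=float)
        )
        return np.prod(alpha[None, :] ** self.class_exponents, axis=1)

    def node_rates(
        self, condition: int, params: ActivationParams | np.ndarray
    ) -> np.ndarray:
        return self.class_rates(params)[self.class_idx[condition]]


def build_network_spec(model_kind: str, design: TaskDesign) -> NetworkSpec:
    if model_kind not in _BUILDERS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    node_fn, exp_fn = _BUILDERS[model_kind]
    nodes = node_fn(design)
    node_pos = {n: i for i, n in enumerate(nodes)}
    conds = condition_list(design)
    exp_to_class: dict[tuple, int] = {}
    class_idx = np.zeros((len(conds), len(nodes)), dtype=np.int64)
    readout = np.zeros((len(conds), 1 if model_kind == "CAR" else 2), dtype=np.int64)
    for ci, (context, category) in enumerate(conds):
        for ni, e in enumerate(exp_fn(design, nodes, context, category)):
            class_idx[ci, ni] = exp_to_class.setdefault(e, len(exp_to_class))
        ls = design.state_of(context)
        if model_kind == "CAR":
            readout[ci, 0] = node_pos[(context, category)]
        elif model_kind == "IAR":
            sign = design.value("new_training", ls, category)
            readout[ci] = (
                node_pos[("ctx", context)],
                node_pos[("catval", category, sign)],
            )
        elif model_kind == "LS":
            readout[ci] = (node_pos[("ls", ls)], node_pos[("lscat", ls, category)])
        else:
            readout[ci] = (
                node_pos[("ctx", context)],
                node_pos[("ctxcat", context, category)],
            )
    exponents = np.array(
        [e for e, _ in sorted(exp_to_class.items(), key=lambda kv: kv[1])],
        dtype=np.int64,
    )
    return NetworkSpec(
        model_kind=model_kind,
        design=design,
        nodes=tuple(nodes),
        class_exponents=exponents,
        class_idx=class_idx,
        readout_idx=readout,
        readout_const=1.0 if model_kind == "CAR" else 2.0,
    )


class MemoryNetwork:
    """Stateful view of a model network: tracks activation across trials.

    The node inventory is fixed at construction; activations start at 0 and
    only grow (all rates are non-negative). ``step_trial`` returns the raw
    predicted RT from the pre-update state, then updates every node.
    """

    def __init__(self, model_kind: str, design: TaskDesign):
        self.spec = build_network_spec(model_kind, design)
        self.activation = np.zeros(self.spec.n_nodes)

    @property
    def model_kind(self) -> str:
        return self.spec.model_kind

    @property
    def nodes(self) -> tuple:
        return self.spec.nodes

    def activation_of(self, node) -> float:
        return float(self.activation[self.spec.nodes.index(node)])

    def _condition_index(self, trial: pd.Series | tuple[str, str]) -> int:
        if isinstance(trial, tuple):
            context, category = trial
        else:
            context, category = trial["context"], trial["category"]
        conds = condition_list(self.spec.design)
        try:
            return conds.index((context, category))
        except ValueError as err:
            raise ValueError(
                f"condition ({context!r}, {category!r}) not representable"
            ) from err

    def rates_for(
        self, trial, params: ActivationParams
    ) -> dict[tuple, float]:
        """Per-node retrieval rates for one trial (``classify_and_rate``)."""
        ci = self._condition_index(trial)
        r = self.spec.node_rates(ci, params)
        return dict(zip(self.spec.nodes, r))

    def step_trial(self, trial, params: ActivationParams) -> float:
        """Raw predicted RT (pre-update read-out), then update all nodes."""
        ci = self._condition_index(trial)
        rt = self.spec.readout_const - float(
            self.activation[self.spec.readout_idx[ci]].sum()
        )
        rates = self.spec.node_rates(ci, params)
        self.activation += rates * (1.0 - self.activation)
        return rt


def build_network(model_kind: str, design: TaskDesign) -> MemoryNetwork:
    return MemoryNetwork(model_kind, design)


def classify_and_rate(
    network: MemoryNetwork, trial, params: ActivationParams
) -> dict[tuple, float]:
    """Rate assigned to every node for one trial's update."""
    return network.rates_for(trial, params)


def step_trial(network: MemoryNetwork, trial, params: ActivationParams) -> float:
    return network.step_trial(trial, params)


# ---------------------------------------------------------------------------
# vectorized sequence prediction


def predict_raw(
    spec: NetworkSpec, cond_seq: np.ndarray, params: ActivationParams | np.ndarray
) -> np.ndarray:
    """Raw predicted RTs for a condition-index sequence on a fresh network."""
    out = np.empty(len(cond_seq), dtype=np.float64)
    run_sequence(
        np.ascontiguousarray(cond_seq, dtype=np.int64),
        spec.class_idx,
        spec.class_rates(params),
        spec.readout_idx,
        spec.readout_const,
        out,
    )
    return out


def zscore_predictions(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score raw predictions; a near-constant vector is degenerate and
    returned as zeros with the flag set."""
    sd = float(np.std(raw))
    if sd < DEGENERATE_SD:
        return np.zeros_like(raw), True
    return (raw - raw.mean()) / sd, False


def predict_sequence(
    model_kind: str,
    params: ActivationParams,
    sequence: TrialSequence | pd.DataFrame,
    design: TaskDesign | None = None,
) -> tuple[np.ndarray, bool]:
    """Standardized predicted RTs for the (correct) generalization trials of
    ``sequence``, plus a degeneracy flag.

    The network is built fresh at generalization onset (training phases are
    not simulated) and steps through the supplied trials in order.
    """
    if isinstance(sequence, TrialSequence):
        design = sequence.design
        df = sequence.trials
    else:
        if design is None:
            raise ValueError("design required when passing a bare DataFrame")
        df = sequence
    if len(df) < 2:
        raise ValueError("need at least two trials to standardize predictions")
    spec = build_network_spec(model_kind, design)
    cond_seq = condition_indices(design, df)
    return zscore_predictions(predict_raw(spec, cond_seq, params))
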