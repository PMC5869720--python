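"""Synthetic networks, condition panels and ground-truth DAC panels.

Topology-only prediction can only be benchmarked against outcomes produced
by a model whose kinetics the predictor does not see.  The hidden model here
is a linear log-space responder with the *same topology* but *different
(hidden) link-weight magnitudes*: each normalized weight is multiplied by a
lognormal factor, emulating the order-of-magnitude kinetic uncertainty that
separates a curated topology from the true dynamics.  Observed fold changes
optionally carry additive Gaussian noise before sign-taking.  This preserves
the premise of the evaluation — dynamics depend on unknown kinetics, only
topology is shared — while staying desk-scale; an optional tanh squashing of
the hidden update stresses the predictor beyond the linear family.

Generator defaults mirror the shape of the densest published evaluation
dataset (22 nodes, 47 links, 2 inputs, 13 perturbation targets, 13
readouts, 66 perturbation conditions).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NetworkError
from .flow import compute_fold, dac_sign
from .network import (
    SignedNetwork,
    WeightMatrix,
    build_adjacency,
    normalize_weights,
)
from .panels import (
    Condition,
    ConditionPanel,
    DACPanel,
    DatasetBundle,
    basal_from_condition,
)
from .propagation import (
    ActivityState,
    BasalActivity,
    PropagationConfig,
    solve_steady_state,
    spectral_margin,
)

__all__ = [
    "GeneratorSpec",
    "HiddenModel",
    "make_cascade",
    "make_random_network",
    "make_toy_network",
    "derive_hidden_model",
    "generate_ground_truth",
    "make_benchmark_dataset",
]

#: spectral margin enforced for hidden models, so their steady state exists
_MIN_MARGIN = 0.05


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape of a synthetic benchmark dataset.

    Defaults mirror a 22-node / 47-link signaling model with 2 inputs,
    13 perturbation targets, 13 readouts and 66 perturbation conditions
    (all singles plus sampled duals).  ``density`` may replace ``n_links``.
    """

    n_nodes: int = 22
    n_links: int | None = 47
    density: float | None = None
    fraction_negative: float = 0.25
    n_inputs: int = 2
    n_perturbation_targets: int = 13
    n_readouts: int = 13
    n_conditions: int = 66
    n_sub_datasets: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if (self.n_links is None) == (self.density is None):
            raise ValueError("specify exactly one of n_links or density")
        max_links = self.n_nodes * (self.n_nodes - 1)  # simple, no self-loops
        if self.density is not None:
            if not 0 < self.density <= 1:
                raise ValueError("density must be in (0, 1]")
            object.__setattr__(
                self, "n_links", max(1, round(self.density * max_links))
            )
        if not 0 < self.n_links <= max_links:
            raise ValueError(
                f"n_links must be in [1, {max_links}] for a simple digraph "
                f"on {self.n_nodes} nodes without self-loops"
            )
        if not 0 <= self.fraction_negative <= 1:
            raise ValueError("fraction_negative must be in [0, 1]")
        if self.n_inputs + self.n_perturbation_targets > self.n_nodes:
            raise ValueError("inputs and perturbation targets exceed node count")
        if self.n_readouts > self.n_nodes - self.n_inputs:
            raise ValueError("too many readouts for the non-input node set")
        p = self.n_perturbation_targets
        if self.n_conditions > p + p * (p - 1) // 2:
            raise ValueError(
                "n_conditions exceeds the number of single plus dual "
                "perturbations"
            )


@dataclass(frozen=True)
class HiddenModel:
    """Ground-truth responder: hidden weights, damping, noise scale.

    ``weights`` shares the network's sign structure but carries the hidden
    magnitudes; ``noise_scale`` is the standard deviation of additive
    Gaussian noise on observed log fold changes; ``dac_threshold`` is the
    detection threshold for calling a direction — noisy folds below it are
    recorded as 0 ("no change"), the way panel DAC calls threshold small
    fold changes (default: twice the noise scale); ``squash`` enables a
    tanh nonlinearity on the hidden update.
    """

    weights: WeightMatrix
    alpha: float = 0.5
    noise_scale: float = 0.0
    dac_threshold: float | None = None
    squash: bool = False

    def __post_init__(self) -> None:
        if not self.squash and spectral_margin(self.weights, self.alpha) <= 0:
            raise ValueError(
                "hidden model would diverge: spectral_margin(W, alpha) <= 0; "
                "respecify the weights"
            )


def _node_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= 26:
        return list(letters[:n])
    return [f"n{i:03d}" for i in range(n)]


def make_cascade(
    length: int, signs: Sequence[int] | None = None
) -> SignedNetwork:
    """A linear cascade n1 -> n2 -> ... -> n_length with the given link signs
    (default all activating)."""
    if length < 2:
        raise ValueError("cascade needs at least 2 nodes")
    if signs is None:
        signs = [1] * (length - 1)
    if len(signs) != length - 1:
        raise ValueError(
            f"need {length - 1} signs for a cascade of length {length}, "
            f"got {len(signs)}"
        )
    nodes = _node_names(length)
    links = [
        (nodes[i], nodes[i + 1], int(signs[i])) for i in range(length - 1)
    ]
    return SignedNetwork(nodes, links, name=f"cascade{length}")


def make_random_network(
    n_nodes: int,
    n_links: int | None = None,
    density: float | None = None,
    fraction_negative: float = 0.25,
    seed: int | None | np.random.Generator = None,
    name: str | None = None,
) -> SignedNetwork:
    """A seeded simple signed digraph without self-loops and with an exact
    link count (or density of the n*(n-1) possible ordered pairs)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_links = n_nodes * (n_nodes - 1)
    if (n_links is None) == (density is None):
        raise ValueError("specify exactly one of n_links or density")
    if density is not None:
        if not 0 < density <= 1:
            raise ValueError("density must be in (0, 1]")
        n_links = max(1, round(density * max_links))
    if not 0 < n_links <= max_links:
        raise NetworkError(
            f"cannot place {n_links} links on {n_nodes} nodes "
            f"(max {max_links} without self-loops)"
        )
    nodes = _node_names(n_nodes)
    all_pairs = [
        (i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j
    ]
    chosen = rng.choice(len(all_pairs), size=n_links, replace=False)
    signs = np.where(rng.random(n_links) < fraction_negative, -1, 1)
    links = [
        (nodes[all_pairs[k][0]], nodes[all_pairs[k][1]], int(g))
        for k, g in zip(chosen, signs)
    ]
    return SignedNetwork(nodes, links, name=name or f"random{n_nodes}")


def make_toy_network() -> tuple[SignedNetwork, list[Condition], float]:
    """The six-node worked-example network with its two documented
    conditions and alpha = 0.5.

    Conditions: (1) node A stimulated (b_A = +1); (2) node A stimulated and
    node E inhibited (b_A = +1, b_E = -1).  Comparing them, the flow on the
    E -> B link reverses sign because E is up-regulated in (1) but
    down-regulated in (2), and F is down-regulated downstream of E -> D.

    Edge provenance: E -> B and E -> D are attested by the published
    worked example (the F_BE sign reversal and E's regulation of D); the
    D -> F leg realizes the documented downstream effect on F.  The
    remaining edges (A -> B, A -> E, B -> C) are a synthetic completion
    chosen to make A reach every node; quantitative claims in tests avoid
    them.
    """
    net = SignedNetwork(
        nodes=["A", "B", "C", "D", "E", "F"],
        links=[
            ("A", "B", 1),
            ("A", "E", 1),
            ("E", "B", 1),
            ("E", "D", 1),
            ("D", "F", 1),
            ("B", "C", 1),
        ],
        name="toy6",
    )
    conditions = [
        Condition(stimuli={"A"}, perturbed=set(), label="A_stimulated"),
        Condition(stimuli={"A"}, perturbed={"E"}, label="A_stim_E_inhibited"),
    ]
    return net, conditions, 0.5


def derive_hidden_model(
    net: SignedNetwork,
    alpha: float = 0.5,
    weight_spread: float = 1.0,
    noise_scale: float = 0.01,
    dac_threshold: float | None = None,
    squash: bool = False,
    seed: int | None | np.random.Generator = None,
) -> HiddenModel:
    """Hidden responder for ``net``: normalized-weight magnitudes jittered by
    lognormal factors ``exp(weight_spread * N(0,1))``, signs kept.

    If the jittered matrix would make ``alpha * rho(W) >= 1 - 0.05`` the
    whole matrix is rescaled to a spectral margin of 0.05; a uniform
    rescaling preserves all flow directions, only the hidden magnitudes'
    overall scale changes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_norm = normalize_weights(build_adjacency(net))
    mask = w_norm.matrix != 0
    factors = np.ones_like(w_norm.matrix)
    factors[mask] = np.exp(weight_spread * rng.standard_normal(int(mask.sum())))
    hidden = w_norm.matrix * factors
    w = WeightMatrix(hidden, w_norm.node_order, normalized=False)
    margin = spectral_margin(w, alpha)
    if margin <= _MIN_MARGIN:
        rho = (1.0 - margin) / alpha
        scale = (1.0 - _MIN_MARGIN) / (alpha * rho)
        w = WeightMatrix(hidden * scale, w_norm.node_order, normalized=False)
    return HiddenModel(
        weights=w,
        alpha=alpha,
        noise_scale=noise_scale,
        dac_threshold=dac_threshold,
        squash=squash,
    )


def _hidden_steady_state(model: HiddenModel, b: BasalActivity) -> ActivityState:
    if not model.squash:
        return solve_steady_state(
            model.weights, b, PropagationConfig(alpha=model.alpha)
        )
    # saturating responder: fixed point of x = tanh(alpha W x + (1-alpha) b)
    x = b.values.copy()
    a, wm = model.alpha, model.weights.matrix
    for _ in range(500):
        x_new = np.tanh(a * (wm @ x) + (1 - a) * b.values)
        if np.linalg.norm(x_new - x) < 1e-10:
            x = x_new
            break
        x = x_new
    return ActivityState(x, model.weights.node_order)


def generate_ground_truth(
    net: SignedNetwork,
    model: HiddenModel,
    panel: ConditionPanel,
    readouts: Sequence[str],
    seed: int | None | np.random.Generator = None,
) -> DACPanel:
    """Simulate the hidden responder over a condition panel and return the
    resulting signed DAC panel over ``readouts``.

    For each condition the hidden steady state is compared against its
    control (same stimuli, no perturbation); Gaussian noise of scale
    ``model.noise_scale`` is added to the log fold change, then folds below
    the detection threshold ``model.dac_threshold`` are called 0 ("no
    change") and the rest signed.  With zero noise the threshold defaults
    to 0 and readouts unaffected by the perturbation come out exactly 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel.validate_against(net)
    order = model.weights.node_order
    idx = {n: i for i, n in enumerate(order)}
    missing = [r for r in readouts if r not in idx]
    if missing:
        raise ValueError(f"readouts not in network: {missing}")
    rows = {}
    control_cache: dict[frozenset, ActivityState] = {}
    for cond in panel.conditions:
        control = panel.control_for(cond)
        key = control.stimuli
        if key not in control_cache:
            control_cache[key] = _hidden_steady_state(
                model, basal_from_condition(control, order)
            )
        x_ctl = control_cache[key]
        x_cond = _hidden_steady_state(model, basal_from_condition(cond, order))
        fold = compute_fold(x_ctl, x_cond).values
        if model.noise_scale > 0:
            fold = fold + rng.normal(0.0, model.noise_scale, size=fold.shape)
        thresh = model.dac_threshold
        if thresh is None:
            thresh = 2.0 * model.noise_scale
        signs = np.where(np.abs(fold) > thresh, np.sign(fold), 0.0)
        rows[cond.label] = [signs[idx[r]] for r in readouts]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(readouts))
    df.index = df.index.astype(str)
    return DACPanel(df)


def _build_panel(
    spec: GeneratorSpec,
    inputs: Sequence[str],
    targets: Sequence[str],
    rng: np.random.Generator,
) -> ConditionPanel:
    """All single perturbations first, then duals sampled without
    replacement, every condition under full input stimulation."""
    singles = [(t,) for t in targets]
    duals = list(combinations(targets, 2))
    conds: list[Condition] = []
    chosen: list[tuple[str, ...]] = list(singles)
    n_extra = spec.n_conditions - len(singles)
    if n_extra < 0:
        chosen = chosen[: spec.n_conditions]
    elif n_extra > 0:
        pick = rng.choice(len(duals), size=n_extra, replace=False)
        chosen += [duals[k] for k in sorted(pick)]
    for combo in chosen:
        conds.append(
            Condition(
                stimuli=set(inputs),
                perturbed=set(combo),
                label="p_" + "+".join(combo),
            )
        )
    return ConditionPanel(tuple(conds))


def make_benchmark_dataset(
    spec: GeneratorSpec,
    alpha: float = 0.5,
    weight_spread: float = 1.0,
    noise_scale: float = 0.01,
    dac_threshold: float | None = None,
    squash: bool = False,
    network: SignedNetwork | None = None,
) -> list[DatasetBundle]:
    """Generate ``spec.n_sub_datasets`` bundles sharing one topology and
    condition panel, with hidden-model magnitudes and noise redrawn per
    sub-dataset.

    Node roles are drawn from the seed: inputs are disjoint from
    perturbation targets; readouts are drawn from non-input nodes and may
    coincide with perturbation targets (as in the published panels, where
    roles overlap).  Everything is a pure function of ``spec`` (+ optional
    fixed ``network``).
    """
    rng = np.random.default_rng(spec.seed)
    if network is None:
        network = make_random_network(
            spec.n_nodes,
            n_links=spec.n_links,
            fraction_negative=spec.fraction_negative,
            seed=rng,
        )
    nodes = list(network.nodes)
    perm = [nodes[i] for i in rng.permutation(len(nodes))]
    inputs = perm[: spec.n_inputs]
    non_inputs = perm[spec.n_inputs :]
    targets = non_inputs[: spec.n_perturbation_targets]
    ro_pick = rng.choice(len(non_inputs), size=spec.n_readouts, replace=False)
    readouts = [non_inputs[i] for i in sorted(ro_pick)]
    panel = _build_panel(spec, inputs, targets, rng)
    bundles = []
    for k in range(spec.n_sub_datasets):
        model = derive_hidden_model(
            network,
            alpha=alpha,
            weight_spread=weight_spread,
            noise_scale=noise_scale,
            dac_threshold=dac_threshold,
            squash=squash,
            seed=rng,
        )
        actual = generate_ground_truth(network, model, panel, readouts, seed=rng)
        bundles.append(
            DatasetBundle(
                network=network,
                panel=panel,
                actual=actual,
                sub_dataset_id=f"sub{k:03d}",
            )
        )
    return bundles
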