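"""Prediction workflow and evaluation statistics.

For each perturbation condition the predictor solves the propagation steady
state for the condition and for its control (same stimuli, no
perturbation), takes the sign of the log fold change at the readout nodes,
and compares it to the actual DAC panel.  Accuracy is the fraction of
readouts whose predicted direction matches the actual one; by default,
readouts whose actual outcome is exactly 0 (no change) are excluded from
the denominator, because the panels score direction (up vs down).

Accuracy matrices (readouts x conditions, averaged over sub-datasets) are
summarized by agglomerative clustering with Manhattan (city-block)
distances and average linkage; the cophenetic distances between readouts
can then be correlated with their shortest-path distances in the
undirected network skeleton to ask whether prediction structure mirrors
topology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .errors import DivergenceError, SingularSystemError
from .flow import DACVector, compute_fold, dac_sign
from .network import (
    SignedNetwork,
    WeightMatrix,
    build_adjacency,
    normalize_weights,
)
from .panels import Condition, ConditionPanel, DACPanel, DatasetBundle, basal_from_condition
from .propagation import ActivityState, PropagationConfig, solve
from .randomize import RandomizationSpec, WeightPolicy, randomize_topology, sample_weights
from .synth import GeneratorSpec, make_benchmark_dataset, make_random_network

__all__ = [
    "PredictionResult",
    "AccuracyReport",
    "ClusteringResult",
    "predict_condition",
    "predict_panel",
    "accuracy",
    "evaluate_dataset",
    "evaluate_bundles_with_weights",
    "cluster_accuracy",
    "topology_dendrogram_correlation",
    "run_benchmark",
    "BENCHMARK_ARMS",
]

logger = logging.getLogger(__name__)

ZeroPolicy = Literal["exclude", "strict"]


@dataclass(frozen=True)
class PredictionResult:
    """Per-condition predicted DAC over readouts plus full activity states."""

    dac: dict[str, DACVector]
    states: dict[str, ActivityState]
    converged: dict[str, bool]


@dataclass(frozen=True)
class AccuracyReport:
    """Per-(sub-dataset, condition) accuracies with summary statistics."""

    per_condition: pd.DataFrame  # columns: sub_dataset, condition, accuracy, n_evaluated
    matrix: pd.DataFrame  # rows = readouts, columns = conditions, mean match rate

    @property
    def median(self) -> float:
        return float(self.per_condition["accuracy"].median())

    @property
    def mean(self) -> float:
        return float(self.per_condition["accuracy"].mean())

    def summary(self) -> dict[str, float]:
        acc = self.per_condition["accuracy"]
        return {
            "n": int(acc.size),
            "mean": float(acc.mean()),
            "median": float(acc.median()),
            "q1": float(acc.quantile(0.25)),
            "q3": float(acc.quantile(0.75)),
            "min": float(acc.min()),
            "max": float(acc.max()),
        }


@dataclass(frozen=True)
class ClusteringResult:
    """Leaf orders and cophenetic distances from clustering an accuracy matrix."""

    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_cophenetic: pd.DataFrame | None  # square, labelled by rows


def _weights_for(net: SignedNetwork) -> WeightMatrix:
    return normalize_weights(build_adjacency(net))


def predict_condition(
    bundle: DatasetBundle,
    cond: Condition,
    cfg: PropagationConfig | None = None,
    weights: WeightMatrix | None = None,
    zero_tol: float = 0.0,
) -> tuple[DACVector, ActivityState]:
    """Predict the DAC of the bundle's readouts for one condition.

    Solves the steady state for the condition and for its control and signs
    the fold change, restricted to the readouts.  ``weights`` overrides the
    bundle's degree-normalized weights (used for weight-policy arms).
    """
    cfg = cfg or PropagationConfig()
    w = weights if weights is not None else _weights_for(bundle.network)
    order = w.node_order
    control = bundle.panel.control_for(cond)
    x_ctl = solve(w, basal_from_condition(control, order), cfg)
    x_cond = solve(w, basal_from_condition(cond, order), cfg)
    fold = compute_fold(x_ctl, x_cond, c1=control.label, c2=cond.label)
    dac = dac_sign(fold, zero_tol=zero_tol).restrict(bundle.readouts)
    return dac, x_cond


def predict_panel(
    w: WeightMatrix,
    panel: ConditionPanel,
    readouts: Sequence[str],
    cfg: PropagationConfig | None = None,
    zero_tol: float = 0.0,
) -> PredictionResult:
    """Predict DACs for every condition of a panel under weight matrix ``w``.

    Control steady states are cached per distinct stimulus set.  Conditions
    whose solve fails to converge (iterative mode) or is numerically
    singular are flagged ``converged=False`` and carry no DAC.
    """
    cfg = cfg or PropagationConfig()
    order = w.node_order
    dacs: dict[str, DACVector] = {}
    states: dict[str, ActivityState] = {}
    converged: dict[str, bool] = {}
    ctl_cache: dict[frozenset, ActivityState] = {}
    for cond in panel.conditions:
        control = panel.control_for(cond)
        try:
            if control.stimuli not in ctl_cache:
                ctl_cache[control.stimuli] = solve(
                    w, basal_from_condition(control, order), cfg
                )
            x_ctl = ctl_cache[control.stimuli]
            x_cond = solve(w, basal_from_condition(cond, order), cfg)
        except (DivergenceError, SingularSystemError) as exc:
            logger.warning("condition %s skipped: %s", cond.label, exc)
            converged[cond.label] = False
            continue
        if not (x_ctl.converged and x_cond.converged):
            logger.warning(
                "condition %s did not converge within the iteration budget",
                cond.label,
            )
            converged[cond.label] = False
            continue
        fold = compute_fold(x_ctl, x_cond, c1=control.label, c2=cond.label)
        dacs[cond.label] = dac_sign(fold, zero_tol=zero_tol).restrict(readouts)
        states[cond.label] = x_cond
        converged[cond.label] = True
    return PredictionResult(dac=dacs, states=states, converged=converged)


def accuracy(
    pred: np.ndarray | DACVector,
    actual: np.ndarray,
    zero_policy: ZeroPolicy = "exclude",
) -> tuple[float, int]:
    """Fraction of readouts where the predicted direction matches the actual.

    Actual values are signed first (real-valued panels are log2 fold
    changes).  Under ``zero_policy="exclude"`` readouts whose actual value
    is exactly 0 are dropped from the denominator; ``"strict"`` keeps them
    and requires the prediction to be 0 too.  Returns ``(accuracy,
    n_evaluated)``; with nothing to evaluate, accuracy is NaN.
    """
    p = pred.values if isinstance(pred, DACVector) else np.asarray(pred)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs actual {a.shape}")
    if p.size == 0:
        raise ValueError("empty readout set")
    a_sign = np.sign(a)
    if zero_policy == "exclude":
        mask = a_sign != 0
    elif zero_policy == "strict":
        mask = np.ones_like(a_sign, dtype=bool)
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    n_eval = int(mask.sum())
    if n_eval == 0:
        return float("nan"), 0
    matches = np.sign(p[mask]) == a_sign[mask]
    return float(matches.mean()), n_eval


def evaluate_dataset(
    bundles: Sequence[DatasetBundle],
    cfg: PropagationConfig | None = None,
    zero_policy: ZeroPolicy = "exclude",
) -> AccuracyReport:
    """Run the prediction workflow over a set of sub-dataset bundles.

    All bundles must share network, panel and readouts; the predictions are
    computed once and scored against each bundle's actual panel.  The
    accuracy matrix entry (readout, condition) is the fraction of
    sub-datasets in which that readout's direction was called correctly
    (actual zeros excluded under the default policy).
    """
    if not bundles:
        raise ValueError("no bundles to evaluate")
    first = bundles[0]
    for b in bundles[1:]:
        if b.network.links != first.network.links or b.readouts != first.readouts:
            raise ValueError("bundles must share network and readouts")
    return evaluate_bundles_with_weights(bundles, _weights_for(first.network), cfg, zero_policy)


def evaluate_bundles_with_weights(
    bundles: Sequence[DatasetBundle],
    w: WeightMatrix,
    cfg: PropagationConfig | None = None,
    zero_policy: ZeroPolicy = "exclude",
) -> AccuracyReport:
    """As :func:`evaluate_dataset` but with an explicit weight matrix
    (randomized topologies and weight-policy arms)."""
    cfg = cfg or PropagationConfig()
    first = bundles[0]
    readouts = list(first.readouts)
    pred = predict_panel(w, first.panel, readouts, cfg)
    rows = []
    match_sum = pd.DataFrame(0.0, index=readouts, columns=list(first.panel.labels))
    match_cnt = pd.DataFrame(0.0, index=readouts, columns=list(first.panel.labels))
    for b in bundles:
        sid = b.sub_dataset_id or "sub000"
        for cond in b.panel.conditions:
            label = cond.label
            if not pred.converged.get(label, False):
                continue
            p = pred.dac[label].values
            a = b.actual.row(label)
            acc, n_eval = accuracy(p, a, zero_policy)
            if n_eval > 0:
                rows.append(
                    {
                        "sub_dataset": sid,
                        "condition": label,
                        "accuracy": acc,
                        "n_evaluated": n_eval,
                    }
                )
            a_sign = np.sign(a)
            scored = (
                a_sign != 0
                if zero_policy == "exclude"
                else np.ones_like(a_sign, dtype=bool)
            )
            ok = (np.sign(p) == a_sign) & scored
            match_sum.loc[:, label] += ok.astype(float)
            match_cnt.loc[:, label] += scored.astype(float)
    per_condition = pd.DataFrame(
        rows, columns=["sub_dataset", "condition", "accuracy", "n_evaluated"]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = match_sum / match_cnt
    return AccuracyReport(per_condition=per_condition, matrix=matrix)


def cluster_accuracy(mat: pd.DataFrame) -> ClusteringResult:
    """Agglomerative clustering (Manhattan distance, average linkage) of an
    accuracy matrix over rows (readouts) and columns (conditions).

    Returns leaf orderings for both axes and the cophenetic distance matrix
    for the rows.  A single row or column yields a trivial ordering and no
    distances on that axis.
    """
    if mat.empty:
        raise ValueError("empty accuracy matrix")
    if mat.isna().any().any():
        raise ValueError("accuracy matrix has missing entries")

    def _axis(df: pd.DataFrame):
        labels = tuple(df.index)
        if len(labels) < 2:
            return labels, None, None
        d = pdist(df.to_numpy(), metric="cityblock")
        z = linkage(d, method="average")
        order = tuple(labels[i] for i in leaves_list(z))
        with warnings.catch_warnings():
            # the cophenetic correlation coefficient is undefined for two
            # leaves; only the distances are used here
            warnings.simplefilter("ignore", RuntimeWarning)
            coph = squareform(cophenet(z, d)[1])
        coph_df = pd.DataFrame(coph, index=list(labels), columns=list(labels))
        return order, z, coph_df

    row_order, row_z, row_coph = _axis(mat)
    col_order, col_z, _ = _axis(mat.T)
    return ClusteringResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_z,
        col_linkage=col_z,
        row_cophenetic=row_coph,
    )


def topology_dendrogram_correlation(
    net: SignedNetwork,
    cophenetic: pd.DataFrame,
    readouts: Sequence[str] | None = None,
) -> float:
    """Pearson correlation, over readout pairs, between cophenetic distance
    in the accuracy dendrogram and shortest-path distance in the undirected,
    unsigned network skeleton.

    Pairs at infinite topological distance (disconnected) are excluded;
    fewer than 3 usable pairs is an error.
    """
    readouts = list(readouts) if readouts is not None else list(cophenetic.index)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((s, t) for s, t, _ in net.links)
    coph_vals = []
    topo_vals = []
    for i in range(len(readouts)):
        for j in range(i + 1, len(readouts)):
            a, b = readouts[i], readouts[j]
            try:
                d = nx.shortest_path_length(g, a, b)
            except nx.NetworkXNoPath:
                continue
            coph_vals.append(float(cophenetic.loc[a, b]))
            topo_vals.append(float(d))
    if len(coph_vals) < 3:
        raise ValueError(
            f"only {len(coph_vals)} usable readout pairs; need at least 3"
        )
    if np.std(coph_vals) == 0 or np.std(topo_vals) == 0:
        raise ValueError("distances are constant; correlation undefined")
    r, _ = pearsonr(coph_vals, topo_vals)
    return float(r)


# ---------------------------------------------------------------------------
# Benchmark: true topology vs randomized topology vs weight policies
# ---------------------------------------------------------------------------

BENCHMARK_ARMS = ("true", "random", "D", "ND", "DA", "NDA")


def run_benchmark(
    spec: GeneratorSpec,
    n_replicates: int = 50,
    arms: Sequence[str] = ("true", "random"),
    alpha: float = 0.5,
    weight_spread: float = 1.0,
    noise_scale: float = 0.01,
    seed: int = 0,
    cfg: PropagationConfig | None = None,
) -> pd.DataFrame:
    """Replicated synthetic benchmark across evaluation arms.

    Each replicate draws a fresh network, panel and hidden-model ground
    truth, then scores: the true topology with normalized weights
    (``"true"``), a degree-preserving randomized topology (``"random"``),
    and/or sampled-weight arms ``"D"``, ``"ND"``, ``"DA"``, ``"NDA"`` on the
    true topology.  Returns a tidy frame with one row per (replicate, arm):
    columns replicate, arm, mean_accuracy, median_accuracy, n_conditions.
    """
    bad = [a for a in arms if a not in BENCHMARK_ARMS]
    if bad:
        raise ValueError(f"unknown arms {bad}; valid: {BENCHMARK_ARMS}")
    cfg = cfg or PropagationConfig(alpha=alpha)
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(master.integers(0, 2**31 - 1))
        rep_spec = GeneratorSpec(
            **{
                **{f: getattr(spec, f) for f in spec.__dataclass_fields__},
                "seed": rep_seed,
                "density": None,
            }
        )
        bundles = make_benchmark_dataset(
            rep_spec,
            alpha=alpha,
            weight_spread=weight_spread,
            noise_scale=noise_scale,
        )
        net = bundles[0].network
        arm_rng = np.random.default_rng(rep_seed + 1)
        for arm in arms:
            if arm == "true":
                w = _weights_for(net)
            elif arm == "random":
                rand_net = randomize_topology(
                    net,
                    RandomizationSpec(seed=int(arm_rng.integers(0, 2**31 - 1))),
                )
                w = _weights_for(rand_net)
            else:
                w = sample_weights(
                    net,
                    WeightPolicy(kind=arm),
                    seed=int(arm_rng.integers(0, 2**31 - 1)),
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = evaluate_bundles_with_weights(bundles, w, cfg)
            acc = report.per_condition["accuracy"]
            rows.append(
                {
                    "replicate": rep,
                    "arm": arm,
                    "mean_accuracy": float(acc.mean()) if len(acc) else float("nan"),
                    "median_accuracy": float(acc.median()) if len(acc) else float("nan"),
                    "n_conditions": int(len(acc)),
                }
            )
    return pd.DataFrame(rows)
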