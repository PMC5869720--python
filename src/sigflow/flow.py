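"""Per-link signal flows, condition fold changes and the direction of
activity change (DAC).

The flow on a link j -> i is ``F[i, j] = W[i, j] * x[j]``: the source's
log-activity scaled by the link weight.  Its sign carries the biology — a
down-regulated source acting through an inhibitory link produces a positive
flow, i.e. it up-regulates the target.

Comparing two conditions, ``x_fold = x(c2) - x(c1)`` is a log fold change;
its sign is the DAC (up / down / unchanged) of each node.  When the two
conditions use different weight matrices the net flow subtracts per-link
flows condition-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import WeightMatrix
from .propagation import ActivityState

__all__ = [
    "FlowMatrix",
    "FoldChange",
    "DACVector",
    "compute_flow",
    "compute_fold",
    "compute_net_flow",
    "dac_sign",
    "write_flow_tsv",
    "write_node_values_tsv",
]


@dataclass(frozen=True)
class FlowMatrix:
    """Per-link signal flows, rows = targets, columns = sources."""

    matrix: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "node_order", tuple(self.node_order))

    def flow(self, source: str, target: str) -> float:
        idx = {n: i for i, n in enumerate(self.node_order)}
        return float(self.matrix[idx[target], idx[source]])


@dataclass(frozen=True)
class FoldChange:
    """Log fold change ``x(c2) - x(c1)`` per node."""

    values: np.ndarray
    node_order: tuple[str, ...]
    c1: str = "c1"
    c2: str = "c2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "node_order", tuple(self.node_order))


@dataclass(frozen=True)
class DACVector:
    """Ternary direction of activity change per node: +1 up, -1 down, 0 none."""

    values: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        if not np.all(np.isin(v, (-1, 0, 1))):
            raise ValueError("DAC entries must be -1, 0 or +1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_order", tuple(self.node_order))

    def restrict(self, nodes: Sequence[str]) -> "DACVector":
        idx = {n: i for i, n in enumerate(self.node_order)}
        missing = [n for n in nodes if n not in idx]
        if missing:
            raise ValueError(f"unknown node labels: {missing}")
        return DACVector(
            np.array([self.values[idx[n]] for n in nodes]), tuple(nodes)
        )


def _check_order(*orders: tuple[str, ...]) -> None:
    first = orders[0]
    if any(o != first for o in orders[1:]):
        raise ValueError("inputs have mismatched node orders")


def compute_flow(w: WeightMatrix, x: ActivityState) -> FlowMatrix:
    """``F[i, j] = W[i, j] * x[j]`` for every link, 0 elsewhere."""
    _check_order(w.node_order, x.node_order)
    return FlowMatrix(w.matrix * x.values[None, :], w.node_order)


def compute_fold(
    x_c1: ActivityState, x_c2: ActivityState, c1: str = "c1", c2: str = "c2"
) -> FoldChange:
    """Elementwise log fold change of condition 2 over condition 1."""
    _check_order(x_c1.node_order, x_c2.node_order)
    return FoldChange(x_c2.values - x_c1.values, x_c1.node_order, c1=c1, c2=c2)


def compute_net_flow(
    w_c1: WeightMatrix,
    x_c1: ActivityState,
    w_c2: WeightMatrix,
    x_c2: ActivityState,
) -> FlowMatrix:
    """Net flow ``W_c2[i,j] x_c2[j] - W_c1[i,j] x_c1[j]`` across conditions.

    Covers links present in either condition's weight matrix; a link absent
    in one condition contributes 0 on that side, so link-removal comparisons
    are well-defined.
    """
    _check_order(w_c1.node_order, x_c1.node_order, w_c2.node_order, x_c2.node_order)
    f = w_c2.matrix * x_c2.values[None, :] - w_c1.matrix * x_c1.values[None, :]
    return FlowMatrix(f, w_c1.node_order)


def dac_sign(fold: FoldChange, zero_tol: float = 0.0) -> DACVector:
    """Ternarize a fold change: +1 above ``zero_tol``, -1 below ``-zero_tol``,
    0 in between.  The default threshold is exactly 0."""
    if zero_tol < 0:
        raise ValueError(f"zero_tol must be >= 0, got {zero_tol}")
    v = np.zeros(fold.values.shape, dtype=int)
    v[fold.values > zero_tol] = 1
    v[fold.values < -zero_tol] = -1
    return DACVector(v, fold.node_order)


def write_flow_tsv(flow: FlowMatrix, path: str | Path) -> None:
    """Export nonzero flows as long-format TSV: source, target, value."""
    rows = []
    for i, tgt in enumerate(flow.node_order):
        for j, src in enumerate(flow.node_order):
            if flow.matrix[i, j] != 0:
                rows.append((src, tgt, flow.matrix[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_values_tsv(
    values: np.ndarray, node_order: Sequence[str], path: str | Path
) -> None:
    """Export a per-node vector (activity, fold or DAC) as node/value TSV."""
    pd.DataFrame({"node": list(node_order), "value": np.asarray(values)}).to_csv(
        path, sep="\t", index=False
    )
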