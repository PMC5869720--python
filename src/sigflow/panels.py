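"""Perturbation-condition panels, actual-outcome (DAC) panels and dataset bundles.

A condition is a set of stimulated input nodes (basal activity +1) and a set
of inhibited perturbation targets (basal activity -1).  A condition panel
collects the conditions under which predictions are scored; a DAC panel
holds the measured or simulated outcomes (ternary signs or real log2 fold
changes) per condition and readout node.  A dataset bundle ties network,
condition panel and actual outcomes together, optionally tagged with a
sub-dataset id when many outcome panels share one topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PanelError
from .network import SignedNetwork, read_network
from .propagation import BasalActivity

__all__ = [
    "Condition",
    "ConditionPanel",
    "DACPanel",
    "DatasetBundle",
    "basal_from_condition",
    "read_condition_panel",
    "write_condition_panel",
    "read_dac_panel",
    "write_dac_panel",
    "load_bundle",
]


@dataclass(frozen=True)
class Condition:
    """One experimental condition: sustained stimuli (+1) and inhibitory
    perturbations (-1), mirroring the convention that all perturbations in
    the evaluation panels are inhibitory."""

    stimuli: frozenset[str]
    perturbed: frozenset[str]
    label: str

    def __init__(
        self,
        stimuli: Iterable[str] = (),
        perturbed: Iterable[str] = (),
        label: str = "",
    ) -> None:
        stimuli = frozenset(stimuli)
        perturbed = frozenset(perturbed)
        overlap = stimuli & perturbed
        if overlap:
            raise PanelError(
                f"nodes cannot be both stimulated and perturbed: {sorted(overlap)}"
            )
        object.__setattr__(self, "stimuli", stimuli)
        object.__setattr__(self, "perturbed", perturbed)
        object.__setattr__(self, "label", label)


@dataclass(frozen=True)
class ConditionPanel:
    """Ordered conditions plus an optional explicit control.

    If ``control`` is None the control for each condition defaults to "same
    stimuli, no perturbations", so the fold change isolates the effect of
    the perturbation.
    """

    conditions: tuple[Condition, ...]
    control: Condition | None = None

    def __post_init__(self) -> None:
        conds = tuple(self.conditions)
        labels = [c.label for c in conds]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PanelError(f"duplicate condition labels: {dupes}")
        object.__setattr__(self, "conditions", conds)

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def control_for(self, cond: Condition) -> Condition:
        if self.control is not None:
            return self.control
        return Condition(stimuli=cond.stimuli, perturbed=(), label="control")

    def validate_against(self, net: SignedNetwork) -> None:
        nodes = set(net.nodes)
        for c in self.conditions:
            unknown = (c.stimuli | c.perturbed) - nodes
            if unknown:
                raise PanelError(
                    f"condition {c.label!r} references unknown nodes: "
                    f"{sorted(unknown)}"
                )


@dataclass(frozen=True)
class DACPanel:
    """Actual outcomes: rows = conditions, columns = readout nodes.

    Entries may be ternary signs {-1, 0, +1} or real log2 fold changes;
    real-valued panels are signed downstream before scoring.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        if df.index.has_duplicates:
            raise PanelError("duplicate condition labels in DAC panel")
        if df.columns.has_duplicates:
            raise PanelError("duplicate readout columns in DAC panel")
        object.__setattr__(self, "values", df)

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def row(self, label: str) -> np.ndarray:
        return self.values.loc[label].to_numpy()


@dataclass(frozen=True)
class DatasetBundle:
    """Network + condition panel + actual DAC outcomes for one sub-dataset."""

    network: SignedNetwork
    panel: ConditionPanel
    actual: DACPanel
    sub_dataset_id: str | None = None

    def __post_init__(self) -> None:
        self.panel.validate_against(self.network)
        nodes = set(self.network.nodes)
        unknown = set(self.actual.readouts) - nodes
        if unknown:
            raise PanelError(f"readouts not in network: {sorted(unknown)}")
        missing = set(self.actual.condition_labels) - set(self.panel.labels)
        if missing:
            raise PanelError(
                f"DAC panel rows without matching condition: {sorted(missing)}"
            )

    @property
    def readouts(self) -> tuple[str, ...]:
        return self.actual.readouts


def basal_from_condition(
    cond: Condition, node_order: Sequence[str]
) -> BasalActivity:
    """Build the basal-activity vector of a condition: +1 at stimulated
    inputs, -1 at inhibited targets, 0 elsewhere."""
    idx = {n: i for i, n in enumerate(node_order)}
    unknown = (cond.stimuli | cond.perturbed) - set(idx)
    if unknown:
        raise PanelError(
            f"condition {cond.label!r} references unknown nodes: {sorted(unknown)}"
        )
    b = np.zeros(len(node_order))
    for n in cond.stimuli:
        b[idx[n]] = 1.0
    for n in cond.perturbed:
        b[idx[n]] = -1.0
    return BasalActivity(b, tuple(node_order))


# ---------------------------------------------------------------------------
# Panel I/O — delimited tables via pandas
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_condition_panel(path: str | Path) -> ConditionPanel:
    """Read a condition panel: first column = condition label, one column per
    node, cell values 1 (stimulus), -1 (perturbation) or 0."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise PanelError(f"{path}: duplicate condition labels: {dupes}")
    conds = []
    for label, row in df.iterrows():
        stimuli = [c for c in df.columns if row[c] == 1]
        perturbed = [c for c in df.columns if row[c] == -1]
        bad = [c for c in df.columns if row[c] not in (0, 1, -1)]
        if bad:
            raise PanelError(
                f"{path}: condition {label!r} has non-ternary entries in "
                f"columns {bad}"
            )
        conds.append(Condition(stimuli, perturbed, label=str(label)))
    return ConditionPanel(tuple(conds))


def write_condition_panel(
    panel: ConditionPanel, path: str | Path, node_order: Sequence[str]
) -> None:
    path = Path(path)
    rows = {}
    for c in panel.conditions:
        rows[c.label] = [
            1 if n in c.stimuli else (-1 if n in c.perturbed else 0)
            for n in node_order
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(node_order))
    df.index.name = "condition"
    df.to_csv(path, sep=_sep_for(path))


def read_dac_panel(path: str | Path) -> DACPanel:
    """Read a DAC panel: first column = condition label, remaining columns =
    readouts; entries ternary or real log2 fold changes."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise PanelError(f"{path}: non-numeric DAC entries ({exc})") from None
    df.index = df.index.astype(str)
    return DACPanel(df)


def write_dac_panel(panel: DACPanel, path: str | Path) -> None:
    path = Path(path)
    out = panel.values.copy()
    out.index.name = "condition"
    out.to_csv(path, sep=_sep_for(path))


def load_bundle(manifest_path: str | Path) -> tuple[DatasetBundle, dict]:
    """Load a dataset bundle from a YAML/JSON manifest.

    The manifest names the network file, condition-panel file, DAC-panel
    file, optionally a readout list and solver settings (``alpha`` etc.).
    Relative paths resolve against the manifest's directory.  Returns the
    bundle and the raw manifest dict (for solver settings).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        if manifest_path.suffix.lower() == ".json":
            manifest = json.load(fh)
        else:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise PanelError(f"{manifest_path}: manifest must be a mapping")
    base = manifest_path.parent

    def resolve(key: str) -> Path:
        if key not in manifest:
            raise PanelError(f"{manifest_path}: missing required key {key!r}")
        return base / manifest[key]

    net = read_network(resolve("network"))
    panel = read_condition_panel(resolve("conditions"))
    dac = read_dac_panel(resolve("dac"))
    if "readouts" in manifest:
        dac = DACPanel(dac.values[list(manifest["readouts"])])
    bundle = DatasetBundle(
        network=net,
        panel=panel,
        actual=dac,
        sub_dataset_id=manifest.get("sub_dataset_id"),
    )
    return bundle, manifest
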