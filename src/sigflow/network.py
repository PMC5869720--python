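"""Signed-digraph data model, adjacency construction and link-weight normalization.

A signaling network is a simple signed digraph: each ordered pair of nodes
carries at most one link, signed ``+1`` (activation) or ``-1`` (inhibition).
The adjacency matrix convention used throughout the package is

    ``A[i, j] = sign of the link from node j (source, column) to node i
    (target, row)``,

so row sums of ``|A|`` are in-degrees and column sums are out-degrees.

Link weights are obtained by the symmetric degree normalization

    ``W = D_in^{-1/2} A D_out^{-1/2}``,

which scales each link by the inverse square roots of its target's in-degree
and its source's out-degree.  After normalization every weight satisfies
``|w| <= 1``, with equality exactly when both endpoint degrees are 1; this
keeps the propagation iteration contractive for any damping ``alpha < 1`` in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import NetworkError

__all__ = [
    "SignedNetwork",
    "AdjacencyMatrix",
    "WeightMatrix",
    "DegreeVectors",
    "build_adjacency",
    "normalize_weights",
    "classify_weight",
    "apply_weight_multipliers",
    "degree_vectors",
    "read_network",
    "write_network",
    "read_weight_multipliers",
]

#: SIF relation tokens accepted for each sign.
SIF_POSITIVE = frozenset({"activates", "+", "1", "+1"})
SIF_NEGATIVE = frozenset({"inhibits", "-", "-1"})

#: Canonical relation token written per sign.
_SIF_TOKEN = {1: "activates", -1: "inhibits"}


@dataclass(frozen=True)
class SignedNetwork:
    """A node-labelled signed digraph.

    Parameters
    ----------
    nodes
        Ordered unique node labels.
    links
        ``(source, target, sign)`` triples with ``sign`` exactly ``+1`` or
        ``-1``.  At most one link per ordered pair; self-loops are permitted
        by the data model (the propagation equations do not forbid them).
    name
        Optional network name.
    """

    nodes: tuple[str, ...]
    links: tuple[tuple[str, str, int], ...]
    name: str | None = None

    def __init__(
        self,
        nodes: Iterable[str],
        links: Iterable[tuple[str, str, int]],
        name: str | None = None,
    ) -> None:
        nodes = tuple(nodes)
        links = tuple((str(s), str(t), int(g)) for s, t, g in links)
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
            raise NetworkError(f"duplicate node labels: {dupes}")
        node_set = set(nodes)
        seen: set[tuple[str, str]] = set()
        for s, t, g in links:
            if s not in node_set or t not in node_set:
                raise NetworkError(f"link {s}->{t} references an unlisted node")
            if g not in (+1, -1):
                raise NetworkError(f"link {s}->{t} has sign {g}; must be +1 or -1")
            if (s, t) in seen:
                raise NetworkError(
                    f"duplicate link for ordered pair ({s}, {t}); "
                    "the model allows one weight per ordered pair"
                )
            seen.add((s, t))
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "links", links)
        object.__setattr__(self, "name", name)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def node_index(self) -> dict[str, int]:
        """Label -> position mapping under this network's node order."""
        return {n: i for i, n in enumerate(self.nodes)}

    def link_signs(self) -> dict[tuple[str, str], int]:
        """(source, target) -> sign mapping."""
        return {(s, t): g for s, t, g in self.links}

    def has_link(self, source: str, target: str) -> bool:
        return any(s == source and t == target for s, t, _ in self.links)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Signed adjacency with rows = targets, columns = sources."""

    matrix: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.node_order), len(self.node_order)):
            raise NetworkError(
                f"adjacency shape {m.shape} does not match "
                f"{len(self.node_order)} nodes"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "node_order", tuple(self.node_order))


@dataclass(frozen=True)
class WeightMatrix:
    """Real link-weight matrix, same orientation as :class:`AdjacencyMatrix`.

    ``normalized`` records whether the weights came out of the degree
    normalization pipeline; it guards against normalizing twice, which is not
    idempotent.
    """

    matrix: np.ndarray
    node_order: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.node_order), len(self.node_order)):
            raise NetworkError(
                f"weight matrix shape {m.shape} does not match "
                f"{len(self.node_order)} nodes"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "node_order", tuple(self.node_order))


@dataclass(frozen=True)
class DegreeVectors:
    """Per-node in- and out-degrees (counts of incident links)."""

    in_degree: np.ndarray
    out_degree: np.ndarray
    node_order: tuple[str, ...]


def build_adjacency(net: SignedNetwork) -> AdjacencyMatrix:
    """Materialize the signed adjacency matrix of ``net``.

    ``A[i, j]`` is the sign of the link from ``net.nodes[j]`` to
    ``net.nodes[i]``, 0 where no link exists.
    """
    n = net.n_nodes
    idx = net.node_index()
    a = np.zeros((n, n), dtype=float)
    for s, t, g in net.links:
        a[idx[t], idx[s]] = g
    return AdjacencyMatrix(a, net.nodes)


def degree_vectors(adj: AdjacencyMatrix) -> DegreeVectors:
    """In-degrees (row sums of ``|A|``) and out-degrees (column sums)."""
    absa = np.abs(adj.matrix)
    return DegreeVectors(
        in_degree=absa.sum(axis=1).astype(int),
        out_degree=absa.sum(axis=0).astype(int),
        node_order=adj.node_order,
    )


def normalize_weights(adj: AdjacencyMatrix | WeightMatrix) -> WeightMatrix:
    """Symmetric degree normalization ``W = D_in^{-1/2} A D_out^{-1/2}``.

    ``D_in`` and ``D_out`` are diagonal matrices of the row/column sums of
    ``|A|``.  Zero-degree diagonal entries would be singular under an inverse
    square root; their contribution is defined as 0, which is harmless because
    a nonzero ``A`` entry implies both incident degrees are at least 1.

    Accepts an unnormalized :class:`WeightMatrix` too (magnitudes then enter
    the degree sums as absolute values), but refuses an already-normalized
    one: re-normalizing is not idempotent.
    """
    if isinstance(adj, WeightMatrix):
        if adj.normalized:
            raise NetworkError(
                "weight matrix is already normalized; re-normalization is not "
                "idempotent — recompute from the adjacency matrix instead"
            )
        a = adj.matrix
    else:
        a = adj.matrix
    absa = np.abs(a)
    d_in = absa.sum(axis=1)
    d_out = absa.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv_sqrt_in = np.where(d_in > 0, 1.0 / np.sqrt(d_in), 0.0)
        inv_sqrt_out = np.where(d_out > 0, 1.0 / np.sqrt(d_out), 0.0)
    w = inv_sqrt_in[:, None] * a * inv_sqrt_out[None, :]
    return WeightMatrix(w, adj.node_order, normalized=True)


def classify_weight(w: float) -> str:
    """Classify a link weight as ``"decay"``, ``"amplification"`` or ``"unit"``.

    Decay weights (``|w| < 1``) shrink the signal flow relative to the source
    activity; amplification weights (``|w| > 1``) grow it.  ``|w| = 1`` is the
    boundary and gets its own ``"unit"`` kind.
    """
    if w == 0:
        raise ValueError("weight 0 does not correspond to a link")
    aw = abs(w)
    if aw < 1:
        return "decay"
    if aw > 1:
        return "amplification"
    return "unit"


def apply_weight_multipliers(
    w: WeightMatrix,
    multipliers: Sequence[tuple[str, str, float]],
) -> WeightMatrix:
    """Scale named link weights by positive factors, leaving others untouched.

    Each multiplier is ``(source, target, factor)`` with ``factor > 0`` (sign
    changes are a topology randomization, not a weight adjustment).  This is
    the post-normalization adjustment used to amplify selected signal flows.
    """
    idx = {n: i for i, n in enumerate(w.node_order)}
    m = w.matrix.copy()
    for s, t, f in multipliers:
        if s not in idx or t not in idx:
            raise NetworkError(f"multiplier names unknown node in link {s}->{t}")
        i, j = idx[t], idx[s]
        if m[i, j] == 0:
            raise NetworkError(f"no link {s}->{t} to adjust")
        if not f > 0:
            raise ValueError(
                f"multiplier for {s}->{t} must be positive, got {f}"
            )
        m[i, j] *= f
    return replace(w, matrix=m)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _parse_sign(token: str) -> int | None:
    if token in SIF_POSITIVE:
        return 1
    if token in SIF_NEGATIVE:
        return -1
    return None


def read_network(path: str | Path, format: str | None = None) -> SignedNetwork:
    """Read a signed network from a SIF or signed edge-list TSV file.

    SIF lines are ``source TAB relation TAB target`` where the relation is
    one of ``activates``/``+``/``1`` or ``inhibits``/``-``/``-1``.  TSV lines
    are ``source TAB sign TAB target`` with the same sign tokens; a single
    header line is tolerated.  Node order is order of first appearance
    (sources before targets within a line).
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown network format {format!r}")
    nodes: list[str] = []
    seen: set[str] = set()
    links: list[tuple[str, str, int]] = []

    def add_node(n: str) -> None:
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# node\t"):
                add_node(line.split("\t", 1)[1].strip())
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1 and format == "sif":
                add_node(parts[0].strip())  # bare node line: isolated node
                continue
            if len(parts) != 3:
                raise NetworkError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            src, mid, tgt = (p.strip() for p in parts)
            sign = _parse_sign(mid)
            if sign is None:
                if lineno == 1:
                    continue  # header line
                raise NetworkError(
                    f"{path}:{lineno}: unknown sign/relation token {mid!r}"
                )
            add_node(src)
            add_node(tgt)
            links.append((src, tgt, sign))
    return SignedNetwork(nodes, links, name=path.stem)


def write_network(
    net: SignedNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write ``net`` as SIF or signed edge-list TSV (round-trips with
    :func:`read_network` up to node ordering)."""
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    with open(path, "w") as fh:
        for s, t, g in net.links:
            if format == "sif":
                fh.write(f"{s}\t{_SIF_TOKEN[g]}\t{t}\n")
            elif format == "tsv":
                fh.write(f"{s}\t{g:+d}\t{t}\n")
            else:
                raise ValueError(f"unknown network format {format!r}")
        # isolated nodes are representable in SIF as bare node lines; for TSV
        # they would be lost — emit them as comments either way for round-trip
        linked = {s for s, _, _ in net.links} | {t for _, t, _ in net.links}
        for n in net.nodes:
            if n not in linked:
                fh.write(f"# node\t{n}\n" if format == "tsv" else f"{n}\n")


def read_weight_multipliers(path: str | Path) -> list[tuple[str, str, float]]:
    """Read ``source TAB target TAB factor`` multiplier lines."""
    out: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkError(
                    f"{path}:{lineno}: expected source, target, factor"
                )
            try:
                factor = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise NetworkError(
                    f"{path}:{lineno}: factor {parts[2]!r} is not a number"
                ) from None
            out.append((parts[0].strip(), parts[1].strip(), factor))
    return out
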