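"""Degree-preserving topology randomization and weight-sampling policies.

The null model for "wrong topology" keeps every node's in- and out-degree
fixed: repeatedly pick two links at random and exchange their targets
(rejecting exchanges that would create a duplicate link or a new self-loop),
then flip the signs of randomly chosen links.  Defaults follow the original
evaluation protocol: number of swap events = number of links L, number of
flip events = floor(L / 2).

Weight-sampling policies replace the degree-normalized weights with random
magnitudes to probe how much the normalization itself matters:

    ``D``          decay only, |w| ~ (0.001, 1)
    ``D_plus_A``   decay and amplification, |w| ~ (0.001, 1000)
    ``N_D``        as D, then degree normalization applied
    ``N_D_plus_A`` as D_plus_A, then degree normalization applied

Signs always come from the network topology.  Magnitudes are drawn
uniformly over the stated range by default; a log-uniform option covers the
reading of "w ~ (a, b)" as spanning its 3-6 decades evenly.  Uniform is the
default because only under it does normalization recover the original
accuracy — the published hallmark of the N(D+A) policy — whereas log-uniform
magnitudes stay heterogeneous after normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import (
    SignedNetwork,
    WeightMatrix,
    build_adjacency,
    normalize_weights,
)

__all__ = [
    "RandomizationSpec",
    "WeightPolicy",
    "swap_links",
    "flip_signs",
    "randomize_topology",
    "sample_weights",
]

_POLICY_ALIASES = {
    "D": "D",
    "N_D": "N_D",
    "ND": "N_D",
    "N(D)": "N_D",
    "D_plus_A": "D_plus_A",
    "DA": "D_plus_A",
    "D+A": "D_plus_A",
    "N_D_plus_A": "N_D_plus_A",
    "NDA": "N_D_plus_A",
    "N(D+A)": "N_D_plus_A",
}


@dataclass(frozen=True)
class RandomizationSpec:
    """Counts and seed for :func:`randomize_topology`.

    ``n_swaps``/``n_flips`` default to L and floor(L/2) for a network with
    L links when left as None.
    """

    n_swaps: int | None = None
    n_flips: int | None = None
    seed: int | None = None
    max_retries: int = 100

    def __post_init__(self) -> None:
        for name in ("n_swaps", "n_flips"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")


@dataclass(frozen=True)
class WeightPolicy:
    """Weight-sampling policy for :func:`sample_weights`."""

    kind: str
    decay_range: tuple[float, float] = (0.001, 1.0)
    amp_range: tuple[float, float] = (0.001, 1000.0)
    distribution: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        kind = _POLICY_ALIASES.get(self.kind)
        if kind is None:
            raise ValueError(
                f"unknown weight policy {self.kind!r}; expected one of "
                f"{sorted(set(_POLICY_ALIASES.values()))} (or aliases "
                "D/ND/DA/NDA)"
            )
        object.__setattr__(self, "kind", kind)
        for rng_name in ("decay_range", "amp_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo < hi):
                raise ValueError(f"{rng_name} must satisfy 0 < low < high")
        if self.distribution not in ("log-uniform", "uniform"):
            raise ValueError(
                f"distribution must be 'log-uniform' or 'uniform', "
                f"got {self.distribution!r}"
            )

    @property
    def normalized(self) -> bool:
        return self.kind.startswith("N_")

    @property
    def magnitude_range(self) -> tuple[float, float]:
        return (
            self.decay_range if self.kind.endswith("D") else self.amp_range
        )


def _rng(seed: int | None | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def swap_links(
    net: SignedNetwork,
    n_swaps: int,
    seed: int | None | np.random.Generator = None,
    max_retries: int = 100,
) -> SignedNetwork:
    """Apply ``n_swaps`` target-exchanging link swaps.

    Each swap picks two distinct links (s1, t1) and (s2, t2) and replaces
    them with (s1, t2) and (s2, t1), keeping signs attached to the source
    link.  Sources keep their out-links and the target multiset is unchanged,
    so every node's in- and out-degree is preserved.  A proposal creating a
    duplicate ordered pair or a new self-loop is rejected and redrawn, up to
    ``max_retries`` times per swap; exhausted budgets skip the swap and a
    single warning reports the count at the end.
    """
    if net.n_links < 2:
        raise ValueError("need at least 2 links to swap")
    rng = _rng(seed)
    links = [list(l) for l in net.links]
    pairs = {(s, t) for s, t, _ in net.links}
    skipped = 0
    for _ in range(n_swaps):
        done = False
        for _ in range(max_retries):
            i, j = rng.choice(len(links), size=2, replace=False)
            s1, t1, g1 = links[i]
            s2, t2, g2 = links[j]
            new1, new2 = (s1, t2), (s2, t1)
            if new1 == (s1, t1):  # same targets: no-op, counts as a swap event
                done = True
                break
            if s1 == t2 or s2 == t1:
                continue  # would create a self-loop
            if (new1 in pairs and new1 != (s2, t2)) or (
                new2 in pairs and new2 != (s1, t1)
            ):
                continue  # would create a duplicate link
            pairs.discard((s1, t1))
            pairs.discard((s2, t2))
            pairs.add(new1)
            pairs.add(new2)
            links[i] = [s1, t2, g1]
            links[j] = [s2, t1, g2]
            done = True
            break
        if not done:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{skipped} of {n_swaps} swaps skipped after exhausting "
            f"{max_retries} retries each",
            stacklevel=2,
        )
    return SignedNetwork(net.nodes, [tuple(l) for l in links], name=net.name)


def flip_signs(
    net: SignedNetwork,
    n_flips: int,
    seed: int | None | np.random.Generator = None,
    distinct: bool = False,
) -> SignedNetwork:
    """Apply ``n_flips`` sign-flip events to randomly selected links.

    Selection is with replacement by default (two flips on the same link
    restore its sign); ``distinct=True`` forces flips on distinct links.
    Topology (the set of ordered pairs) is unchanged.
    """
    if net.n_links < 1:
        raise ValueError("need at least 1 link to flip")
    rng = _rng(seed)
    links = [list(l) for l in net.links]
    if distinct:
        if n_flips > len(links):
            raise ValueError(
                f"cannot flip {n_flips} distinct links out of {len(links)}"
            )
        chosen = rng.choice(len(links), size=n_flips, replace=False)
    else:
        chosen = rng.integers(0, len(links), size=n_flips)
    for i in chosen:
        links[i][2] = -links[i][2]
    return SignedNetwork(net.nodes, [tuple(l) for l in links], name=net.name)


def randomize_topology(
    net: SignedNetwork, spec: RandomizationSpec | None = None
) -> SignedNetwork:
    """Degree-preserving randomization: link swapping followed by sign
    flipping, with default counts L swaps and floor(L/2) flips."""
    spec = spec or RandomizationSpec()
    n_swaps = net.n_links if spec.n_swaps is None else spec.n_swaps
    n_flips = net.n_links // 2 if spec.n_flips is None else spec.n_flips
    rng = _rng(spec.seed)
    out = net
    if n_swaps > 0:
        out = swap_links(out, n_swaps, seed=rng, max_retries=spec.max_retries)
    if n_flips > 0:
        out = flip_signs(out, n_flips, seed=rng)
    return out


def sample_weights(
    net: SignedNetwork,
    policy: WeightPolicy,
    seed: int | None | np.random.Generator = None,
) -> WeightMatrix:
    """Draw a link-weight matrix under a sampling policy.

    Magnitudes are drawn from the policy's range (uniform by default,
    log-uniform optional), signs are taken from the links.  For ``N_*`` kinds the degree
    normalization is applied to the sampled matrix, with the sampled
    magnitudes entering the degree sums as absolute values.
    """
    rng = _rng(policy.seed if seed is None else seed)
    adj = build_adjacency(net)
    lo, hi = policy.magnitude_range
    mask = adj.matrix != 0
    n_entries = int(mask.sum())
    if policy.distribution == "log-uniform":
        mags = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_entries))
    else:
        mags = rng.uniform(lo, hi, size=n_entries)
    m = np.zeros_like(adj.matrix)
    m[mask] = np.sign(adj.matrix[mask]) * mags
    w = WeightMatrix(m, adj.node_order, normalized=False)
    if policy.normalized:
        w = normalize_weights(w)
    return w
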