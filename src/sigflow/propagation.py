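"""Log-linear signal propagation: iterative update and exact steady state.

The model is multiplicative in raw activities; taking logarithms turns it
into the linear difference equation

    ``x(t+1) = alpha * W @ x(t) + (1 - alpha) * b``

where ``x`` is the vector of log-activities, ``b`` the log basal activities
(sustained stimulation ``+1``, inhibitory perturbation ``-1``), ``W`` the
(normalized) link-weight matrix and ``alpha`` in (0, 1) balances incoming
signal flow against basal activity.  The steady state solves

    ``x_s = (1 - alpha) * (I - alpha W)^{-1} b``

and is independent of the initial state.  Convergence of the iteration and
invertibility of ``I - alpha W`` are both certified by a positive spectral
margin ``1 - alpha * rho(W)``.

Everything here works in log-space; callers wanting raw activities
exponentiate themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DivergenceError, SingularSystemError
from .network import WeightMatrix

__all__ = [
    "PropagationConfig",
    "BasalActivity",
    "ActivityState",
    "Trajectory",
    "propagate_iterative",
    "solve_steady_state",
    "solve",
    "spectral_margin",
]

_NORMS = {"l2": 2, "l1": 1, "linf": np.inf}

#: condition-number threshold above which I - alpha*W is treated as singular
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class PropagationConfig:
    """Solver settings.

    alpha : damping hyperparameter in the open interval (0, 1); 0.5 by
        default, meaning basal activity and incoming flow contribute equally.
    tol : iterative stopping tolerance on ``norm(x(t+1) - x(t))``.
    max_iter : iteration budget; hitting it returns ``converged=False``
        rather than raising, so evaluation workflows can skip the condition.
    mode : ``"exact"`` (linear solve, the default) or ``"iterative"``.
    norm : convergence norm, one of ``"l2"`` (default), ``"l1"``, ``"linf"``.
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    mode: str = "exact"
    norm: str = "l2"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if not self.max_iter >= 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.mode not in ("exact", "iterative"):
            raise ValueError(f"mode must be 'exact' or 'iterative', got {self.mode}")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {sorted(_NORMS)}, got {self.norm}")


@dataclass(frozen=True)
class BasalActivity:
    """Log basal activity vector ``b`` over an ordered node set."""

    values: np.ndarray
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.shape != (len(self.node_order),):
            raise ValueError(
                f"basal vector length {v.size} does not match "
                f"{len(self.node_order)} nodes"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("basal activities must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_order", tuple(self.node_order))

    @classmethod
    def from_dict(
        cls, values: Mapping[str, float], node_order: Sequence[str]
    ) -> "BasalActivity":
        unknown = set(values) - set(node_order)
        if unknown:
            raise ValueError(f"unknown node labels: {sorted(unknown)}")
        return cls(
            np.array([values.get(n, 0.0) for n in node_order]), tuple(node_order)
        )


@dataclass(frozen=True)
class ActivityState:
    """Log-activity vector for one condition, with convergence metadata."""

    values: np.ndarray
    node_order: tuple[str, ...]
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_order", tuple(self.node_order))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.values.tolist()))


@dataclass(frozen=True)
class Trajectory:
    """Snapshots x(t=1), x(t=2), ... of the iterative update."""

    states: tuple[ActivityState, ...]

    def __len__(self) -> int:
        return len(self.states)

    def as_array(self) -> np.ndarray:
        return np.stack([s.values for s in self.states])


def _check_aligned(w: WeightMatrix, b: BasalActivity) -> None:
    if w.node_order != b.node_order:
        raise ValueError(
            "weight matrix and basal activity have mismatched node orders"
        )


def propagate_iterative(
    w: WeightMatrix,
    b: BasalActivity,
    cfg: PropagationConfig | None = None,
    return_trajectory: bool = False,
) -> ActivityState | tuple[ActivityState, Trajectory]:
    """Iterate ``x(t+1) = alpha W x(t) + (1-alpha) b`` until the step norm
    falls below ``cfg.tol``.

    The initial state ``x(t=1)`` equals the basal activity ``b``.  Returns a
    state flagged ``converged=False`` if ``max_iter`` updates did not reach
    the tolerance; raises :class:`DivergenceError` on non-finite values
    (spectral margin <= 0).
    """
    cfg = cfg or PropagationConfig()
    _check_aligned(w, b)
    ord_ = _NORMS[cfg.norm]
    x = b.values.copy()
    traj = [ActivityState(x.copy(), w.node_order, iterations=0)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        x_new = cfg.alpha * (w.matrix @ x) + (1 - cfg.alpha) * b.values
        if not np.all(np.isfinite(x_new)):
            raise DivergenceError(
                f"non-finite activities at iteration {it}; the propagation "
                "diverges — check spectral_margin(W, alpha) > 0"
            )
        delta = float(np.linalg.norm(x_new - x, ord=ord_))
        x = x_new
        if return_trajectory:
            traj.append(ActivityState(x.copy(), w.node_order, iterations=it))
        if delta < cfg.tol:
            converged = True
            break
    state = ActivityState(x, w.node_order, converged=converged, iterations=it)
    if return_trajectory:
        return state, Trajectory(tuple(traj))
    return state


def solve_steady_state(
    w: WeightMatrix, b: BasalActivity, cfg: PropagationConfig | None = None
) -> ActivityState:
    """Exact steady state ``x_s = (1-alpha)(I - alpha W)^{-1} b``.

    Uses a linear solve rather than explicit inversion.  Raises
    :class:`SingularSystemError` when ``I - alpha W`` is singular or its
    condition number exceeds 1e12.
    """
    cfg = cfg or PropagationConfig()
    _check_aligned(w, b)
    n = len(w.node_order)
    m = np.eye(n) - cfg.alpha * w.matrix
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularSystemError(
            f"I - alpha*W is singular or near-singular "
            f"(condition number {cond:.3e}); the steady state is not "
            "well-defined for these weights"
        )
    x = (1 - cfg.alpha) * np.linalg.solve(m, b.values)
    return ActivityState(x, w.node_order, converged=True, iterations=0)


def solve(
    w: WeightMatrix, b: BasalActivity, cfg: PropagationConfig | None = None
) -> ActivityState:
    """Dispatch on ``cfg.mode``: exact linear solve or iterative update."""
    cfg = cfg or PropagationConfig()
    if cfg.mode == "iterative":
        return propagate_iterative(w, b, cfg)
    return solve_steady_state(w, b, cfg)


def spectral_margin(w: WeightMatrix, alpha: float) -> float:
    """``1 - alpha * rho(W)`` with ``rho`` the spectral radius.

    A positive margin certifies convergence of the propagation iteration and
    invertibility of ``I - alpha W``.
    """
    if len(w.node_order) == 0:
        return 1.0
    rho = float(np.max(np.abs(np.linalg.eigvals(w.matrix))))
    return 1.0 - alpha * rho
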