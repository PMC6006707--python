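"""Steady-state solving for one model: multi-start integration and
deduplication of the reached attractors.

A model is integrated window by window (fixed-step Euler or classic
Runge-Kutta) until the largest per-gene change of log2 level within one
window drops below ``conv_tol``; runs that exhaust ``max_windows`` (for
example on a limit cycle) are flagged non-converged and excluded.
Distinct stable states are the greedy subset of converged endpoints whose
pairwise Euclidean distances in log2 space all exceed ``dedup_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import ParamSet, hill_affine_coefficients, level_bounds
from .topology import CircuitTopology

__all__ = [
    "SolverConfig",
    "StableStateSet",
    "sample_initial_condition",
    "sample_initial_conditions",
    "integrate_to_steady",
    "deduplicate_states",
    "find_stable_states",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the steady-state solver.

    ``dt`` defaults to 0.01 for Euler and 0.1 for Runge-Kutta; a window
    of ``t_window`` time units is integrated between convergence checks.
    """

    method: str = "rk4"
    dt: float = None  # type: ignore[assignment]
    t_window: float = 50.0
    max_windows: int = 200
    conv_tol: float = 1e-3
    dedup_tol: float = 1.0
    level_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.dt is None:
            object.__setattr__(self, "dt", 0.01 if self.method == "euler" else 0.1)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_window < 10 * self.dt:
            raise ValueError("t_window must be at least 10*dt")
        if self.conv_tol <= 0 or self.dedup_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_windows < 1:
            raise ValueError("max_windows must be >= 1")

    @property
    def steps_per_window(self) -> int:
        return max(1, int(round(self.t_window / self.dt)))


@dataclass
class StableStateSet:
    """Distinct stable steady states found for one model."""

    model_index: int
    states: list[np.ndarray] = field(default_factory=list)
    n_nonconverged: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states)


def _edge_arrays(topology: CircuitTopology):
    src = np.array([topology.gene_index(e.source) for e in topology.edges],
                   dtype=np.int64)
    tgt = np.array([topology.gene_index(e.target) for e in topology.edges],
                   dtype=np.int64)
    return src, tgt


def sample_initial_conditions(
    params: ParamSet,
    topology: CircuitTopology,
    n: int,
    rng: np.random.Generator,
    floor: float = 1e-10,
) -> np.ndarray:
    """Draw ``n`` initial expression vectors, log-uniform per gene.

    Bounds per gene are the extreme steady-level bounds of the model
    (see :func:`pyracipe.model_core.level_bounds`).  A gene whose upper
    bound is at the floor (e.g. a knocked-out gene) starts at exactly 0.
    Returns shape ``(n, n_genes)``.
    """
    lo, hi = level_bounds(params, topology, floor=floor)
    llo, lhi = np.log(lo), np.log(hi)
    draws = rng.uniform(llo, lhi, size=(n, topology.n_genes))
    levels = np.exp(draws)
    degenerate = lo >= hi  # unregulated gene: interval collapses to G/k
    levels[:, degenerate] = lo[degenerate]
    levels[:, hi <= floor] = 0.0
    return levels


def sample_initial_condition(
    params: ParamSet,
    topology: CircuitTopology,
    rng: np.random.Generator,
    floor: float = 1e-10,
) -> np.ndarray:
    return sample_initial_conditions(params, topology, 1, rng, floor=floor)[0]


def _integrate_batch(
    params: ParamSet,
    topology: CircuitTopology,
    inits: np.ndarray,
    cfg: SolverConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of initial conditions; returns (states, converged)
    with states of shape ``(n, n_genes)``."""
    src, tgt = _edge_arrays(topology)
    hA, hB = hill_affine_coefficients(params, topology)
    x0 = np.ascontiguousarray(np.asarray(inits, dtype=float).T)
    out, conv = _kernels.integrate_model(
        x0,
        np.asarray(params.production, dtype=float),
        np.asarray(params.degradation, dtype=float),
        src,
        tgt,
        np.asarray(params.threshold, dtype=float),
        np.asarray(params.hill, dtype=float),
        hA,
        hB,
        cfg.method == "rk4",
        float(cfg.dt),
        cfg.steps_per_window,
        cfg.max_windows,
        float(cfg.conv_tol),
        float(cfg.level_floor),
    )
    return out.T.copy(), conv


def integrate_to_steady(
    params: ParamSet,
    topology: CircuitTopology,
    init: np.ndarray,
    cfg: SolverConfig = SolverConfig(),
) -> tuple[np.ndarray | None, bool]:
    """Advance one trajectory to a stable steady state.

    Returns ``(state, True)`` on convergence or ``(final state, False)``
    if the run never settles (NaN/overflow also lands here, never an
    exception).
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (topology.n_genes,) or np.any(init < 0):
        raise ValueError("initial condition must be a non-negative vector "
                         "matching the topology")
    states, conv = _integrate_batch(params, topology, init[None, :], cfg)
    return states[0], bool(conv[0])


def deduplicate_states(
    states, dedup_tol: float = 1.0, floor: float = 1e-10
) -> list[np.ndarray]:
    """Greedy first-come deduplication in log2 space.

    A state is kept iff its Euclidean distance (log2 levels) to every
    previously kept state exceeds ``dedup_tol``; output preserves
    first-occurrence order.
    """
    kept: list[np.ndarray] = []
    kept_log: list[np.ndarray] = []
    for s in states:
        s = np.asarray(s, dtype=float)
        slog = np.log2(np.maximum(s, 0.0) + floor)
        if all(np.linalg.norm(slog - kl) > dedup_tol for kl in kept_log):
            kept.append(s)
            kept_log.append(slog)
    return kept


def find_stable_states(
    params: ParamSet,
    topology: CircuitTopology,
    n_init: int,
    rng: np.random.Generator,
    cfg: SolverConfig = SolverConfig(),
    model_index: int = 0,
) -> StableStateSet:
    """Multi-start enumeration of a model's distinct stable states."""
    inits = sample_initial_conditions(
        params, topology, n_init, rng, floor=cfg.level_floor
    )
    finals, conv = _integrate_batch(params, topology, inits, cfg)
    states = deduplicate_states(
        finals[conv], dedup_tol=cfg.dedup_tol, floor=cfg.level_floor
    )
    return StableStateSet(
        model_index=model_index,
        states=states,
        n_nonconverged=int(np.sum(~conv)),
    )
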