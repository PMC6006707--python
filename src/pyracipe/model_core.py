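"""Shifted-Hill regulatory kinetics and the circuit ODE right-hand side.

Each gene ``i`` obeys a production/degradation balance

    dX_i/dt = G_i * prod_j F_ji(X_j) - k_i * X_i

where the product runs over the regulators ``j`` of ``i``.  The response
to a single regulator is built from the shifted Hill function

    H_S(X) = lambda + (1 - lambda) / (1 + (X / X0)^n),

which interpolates between 1 (regulator absent) and the maximum fold
change ``lambda`` (regulator saturating).  For inhibition
(``lambda < 1``) the regulatory factor is ``F = H_S`` directly.  For
activation (``lambda > 1``), ``G_i`` is defined as the production rate
with all activators bound (and no inhibitor), so the activating factor
is normalized to saturate at one: ``F = H_S / lambda``, ranging from
``1/lambda`` with the activator absent up to 1.  Multiple regulators act
independently, so their factors multiply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import CircuitTopology

__all__ = [
    "ParamSet",
    "shifted_hill",
    "regulation_factor",
    "derivatives",
    "level_bounds",
    "hill_affine_coefficients",
]


@dataclass
class ParamSet:
    """Kinetic parameters of one randomized model.

    Arrays follow topology order: ``production`` (G) and ``degradation``
    (k) per gene; ``threshold`` (X0), ``hill`` (n) and ``fold_change``
    (lambda) per edge, in edge-list order.
    """

    production: np.ndarray
    degradation: np.ndarray
    threshold: np.ndarray
    hill: np.ndarray
    fold_change: np.ndarray

    def validate(self, topology: CircuitTopology) -> None:
        ng, ne = topology.n_genes, topology.n_edges
        if len(self.production) != ng or len(self.degradation) != ng:
            raise ValueError("per-gene parameter arrays do not match topology")
        if not (len(self.threshold) == len(self.hill) == len(self.fold_change) == ne):
            raise ValueError("per-edge parameter arrays do not match topology")
        if np.any(self.production < 0):
            raise ValueError("production rates must be >= 0")
        if np.any(self.degradation <= 0):
            raise ValueError("degradation rates must be > 0")
        if np.any(self.threshold <= 0):
            raise ValueError("thresholds must be > 0")
        if np.any(self.hill < 1):
            raise ValueError("Hill coefficients must be >= 1")
        for e, lam in zip(topology.edges, self.fold_change):
            if e.is_inhibition and not 0 < lam <= 1:
                raise ValueError(
                    f"inhibitory fold change for {e.source}->{e.target} "
                    f"must lie in (0, 1], got {lam}"
                )
            if not e.is_inhibition and lam < 1:
                raise ValueError(
                    f"activating fold change for {e.source}->{e.target} "
                    f"must be >= 1, got {lam}"
                )


def shifted_hill(X, X0, n, lam):
    """Shifted Hill function ``lam + (1 - lam) / (1 + (X/X0)^n)``.

    Accepts scalars or arrays; bounded between ``min(1, lam)`` and
    ``max(1, lam)``.  ``X0`` must be positive.
    """
    X0 = np.asarray(X0, dtype=float)
    if np.any(X0 <= 0):
        raise ValueError("shifted_hill: threshold X0 must be > 0")
    X = np.asarray(X, dtype=float)
    h_inh = 1.0 / (1.0 + (X / X0) ** n)
    out = lam + (1.0 - lam) * h_inh
    return out if out.ndim else float(out)


def regulation_factor(X, X0, n, lam, inhibition: bool):
    """Multiplicative effect of one regulator on its target's production.

    Inhibition: the shifted Hill value itself (1 down to lam).
    Activation: shifted Hill normalized by lam (1/lam up to 1), because
    the target's G is its production rate at full activator binding.
    """
    h = shifted_hill(X, X0, n, lam)
    return h if inhibition else h / lam


def derivatives(
    state: np.ndarray, params: ParamSet, topology: CircuitTopology
) -> np.ndarray:
    """Rates dX/dt for every gene at the given expression state."""
    state = np.asarray(state, dtype=float)
    if state.shape != (topology.n_genes,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({topology.n_genes},)"
        )
    production = params.production.astype(float).copy()
    for idx, e in enumerate(topology.edges):
        j = topology.gene_index(e.source)
        i = topology.gene_index(e.target)
        production[i] *= regulation_factor(
            state[j],
            params.threshold[idx],
            params.hill[idx],
            params.fold_change[idx],
            e.is_inhibition,
        )
    return production - params.degradation * state


def hill_affine_coefficients(
    params: ParamSet, topology: CircuitTopology
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge constants (a, b) with regulatory factor a + b/(1+(X/X0)^n).

    Inhibition: a = lam, b = 1 - lam.  Activation (normalized by lam):
    a = 1, b = 1/lam - 1.  Used by the compiled integrator.
    """
    a = np.empty(topology.n_edges)
    b = np.empty(topology.n_edges)
    for idx, e in enumerate(topology.edges):
        lam = params.fold_change[idx]
        if e.is_inhibition:
            a[idx] = lam
            b[idx] = 1.0 - lam
        else:
            a[idx] = 1.0
            b[idx] = 1.0 / lam - 1.0
    return a, b


def level_bounds(
    params: ParamSet, topology: CircuitTopology, floor: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Extreme steady-state level bounds per gene.

    Each incoming inhibition contributes a factor in [lam, 1] and each
    incoming activation a factor in [1/lam, 1], so gene i's steady level
    lies between G_i/k_i times the product of the minimal factors and
    G_i/k_i itself.  Used to bound log-uniform initial-condition
    sampling; the lower bound is floored at ``floor``.
    """
    base = params.production / params.degradation
    lo = base.copy()
    hi = base.copy()
    for idx, e in enumerate(topology.edges):
        i = topology.gene_index(e.target)
        lam = params.fold_change[idx]
        lo[i] *= lam if e.is_inhibition else 1.0 / lam
    return np.maximum(lo, floor), np.maximum(hi, floor)
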