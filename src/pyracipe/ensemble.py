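"""Ensemble orchestration: many randomized models, many starts each.

``run_ensemble`` samples ``num_models`` parameter sets from the circuit's
randomization ranges, enumerates each model's stable states from
``num_init_conds`` log-uniform starts, and collects everything into an
:class:`EnsembleResult`.  Each model's random stream is derived from
``(master_seed, stream, model_index)`` so results do not depend on
execution order.

On disk the ensemble follows the plain-matrix convention:

* ``<prefix>.topo``            the circuit
* ``<prefix>.prs``             parameter ranges (tab-delimited)
* ``<prefix>_parameter.dat``   one row per model: index (1-based), number
  of stable states, then the parameters in ``.prs`` order
* ``<prefix>_solution_<i>.dat`` for each realized state count ``i``: one
  row per model with ``i`` states: index, then i * n_genes log2 levels
  (states in discovery order, genes in topology order)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .randomization import (
    ParameterRanges,
    build_parameter_ranges,
    paramset_from_vector,
    paramset_to_vector,
    read_prs,
    sample_parameters,
    write_prs,
)
from .simulate import SolverConfig, StableStateSet, find_stable_states
from .topology import CircuitTopology, load_topo, write_topo

__all__ = ["EnsembleResult", "run_ensemble", "write_outputs", "read_outputs"]


@dataclass
class EnsembleResult:
    topology: CircuitTopology
    ranges: ParameterRanges
    params: np.ndarray                      # (num_models, n_parameters)
    models: list[StableStateSet]            # one record per model
    num_models: int
    num_init_conds: int
    master_seed: int | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)

    @property
    def state_counts(self) -> np.ndarray:
        return np.array([m.n_states for m in self.models], dtype=int)

    @property
    def total_states(self) -> int:
        return int(self.state_counts.sum())

    def state_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """All stable states stacked: (model indices, log2-level matrix)."""
        rows = []
        owners = []
        floor = self.solver.level_floor
        for m in self.models:
            for s in m.states:
                rows.append(np.log2(np.maximum(s, 0.0) + floor))
                owners.append(m.model_index)
        if rows:
            return np.array(owners, dtype=int), np.vstack(rows)
        return np.zeros(0, dtype=int), np.zeros((0, self.topology.n_genes))

    def paramset(self, model_index: int):
        return paramset_from_vector(self.params[model_index], self.ranges)


def _model_rng(master_seed: int, stream: int, model: int) -> np.random.Generator:
    return np.random.default_rng([master_seed, stream, model])


def run_ensemble(
    topology: CircuitTopology,
    num_models: int,
    num_init_conds: int,
    solver: SolverConfig = SolverConfig(),
    master_seed: int = 1,
    ranges: ParameterRanges | None = None,
) -> EnsembleResult:
    """Generate and solve the randomized model ensemble.

    ``ranges`` can be supplied (e.g. after a perturbation) to reuse the
    ranges of a reference ensemble; otherwise they are estimated from the
    topology with a stream derived from the master seed.
    """
    if num_models < 1 or num_init_conds < 1:
        raise ValueError("num_models and num_init_conds must be >= 1")
    if ranges is None:
        ranges = build_parameter_ranges(topology, rng=_model_rng(master_seed, 0, 0))
    params = np.empty((num_models, len(ranges)))
    models: list[StableStateSet] = []
    for m in range(num_models):
        rng = _model_rng(master_seed, 1, m)
        pset = sample_parameters(ranges, rng)
        params[m] = paramset_to_vector(pset, ranges)
        result = find_stable_states(
            pset, topology, num_init_conds, rng, cfg=solver, model_index=m
        )
        models.append(result)
    return EnsembleResult(
        topology=topology,
        ranges=ranges,
        params=params,
        models=models,
        num_models=num_models,
        num_init_conds=num_init_conds,
        master_seed=master_seed,
        solver=solver,
    )


def write_outputs(result: EnsembleResult, prefix: str) -> list[str]:
    """Serialize an ensemble; returns the list of files written."""
    files = []
    topo_path = f"{prefix}.topo"
    write_topo(result.topology, topo_path)
    files.append(topo_path)
    prs_path = f"{prefix}.prs"
    write_prs(result.ranges, prs_path)
    files.append(prs_path)

    param_path = f"{prefix}_parameter.dat"
    with open(param_path, "w", encoding="utf-8") as fh:
        for m, model in enumerate(result.models):
            row = [str(m + 1), str(model.n_states)]
            row += [f"{v:.6g}" for v in result.params[m]]
            fh.write("\t".join(row) + "\n")
    files.append(param_path)

    floor = result.solver.level_floor
    counts = sorted({m.n_states for m in result.models if m.n_states > 0})
    for count in counts:
        sol_path = f"{prefix}_solution_{count}.dat"
        with open(sol_path, "w", encoding="utf-8") as fh:
            for m, model in enumerate(result.models):
                if model.n_states != count:
                    continue
                row = [str(m + 1)]
                for s in model.states:
                    row += [
                        f"{v:.6f}"
                        for v in np.log2(np.maximum(s, 0.0) + floor)
                    ]
                fh.write("\t".join(row) + "\n")
        files.append(sol_path)
    return files


def read_outputs(prefix: str) -> EnsembleResult:
    """Reconstruct an ensemble from its output files.

    Log2 levels are mapped back to linear levels; values at the level
    floor are restored to exactly zero.
    """
    topology = load_topo(f"{prefix}.topo")
    ranges = read_prs(f"{prefix}.prs", topology)
    floor = SolverConfig().level_floor

    param_path = f"{prefix}_parameter.dat"
    counts: list[int] = []
    param_rows: list[np.ndarray] = []
    with open(param_path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2 + len(ranges):
                raise ValueError(
                    f"{param_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {2 + len(ranges)}"
                )
            counts.append(int(fields[1]))
            param_rows.append(np.array([float(v) for v in fields[2:]]))
    num_models = len(counts)
    params = (
        np.vstack(param_rows) if param_rows else np.zeros((0, len(ranges)))
    )

    models = [
        StableStateSet(model_index=m, states=[]) for m in range(num_models)
    ]
    ng = topology.n_genes
    for count in sorted({c for c in counts if c > 0}):
        sol_path = f"{prefix}_solution_{count}.dat"
        if not os.path.exists(sol_path):
            raise ValueError(
                f"missing {sol_path} although {param_path} lists models "
                f"with {count} states"
            )
        with open(sol_path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 1 + count * ng:
                    raise ValueError(
                        f"{sol_path}: line {lineno} has {len(fields)} fields,"
                        f" expected {1 + count * ng}"
                    )
                m = int(fields[0]) - 1
                if not 0 <= m < num_models or counts[m] != count:
                    raise ValueError(
                        f"{sol_path}: line {lineno} references model "
                        f"{fields[0]} inconsistently with {param_path}"
                    )
                vals = np.array([float(v) for v in fields[1:]])
                for si in range(count):
                    levels = 2.0 ** vals[si * ng:(si + 1) * ng]
                    levels[levels <= floor * (1 + 1e-9)] = 0.0
                    models[m].states.append(levels)
    for m, c in enumerate(counts):
        if len(models[m].states) != c:
            raise ValueError(
                f"model {m + 1}: expected {c} states, found "
                f"{len(models[m].states)} in solution files"
            )
    return EnsembleResult(
        topology=topology,
        ranges=ranges,
        params=params,
        models=models,
        num_models=num_models,
        num_init_conds=0,
        master_seed=None,
    )
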