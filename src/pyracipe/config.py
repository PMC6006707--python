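"""Simulation configuration shared by range building, solving and the CLI.

Defaults encode the standard randomization ranges: production rates
uniform on [1, 100], degradation rates uniform on [0.1, 1], Hill
coefficients uniform integers on {1..6}, and fold changes uniform on
[1, 100] (reciprocal for inhibition, so inhibitory lambda lies in
[0.01, 1]).  Threshold ranges are estimated per circuit from the
half-functional rule (see :mod:`pyracipe.randomization`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class SimulationConfig:
    # ensemble size
    num_models: int = 10_000          # randomized models (nRM)
    num_init_conds: int = 1_000       # initial conditions per model (nIC)
    seed: int = 1

    # solver
    method: str = "rk4"               # "euler" or "rk4"
    dt: float | None = None           # None -> 0.01 (euler) / 0.1 (rk4)
    t_window: float = 50.0            # time integrated per convergence check
    max_windows: int = 200
    conv_tol: float = 1e-3            # max |delta log2 level| per window
    dedup_tol: float = 1.0            # Euclidean distance in log2 space
    level_floor: float = 1e-10        # floor applied before log transforms

    # randomization ranges
    prod_min: float = 1.0
    prod_max: float = 100.0
    deg_min: float = 0.1
    deg_max: float = 1.0
    hill_min: int = 1
    hill_max: int = 6
    fold_min: float = 1.0
    fold_max: float = 100.0
    threshold_mult_low: float = 0.02   # threshold range = M * [low, high]
    threshold_mult_high: float = 1.98  # around the median standalone level M
    mc_samples: int = 10_000           # Monte-Carlo draws for the median

    # output
    prefix: str = "circuit"

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.dt is None:
            self.dt = 0.01 if self.method == "euler" else 0.1
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_window < 10 * self.dt:
            raise ValueError("t_window must be at least 10*dt")
        for name in ("num_models", "num_init_conds", "max_windows",
                     "conv_tol", "dedup_tol", "level_floor", "mc_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **overrides) -> "SimulationConfig":
        known = {f.name for f in fields(self)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return SimulationConfig(**values)


DEFAULT_CONFIG = SimulationConfig()
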