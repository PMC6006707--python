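"""Parameter randomization ranges and sampling.

Production and degradation ranges are preset (config-overridable); the
threshold range of every regulatory link is estimated numerically so the
link satisfies the *half-functional rule*: across the ensemble, the
regulator's level should cross its threshold in roughly half the models.

The threshold range for a link is ``(0.02*M, 1.98*M)`` where ``M`` is
the Monte-Carlo median of the regulator's level across the ensemble — an
interval symmetric about the median, so a uniformly drawn threshold is
crossed with ~50% probability.  Because a regulated gene's level depends
on its regulators' levels and thresholds, the per-gene medians are
computed self-consistently: starting from the unregulated level
``G/k``, each iteration re-draws every gene's level sample as ``G/k``
times the regulatory factors of its incoming links, with regulator
levels resampled from the previous iteration and thresholds drawn from
the current median estimates, until the medians stabilize.  For an
unregulated gene this reduces to the median of ``G/k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, SimulationConfig
from .model_core import ParamSet
from .topology import CircuitTopology, RegEdge

__all__ = [
    "RangeEntry",
    "ParameterRanges",
    "build_parameter_ranges",
    "estimate_gene_medians",
    "estimate_threshold_range",
    "sample_parameters",
    "write_prs",
    "read_prs",
]

# sampling laws
UNIFORM = "uniform"
INT_UNIFORM = "int_uniform"
RECIPROCAL = "reciprocal_uniform"   # 1 / U[1/max, 1/min]; inhibitory fold changes


@dataclass(frozen=True)
class RangeEntry:
    name: str
    minimum: float
    maximum: float
    law: str

    def sample(self, rng: np.random.Generator) -> float:
        # Degenerate intervals (e.g. a knocked-out production range) still
        # consume one draw so perturbed ensembles stay paired with the
        # reference ensemble under the same seed.
        if self.law == UNIFORM:
            return float(rng.uniform(self.minimum, self.maximum))
        if self.law == INT_UNIFORM:
            return float(rng.integers(int(self.minimum), int(self.maximum) + 1))
        if self.law == RECIPROCAL:
            return float(1.0 / rng.uniform(1.0 / self.maximum, 1.0 / self.minimum))
        raise ValueError(f"unknown sampling law {self.law!r}")


class ParameterRanges:
    """Ordered randomization intervals for every model parameter.

    Canonical order (identical in ``circuit.prs`` and in the columns of
    ``circuit_parameter.dat``): per gene ``Prod_of_<g>``, ``Deg_of_<g>``
    in topology order, then per edge ``Trd_of_<s>To<t>``,
    ``Num_of_<s>To<t>``, ``Fld_of_<s>To<t>`` in edge order.
    """

    def __init__(self, topology: CircuitTopology, entries: list[RangeEntry]):
        expected = canonical_names(topology)
        got = [e.name for e in entries]
        if got != expected:
            raise ValueError(
                "range entries do not match the canonical parameter order "
                f"for this topology (expected {len(expected)} entries)"
            )
        for e in entries:
            if e.minimum > e.maximum:
                raise ValueError(f"{e.name}: minimum {e.minimum} > maximum {e.maximum}")
        self.topology = topology
        self.entries = list(entries)
        self._index = {e.name: i for i, e in enumerate(entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> RangeEntry:
        return self.entries[self._index[name]]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterRanges)
            and self.topology == other.topology
            and self.entries == other.entries
        )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def with_entry(self, name: str, **changes) -> "ParameterRanges":
        """Copy with one entry's fields replaced (used by perturbations)."""
        entries = list(self.entries)
        i = self._index[name]
        old = entries[i]
        entries[i] = RangeEntry(
            name=old.name,
            minimum=changes.get("minimum", old.minimum),
            maximum=changes.get("maximum", old.maximum),
            law=changes.get("law", old.law),
        )
        return ParameterRanges(self.topology, entries)


def canonical_names(topology: CircuitTopology) -> list[str]:
    names: list[str] = []
    for g in topology.genes:
        names += [f"Prod_of_{g}", f"Deg_of_{g}"]
    for e in topology.edges:
        tag = f"{e.source}To{e.target}"
        names += [f"Trd_of_{tag}", f"Num_of_{tag}", f"Fld_of_{tag}"]
    return names


def _round_sig(x: float, digits: int = 6) -> float:
    return float(np.format_float_positional(
        x, precision=digits, unique=False, fractional=False, trim="-"
    ))


def _fold_entry(edge: RegEdge, cfg: SimulationConfig, name: str) -> RangeEntry:
    if edge.is_inhibition:
        return RangeEntry(name, 1.0 / cfg.fold_max, 1.0 / cfg.fold_min, RECIPROCAL)
    return RangeEntry(name, cfg.fold_min, cfg.fold_max, UNIFORM)


def _sample_fold_change(entry: RangeEntry, rng, size: int) -> np.ndarray:
    if entry.law == RECIPROCAL:
        return 1.0 / rng.uniform(1.0 / entry.maximum, 1.0 / entry.minimum, size)
    return rng.uniform(entry.minimum, entry.maximum, size=size)


def estimate_gene_medians(
    topology: CircuitTopology,
    ranges,
    mc_samples: int = 10_000,
    rng: np.random.Generator | None = None,
    cfg: SimulationConfig = DEFAULT_CONFIG,
    n_iterations: int = 10,
) -> dict[str, float]:
    """Self-consistent Monte-Carlo medians of every gene's level.

    ``ranges`` maps parameter names to :class:`RangeEntry` for the
    production, degradation and fold-change parameters (a
    :class:`ParameterRanges` or a plain dict).  Each iteration rebuilds
    every gene's level sample as (G/k) times, per incoming link, the
    regulatory factor evaluated at a regulator level resampled from the
    previous iteration against a threshold drawn around the current
    median; medians are updated until they stabilize.
    """
    if mc_samples < 1000:
        raise ValueError("mc_samples must be >= 1000 for a stable median estimate")
    if rng is None:
        rng = np.random.default_rng()

    def base_level(gene: str) -> np.ndarray:
        prod = ranges[f"Prod_of_{gene}"]
        deg = ranges[f"Deg_of_{gene}"]
        G = rng.uniform(prod.minimum, prod.maximum, size=mc_samples)
        k = rng.uniform(deg.minimum, deg.maximum, size=mc_samples)
        return G / k

    levels = {g: base_level(g) for g in topology.genes}
    medians = {g: float(np.median(v)) for g, v in levels.items()}
    hill_lo, hill_hi = int(cfg.hill_min), int(cfg.hill_max)
    for _ in range(n_iterations):
        new_levels = {}
        for gene in topology.genes:
            lvl = base_level(gene)
            for e in topology.in_edges(gene):
                fld = ranges[f"Fld_of_{e.source}To{e.target}"]
                reg_med = max(medians[e.source], 1e-300)
                X = rng.permutation(levels[e.source])
                B0 = rng.uniform(
                    cfg.threshold_mult_low * reg_med,
                    cfg.threshold_mult_high * reg_med,
                    mc_samples,
                )
                n = rng.integers(hill_lo, hill_hi + 1, mc_samples)
                lam = _sample_fold_change(fld, rng, mc_samples)
                hs = lam + (1.0 - lam) / (1.0 + (X / B0) ** n)
                if not e.is_inhibition:
                    hs = hs / lam
                lvl = lvl * hs
            new_levels[gene] = lvl
        levels = new_levels
        medians = {g: float(np.median(v)) for g, v in levels.items()}
    return medians


def estimate_threshold_range(
    edge: RegEdge,
    topology: CircuitTopology,
    ranges,
    mc_samples: int = 10_000,
    rng: np.random.Generator | None = None,
    cfg: SimulationConfig = DEFAULT_CONFIG,
    medians: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Half-functional threshold interval for one regulatory link.

    Returns ``(mult_low * M, mult_high * M)`` where M is the regulator's
    self-consistent median level (see :func:`estimate_gene_medians`; a
    precomputed ``medians`` mapping avoids re-running the estimate per
    edge).
    """
    if medians is None:
        medians = estimate_gene_medians(
            topology, ranges, mc_samples=mc_samples, rng=rng, cfg=cfg
        )
    M = medians[edge.source]
    return cfg.threshold_mult_low * M, cfg.threshold_mult_high * M


def build_parameter_ranges(
    topology: CircuitTopology,
    cfg: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
) -> ParameterRanges:
    """Randomization ranges for every parameter of a circuit.

    Threshold bounds are Monte-Carlo estimates (seeded through ``rng``)
    rounded to 6 significant digits so the ``.prs`` file round-trips
    exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    entries: list[RangeEntry] = []
    for g in topology.genes:
        entries.append(RangeEntry(f"Prod_of_{g}", cfg.prod_min, cfg.prod_max, UNIFORM))
        entries.append(RangeEntry(f"Deg_of_{g}", cfg.deg_min, cfg.deg_max, UNIFORM))
    base = {e.name: e for e in entries}
    for e in topology.edges:
        tag = f"{e.source}To{e.target}"
        base[f"Fld_of_{tag}"] = _fold_entry(e, cfg, f"Fld_of_{tag}")
    medians = estimate_gene_medians(
        topology, base, mc_samples=cfg.mc_samples, rng=rng, cfg=cfg
    )
    for e in topology.edges:
        tag = f"{e.source}To{e.target}"
        lo, hi = estimate_threshold_range(
            e, topology, base, mc_samples=cfg.mc_samples, rng=rng, cfg=cfg,
            medians=medians,
        )
        entries.append(
            RangeEntry(f"Trd_of_{tag}", _round_sig(lo), _round_sig(hi), UNIFORM)
        )
        entries.append(
            RangeEntry(f"Num_of_{tag}", float(cfg.hill_min), float(cfg.hill_max),
                       INT_UNIFORM)
        )
        entries.append(base[f"Fld_of_{tag}"])
    return ParameterRanges(topology, entries)


def sample_parameters(
    ranges: ParameterRanges, rng: np.random.Generator
) -> ParamSet:
    """Draw one complete parameter set, each parameter independent."""
    values = np.array([e.sample(rng) for e in ranges.entries])
    return paramset_from_vector(values, ranges)


def paramset_from_vector(values: np.ndarray, ranges: ParameterRanges) -> ParamSet:
    topo = ranges.topology
    ng, ne = topo.n_genes, topo.n_edges
    per_gene = values[: 2 * ng].reshape(ng, 2)
    per_edge = values[2 * ng:].reshape(ne, 3)
    return ParamSet(
        production=per_gene[:, 0].copy(),
        degradation=per_gene[:, 1].copy(),
        threshold=per_edge[:, 0].copy(),
        hill=per_edge[:, 1].copy(),
        fold_change=per_edge[:, 2].copy(),
    )


def paramset_to_vector(params: ParamSet, ranges: ParameterRanges) -> np.ndarray:
    per_gene = np.column_stack([params.production, params.degradation]).ravel()
    per_edge = np.column_stack(
        [params.threshold, params.hill, params.fold_change]
    ).ravel()
    return np.concatenate([per_gene, per_edge])


def write_prs(ranges: ParameterRanges, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Parameter\tMinimum\tMaximum\n")
        for e in ranges.entries:
            fh.write(f"{e.name}\t{e.minimum:.6g}\t{e.maximum:.6g}\n")


def read_prs(path, topology: CircuitTopology) -> ParameterRanges:
    """Rebuild ranges from a ``.prs`` file; sampling laws are implied by
    the parameter kind and the edge type in the topology."""
    inhibitory = {
        f"Fld_of_{e.source}To{e.target}" for e in topology.edges if e.is_inhibition
    }
    entries: list[RangeEntry] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if [h.lower() for h in header] != ["parameter", "minimum", "maximum"]:
            raise ValueError(f"{path}: missing 'Parameter Minimum Maximum' header")
        for line in fh:
            if not line.strip():
                continue
            name, lo, hi = line.split()
            if name.startswith("Num_of_"):
                law = INT_UNIFORM
            elif name in inhibitory:
                law = RECIPROCAL
            else:
                law = UNIFORM
            entries.append(RangeEntry(name, float(lo), float(hi), law))
    return ParameterRanges(topology, entries)
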