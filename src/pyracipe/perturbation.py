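"""In-silico perturbations applied to a circuit before ensemble generation.

A perturbation transforms (topology, ranges) and is applied to the whole
ensemble: knockout pins a gene's production range to [0, 0] (its level
decays to zero, so its outgoing regulations sit at the unregulated
shifted-Hill value of 1); over-expression / knockdown scale the
production range by a factor; link removal deletes an edge and its three
kinetic parameters.  Threshold ranges are *not* re-estimated, so a
perturbed ensemble run with the same master seed shares every untouched
parameter with the reference ensemble (paired design).
"""

from __future__ import annotations

from dataclasses import dataclass

from .randomization import ParameterRanges, RangeEntry, canonical_names
from .topology import CircuitTopology, TopologyError

__all__ = ["PerturbationSpec", "apply_perturbation", "apply_perturbations"]

_KINDS = ("knockout", "overexpress", "knockdown", "remove_link")
_DEFAULT_FACTOR = {"overexpress": 10.0, "knockdown": 0.1}


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation: kind, target gene or (source, target) edge, and a
    positive production-scaling factor for over/under-expression."""

    kind: str
    target: str | tuple[str, str]
    factor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "remove_link":
            if not (isinstance(self.target, tuple) and len(self.target) == 2):
                raise ValueError("remove_link target must be (source, target)")
        elif not isinstance(self.target, str):
            raise ValueError(f"{self.kind} target must be a gene name")
        if self.factor is None and self.kind in _DEFAULT_FACTOR:
            object.__setattr__(self, "factor", _DEFAULT_FACTOR[self.kind])
        if self.factor is not None and self.factor <= 0:
            raise ValueError("factor must be > 0")


def apply_perturbation(
    topology: CircuitTopology,
    ranges: ParameterRanges,
    spec: PerturbationSpec,
) -> tuple[CircuitTopology, ParameterRanges]:
    """Return the perturbed (topology, ranges) pair.

    All ranges other than the targeted one — in particular previously
    estimated threshold ranges — are left untouched.
    """
    if spec.kind == "knockout":
        gene = _check_gene(topology, spec.target)
        return topology, ranges.with_entry(
            f"Prod_of_{gene}", minimum=0.0, maximum=0.0
        )
    if spec.kind in ("overexpress", "knockdown"):
        gene = _check_gene(topology, spec.target)
        entry = ranges[f"Prod_of_{gene}"]
        return topology, ranges.with_entry(
            f"Prod_of_{gene}",
            minimum=entry.minimum * spec.factor,
            maximum=entry.maximum * spec.factor,
        )
    # remove_link
    src, tgt = spec.target
    edge = topology.find_edge(src, tgt)
    remaining = tuple(e for e in topology.edges if e != edge)
    if not remaining:
        raise TopologyError("removing the last edge would empty the circuit")
    new_topo = CircuitTopology(remaining)
    dropped = {f"{p}_of_{src}To{tgt}" for p in ("Trd", "Num", "Fld")}
    by_name = {e.name: e for e in ranges.entries if e.name not in dropped}
    new_entries = [by_name[name] for name in canonical_names(new_topo)]
    return new_topo, ParameterRanges(new_topo, new_entries)


def apply_perturbations(
    topology: CircuitTopology,
    ranges: ParameterRanges,
    specs,
) -> tuple[CircuitTopology, ParameterRanges]:
    """Compose perturbations left to right."""
    for spec in specs:
        topology, ranges = apply_perturbation(topology, ranges, spec)
    return topology, ranges


def _check_gene(topology: CircuitTopology, gene: str) -> str:
    topology.gene_index(gene)  # raises TopologyError if unknown
    return gene
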