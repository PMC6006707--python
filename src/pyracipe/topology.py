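"""Circuit topologies: typed regulatory edge lists.

A circuit is described entirely by its regulatory links.  Each link is a
directed edge ``source -> target`` annotated as transcriptional activation
(type 1) or inhibition (type 2).  The gene list is derived from the edges,
in first-appearance order, so an edge list is the only required input.

The on-disk format (``.topo``) is a whitespace-delimited table with one
edge per line and an optional ``Source Target Type`` header::

    Source Target Type
    A      B      2
    B      A      2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

ACTIVATION = 1
INHIBITION = 2

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "RegEdge",
    "CircuitTopology",
    "TopologyError",
    "parse_topo",
    "load_topo",
    "serialize_topo",
    "write_topo",
    "toggle_switch",
    "generate_cts",
]


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


@dataclass(frozen=True)
class RegEdge:
    """One directed regulatory link.

    ``kind`` is 1 for activation, 2 for inhibition.
    """

    source: str
    target: str
    kind: int

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise TopologyError("edge endpoints must be non-empty gene names")
        if self.kind not in (ACTIVATION, INHIBITION):
            raise TopologyError(
                f"edge {self.source}->{self.target}: unknown regulation type "
                f"{self.kind!r} (expected 1=activation or 2=inhibition)"
            )

    @property
    def is_inhibition(self) -> bool:
        return self.kind == INHIBITION


@dataclass(frozen=True)
class CircuitTopology:
    """A gene circuit: ordered gene names plus typed directed edges.

    Genes are exactly the names appearing in the edges, ordered by first
    appearance; duplicate (source, target) pairs are rejected.
    """

    edges: tuple[RegEdge, ...]
    genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.edges:
            raise TopologyError("empty circuit: at least one edge is required")
        derived: list[str] = []
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise TopologyError(f"duplicate edge {e.source} -> {e.target}")
            seen_pairs.add(pair)
            for g in pair:
                if g not in derived:
                    derived.append(g)
        if self.genes:
            if tuple(self.genes) != tuple(derived):
                raise TopologyError(
                    "gene list must equal the first-appearance order of edge "
                    f"endpoints; expected {tuple(derived)}, got {tuple(self.genes)}"
                )
        else:
            object.__setattr__(self, "genes", tuple(derived))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_index(self, name: str) -> int:
        try:
            return self.genes.index(name)
        except ValueError:
            raise TopologyError(f"unknown gene {name!r}") from None

    def in_edges(self, target: str) -> list[RegEdge]:
        return [e for e in self.edges if e.target == target]

    def out_edges(self, source: str) -> list[RegEdge]:
        return [e for e in self.edges if e.source == source]

    def find_edge(self, source: str, target: str) -> RegEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise TopologyError(f"no edge {source} -> {target} in circuit")


_HEADER = ("source", "target", "type")


def parse_topo(text: str) -> CircuitTopology:
    """Parse the content of a ``.topo`` file.

    Any run of spaces/tabs delimits fields; blank lines are ignored; a
    literal ``Source Target Type`` header (case-insensitive) is skipped.
    """
    edges: list[RegEdge] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if tuple(f.lower() for f in fields) == _HEADER:
            continue
        if len(fields) != 3:
            raise TopologyError(
                f"line {lineno}: expected 3 whitespace-delimited fields "
                f"(Source Target Type), got {len(fields)}: {line!r}"
            )
        src, tgt, kind_s = fields
        try:
            kind = int(kind_s)
        except ValueError:
            raise TopologyError(
                f"line {lineno}: regulation type {kind_s!r} is not an integer"
            ) from None
        if kind not in (ACTIVATION, INHIBITION):
            raise TopologyError(
                f"line {lineno}: unknown regulation type {kind} "
                "(1=activation, 2=inhibition)"
            )
        edges.append(RegEdge(src, tgt, kind))
    if not edges:
        raise TopologyError("empty circuit: no edges found")
    return CircuitTopology(tuple(edges))


def load_topo(path) -> CircuitTopology:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_topo(fh.read())


def serialize_topo(topology: CircuitTopology, header: bool = True) -> str:
    lines = ["Source\tTarget\tType"] if header else []
    for e in topology.edges:
        lines.append(f"{e.source}\t{e.target}\t{e.kind}")
    return "\n".join(lines) + "\n"


def write_topo(topology: CircuitTopology, path, header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_topo(topology, header=header))


def toggle_switch(gene_a: str = "A", gene_b: str = "B") -> CircuitTopology:
    """The two-gene mutual-inhibition motif."""
    return CircuitTopology(
        (RegEdge(gene_a, gene_b, INHIBITION), RegEdge(gene_b, gene_a, INHIBITION))
    )


def generate_cts(variant: str, n_motifs: int) -> CircuitTopology:
    """Build a chain of coupled toggle switches (CTS-I or CTS-II).

    ``n_motifs`` toggle-switch motifs (Ai, Bi, mutual inhibition) are
    coupled by activations among consecutive same-side genes.  Variant
    "I" uses unidirectional activations running in opposite directions
    along the two sides -- Ai -> Ai+1 and Bi+1 -> Bi -- so the A chain
    propagates its state forward and the B chain backward; the robust
    expression patterns of the circuit are then the cascade states with
    an A-dominant prefix and a B-dominant suffix, and the two chain
    roots (A1 and the last B gene) are the circuit's most critical
    genes.  Variant "II" couples consecutive motifs by mutual
    activations on both sides.
    """
    variant = str(variant).upper()
    if variant not in ("I", "II"):
        raise TopologyError(f"unknown CTS variant {variant!r} (expected 'I' or 'II')")
    if n_motifs < 1:
        raise TopologyError("n_motifs must be >= 1")
    edges: list[RegEdge] = []
    for i in range(1, n_motifs + 1):
        edges.append(RegEdge(f"A{i}", f"B{i}", INHIBITION))
        edges.append(RegEdge(f"B{i}", f"A{i}", INHIBITION))
    for i in range(1, n_motifs):
        if variant == "I":
            edges.append(RegEdge(f"A{i}", f"A{i + 1}", ACTIVATION))
            edges.append(RegEdge(f"B{i + 1}", f"B{i}", ACTIVATION))
        else:
            for side in ("A", "B"):
                edges.append(RegEdge(f"{side}{i}", f"{side}{i + 1}", ACTIVATION))
                edges.append(RegEdge(f"{side}{i + 1}", f"{side}{i}", ACTIVATION))
    return CircuitTopology(tuple(edges))
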