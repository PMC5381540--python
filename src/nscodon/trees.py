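"""Three-taxon trees with explicit root placement.

For nonstationary processes the direction of time matters and is set by the
root.  Two topologies are supported:

* ``node_rooted`` — the root has degree three, one edge to each leaf.  This is
  the only topology on which the general nonstationary model is identifiable,
  so it is the only one accepted for fitting.
* ``edge_rooted`` — the root has degree two: one edge to an outgroup leaf and
  one to an internal node carrying the two ingroup leaves.  Used for
  simulation only.

Newick conventions: ``(A,B,C);`` is the node-rooted triad; ``(A,(B,C));`` is
the edge-rooted triad with the root on A's stem.  Edges are keyed by their
child node label; the internal node of the edge-rooted tree is labelled
``"internal"`` unless named in the newick string.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from Bio import Phylo

from .models import CodonFreqs, EdgeProcess

ROOT = "root"
INTERNAL = "internal"


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class Topology:
    """A rooted three-taxon topology as directed parent->child edges."""

    kind: str  # node_rooted | edge_rooted
    taxa: tuple[str, str, str]
    edges: tuple[tuple[str, str], ...]
    root: str = ROOT

    def __post_init__(self) -> None:
        if self.kind not in ("node_rooted", "edge_rooted"):
            raise TreeError(f"unknown topology kind {self.kind!r}")
        if len(set(self.taxa)) != 3:
            raise TreeError("exactly three distinct taxa required")
        n_edges = 3 if self.kind == "node_rooted" else 4
        if len(self.edges) != n_edges:
            raise TreeError(f"{self.kind} triad needs {n_edges} edges")

    @classmethod
    def node_rooted(cls, taxa: tuple[str, str, str] | list[str]) -> "Topology":
        taxa = tuple(taxa)
        return cls(
            kind="node_rooted",
            taxa=taxa,
            edges=tuple((ROOT, t) for t in taxa),
        )

    @classmethod
    def edge_rooted(
        cls, outgroup: str, ingroup: tuple[str, str] | list[str],
        internal: str = INTERNAL,
    ) -> "Topology":
        ingroup = tuple(ingroup)
        return cls(
            kind="edge_rooted",
            taxa=(outgroup,) + ingroup,
            edges=(
                (ROOT, outgroup),
                (ROOT, internal),
                (internal, ingroup[0]),
                (internal, ingroup[1]),
            ),
        )

    @property
    def parent(self) -> dict[str, str]:
        return {child: par for par, child in self.edges}

    def path_to_root(self, node: str) -> list[tuple[str, str]]:
        """Edges on the root->node path, in root-to-node order."""
        parent = self.parent
        if node != self.root and node not in parent:
            raise TreeError(f"unknown node {node!r}")
        path: list[tuple[str, str]] = []
        while node != self.root:
            par = parent[node]
            path.append((par, node))
            node = par
        return list(reversed(path))

    def path_between(self, taxon1: str, taxon2: str) -> list[tuple[str, str]]:
        """Edges on the (undirected) path between two leaves."""
        p1 = self.path_to_root(taxon1)
        p2 = self.path_to_root(taxon2)
        shared = 0
        while shared < min(len(p1), len(p2)) and p1[shared] == p2[shared]:
            shared += 1
        return p1[shared:] + p2[shared:]


def parse_newick(newick: str) -> Topology:
    """Read a three-taxon topology from a newick string or one-tree file text."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    root = tree.root
    kids = root.clades
    leaves = [t.name for t in tree.get_terminals()]
    if len(leaves) != 3 or any(n is None for n in leaves):
        raise TreeError("expected a three-taxon tree with named leaves")
    if len(kids) == 3:
        return Topology.node_rooted(tuple(leaves))
    if len(kids) == 2:
        sub = [k for k in kids if not k.is_terminal()]
        out = [k for k in kids if k.is_terminal()]
        if len(sub) != 1 or len(out) != 1:
            raise TreeError("edge-rooted triad must be (outgroup,(in1,in2))")
        ingroup = tuple(c.name for c in sub[0].clades)
        if len(ingroup) != 2:
            raise TreeError("edge-rooted triad must have two ingroup leaves")
        internal = sub[0].name or INTERNAL
        return Topology.edge_rooted(out[0].name, ingroup, internal=internal)
    raise TreeError("root must have degree 2 or 3")


def to_newick(top: Topology) -> str:
    if top.kind == "node_rooted":
        return "({},{},{});".format(*top.taxa)
    children: dict[str, list[str]] = {}
    for par, child in top.edges:
        children.setdefault(par, []).append(child)
    out = [c for c in children[top.root] if c not in children][0]
    internal = [c for c in children[top.root] if c in children][0]
    a, b = children[internal]
    return f"({out},({a},{b}));"


@dataclass(frozen=True)
class TreeModel:
    """A topology with a root codon distribution and a process per edge."""

    topology: Topology
    root_freqs: CodonFreqs
    edge_processes: dict[str, EdgeProcess]  # keyed by child node
    sharing: str = "per-edge"

    def __post_init__(self) -> None:
        children = {child for _, child in self.topology.edges}
        if set(self.edge_processes) != children:
            raise TreeError("every edge needs a process (keyed by child node)")

    @property
    def family(self) -> str:
        return next(iter(self.edge_processes.values())).family


def node_distribution(model: TreeModel, node: str) -> CodonFreqs:
    """Codon distribution at a node: the root distribution propagated forward
    through the transition matrices on the root->node path."""
    pi = model.root_freqs.pi
    for _, child in model.topology.path_to_root(node):
        pi = pi @ model.edge_processes[child].P
    pi = np.clip(pi, 0.0, None)
    return CodonFreqs(pi / pi.sum())


@dataclass(frozen=True)
class FittableVerdict:
    ok: bool
    reason: str


def validate_fittable(
    family: str, topology: Topology, intent: str = "fit"
) -> FittableVerdict:
    """Whether a model family may be fitted (or simulated) on a topology.

    The nonstationary GNC model is only consistently estimable on a
    node-rooted tree with at least three taxa; edge-rooted GNC is allowed for
    simulation only.  Time-reversible families are insensitive to root
    placement and always allowed.
    """
    if intent not in ("fit", "simulate"):
        raise TreeError(f"unknown intent {intent!r}")
    if intent == "simulate":
        return FittableVerdict(True, "simulation permitted on any rooted topology")
    if family == "GNC" and topology.kind == "edge_rooted":
        return FittableVerdict(
            False,
            "GNC is not identifiable on an edge-rooted topology; "
            "fit requires a node-rooted tree with three taxa",
        )
    return FittableVerdict(True, f"{family} fittable on {topology.kind} triad")
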