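"""Rooted, fixed-topology species tree with node ages and fossil calibrations.

The tree topology is fixed for the whole analysis; only the ages of the
internal nodes move.  Tips are contemporaneous (age 0), every internal node
is strictly older than both of its children, and ages are expressed in an
abstract time unit (by convention 100 Myr per unit).  The depth-first
left-to-right leaf order is frozen at parse time: it defines the row layout
of every encoded alignment and the key layout of the subtree pattern
compression, so it must never change during a run.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import dendropy

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "CalibrationSpec",
    "parse_newick",
    "write_newick",
    "parse_calibration_config",
    "resolve_calibrations",
    "validate_ages",
]


@dataclass
class TreeNode:
    id: int
    parent: int | None = None
    children: tuple[int, ...] = ()
    age: float = 0.0
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Indexed rooted binary tree.

    Nodes are stored in a flat list addressed by integer id; ``leaf_order``
    is the canonical depth-first ordering of leaf ids.
    """

    def __init__(self, nodes: list[TreeNode], root_id: int):
        self.nodes = nodes
        self.root_id = root_id
        self.leaf_order: list[int] = [
            nid for nid in self._depth_first(root_id) if nodes[nid].is_leaf
        ]
        self.n_leaves = len(self.leaf_order)
        # leaf label -> position in leaf_order (the alignment row index)
        self.leaf_index: dict[str, int] = {
            nodes[nid].label: i for i, nid in enumerate(self.leaf_order)
        }
        if len(self.leaf_index) != self.n_leaves:
            raise ValueError("duplicate leaf labels in tree")
        self._leaves_below: dict[int, frozenset[str]] | None = None

    # -- traversals ---------------------------------------------------------

    def _depth_first(self, start: int):
        stack = [start]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def preorder(self) -> list[int]:
        return list(self._depth_first(self.root_id))

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    def internal_ids(self) -> list[int]:
        return [nid for nid in self.preorder() if not self.nodes[nid].is_leaf]

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaves_below(self, nid: int) -> frozenset[str]:
        """Set of leaf labels in the subtree rooted at ``nid`` (cached)."""
        if self._leaves_below is None:
            self._leaves_below = {}
            for node_id in self.postorder():
                node = self.nodes[node_id]
                if node.is_leaf:
                    self._leaves_below[node_id] = frozenset([node.label])
                else:
                    acc: frozenset[str] = frozenset()
                    for c in node.children:
                        acc |= self._leaves_below[c]
                    self._leaves_below[node_id] = acc
        return self._leaves_below[nid]

    def mrca(self, labels: set[str]) -> int:
        """Most recent common ancestor of a set of leaf labels.

        Walks up from one member leaf until the subtree covers the clade.
        """
        missing = labels - set(self.leaf_index)
        if missing:
            raise KeyError(f"unknown leaf labels: {sorted(missing)}")
        start = next(iter(labels))
        nid = self.leaf_order[self.leaf_index[start]]
        while not labels <= self.leaves_below(nid):
            nid = self.nodes[nid].parent
        return nid

    def copy_ages(self) -> dict[int, float]:
        return {n.id: n.age for n in self.nodes}

    def set_ages(self, ages: dict[int, float]) -> None:
        for nid, age in ages.items():
            self.nodes[nid].age = age


@dataclass(frozen=True)
class CalibrationSpec:
    """Soft-uniform fossil calibration on the MRCA of ``clade``.

    A fraction ``1 - 2*tail_prob`` of the prior mass is uniform on
    ``[t_lower, t_upper]``; each side carries ``tail_prob`` in an
    exponentially decaying tail, continuous at the bounds.
    """

    clade: frozenset[str]
    t_lower: float
    t_upper: float
    tail_prob: float = 0.025
    kind: str = "soft_uniform"

    def __post_init__(self):
        if not (0 <= self.t_lower < self.t_upper):
            raise ValueError("require 0 <= t_lower < t_upper")
        if not (0 < self.tail_prob < 0.5):
            raise ValueError("tail_prob must lie in (0, 0.5)")
        if self.kind != "soft_uniform":
            raise ValueError(f"unsupported calibration kind {self.kind!r}")


# -- newick I/O -------------------------------------------------------------


def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted binary newick string into a :class:`SpeciesTree`.

    Branch lengths, when present, only seed the initial ages: each node's
    age is set to its height (the maximum path length down to a leaf), so
    tips sit at 0 even if the input is not perfectly ultrametric.  Without
    branch lengths, ages are spread uniformly by topological height with
    the root at 1.0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels: {exc}") from None
    nodes: list[TreeNode] = []
    id_of: dict = {}

    has_lengths = any(
        e.length is not None for e in dtree.preorder_edge_iter() if e.head_node.parent_node
    )

    for dnode in dtree.postorder_node_iter():
        kids = dnode.child_nodes()
        if len(kids) not in (0, 2):
            raise ValueError(
                f"tree is not strictly binary: node with {len(kids)} children"
            )
        nid = len(nodes)
        id_of[dnode] = nid
        if kids:
            node = TreeNode(id=nid, children=tuple(id_of[k] for k in kids))
        else:
            label = dnode.taxon.label if dnode.taxon else None
            if label is None:
                raise ValueError("leaf without a label")
            node = TreeNode(id=nid, label=label)
        nodes.append(node)

    for dnode in dtree.preorder_node_iter():
        for k in dnode.child_nodes():
            nodes[id_of[k]].parent = id_of[dnode]

    root_id = id_of[dtree.seed_node]
    labels = [n.label for n in nodes if n.is_leaf]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")

    # seed ages from heights
    for dnode in dtree.postorder_node_iter():
        n = nodes[id_of[dnode]]
        if n.is_leaf:
            n.age = 0.0
        elif has_lengths:
            n.age = max(
                nodes[id_of[k]].age + (k.edge.length or 0.0)
                for k in dnode.child_nodes()
            )
        else:
            n.age = 1.0 + max(nodes[c].age for c in n.children)
    if not has_lengths:
        root_age = nodes[root_id].age
        for n in nodes:
            n.age /= root_age

    return SpeciesTree(nodes, root_id)


def write_newick(tree: SpeciesTree, with_ages: bool = True) -> str:
    """Serialize; branch lengths are parent_age - child_age when requested."""

    def rec(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
        if with_ages and node.parent is not None:
            s += f":{tree.nodes[node.parent].age - node.age:.12g}"
        return s

    return rec(tree.root_id) + ";"


# -- calibration config -----------------------------------------------------

_KEY_RE = re.compile(r"^\s*([A-Za-z_]+)\s*=\s*(.+?)\s*$")


def parse_calibration_config(text: str) -> list[CalibrationSpec]:
    """Parse plain-text ``[calibration]`` blocks.

    Each block holds ``clade`` (comma-separated leaf labels), ``min``,
    ``max`` and optionally ``tail`` and ``type``::

        [calibration]
        clade = A,B
        type = soft_uniform
        min = 0.5
        max = 1.0
        tail = 0.025
    """
    specs: list[CalibrationSpec] = []
    block: dict[str, str] | None = None

    def flush(b: dict[str, str] | None):
        if b is None:
            return
        try:
            clade = frozenset(s.strip() for s in b["clade"].split(",") if s.strip())
            spec = CalibrationSpec(
                clade=clade,
                t_lower=float(b["min"]),
                t_upper=float(b["max"]),
                tail_prob=float(b.get("tail", 0.025)),
                kind=b.get("type", "soft_uniform"),
            )
        except KeyError as exc:
            raise ValueError(f"calibration block missing key {exc}") from None
        specs.append(spec)

    for raw in io.StringIO(text):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "[calibration]":
            flush(block)
            block = {}
            continue
        m = _KEY_RE.match(line)
        if m and block is not None:
            block[m.group(1).lower()] = m.group(2)
        else:
            raise ValueError(f"cannot parse calibration line: {raw.strip()!r}")
    flush(block)
    return specs


def resolve_calibrations(
    tree: SpeciesTree, specs: list[CalibrationSpec]
) -> dict[int, CalibrationSpec]:
    """Map each calibration to the id of its clade's MRCA.

    The root must carry a calibration: the birth-death-sampling age density
    is conditional on the root age, which would otherwise be unanchored.
    """
    out: dict[int, CalibrationSpec] = {}
    for spec in specs:
        nid = tree.mrca(set(spec.clade))
        if tree.nodes[nid].is_leaf:
            raise ValueError(f"clade {sorted(spec.clade)} resolves to a leaf")
        if nid in out:
            raise ValueError(
                f"two calibrations resolve to the same node (clade {sorted(spec.clade)})"
            )
        out[nid] = spec
    if tree.root_id not in out:
        raise ValueError("a calibration on the root is required")
    return out


def validate_ages(tree: SpeciesTree) -> list[str]:
    """Return human-readable violations of the age ordering contract."""
    problems: list[str] = []
    for node in tree.nodes:
        if node.is_leaf:
            if node.age != 0.0:
                problems.append(f"leaf {node.label!r} has nonzero age {node.age}")
        else:
            for c in node.children:
                if not tree.nodes[c].age < node.age:
                    problems.append(
                        f"node {node.id} (age {node.age}) not older than child "
                        f"{c} (age {tree.nodes[c].age})"
                    )
    return problems
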