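"""Decision hierarchy: node tree, validation, and pairwise-comparison enumeration.

A hierarchy is a three-level tree: one root (the decision goal), a set of
level-2 categories, and optional level-3 elements under each category.
Every sibling set with at least two members forms a *comparison block*;
within each block a respondent judges all unordered item pairs, so a block
of ``k`` items contributes ``k*(k-1)/2`` pairwise comparisons.

Level-2 categories without children are legal: they participate in the
level-2 block but induce no level-3 comparisons and carry no global leaf
weight of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping

import yaml


class HierarchyError(ValueError):
    """Structural problem in a hierarchy definition."""


@dataclass(frozen=True)
class HierarchyNode:
    """One node of the decision tree.

    Parameters
    ----------
    id : str
        Short stable slug used as key in data files (e.g. ``"medical_issues"``).
    label : str
        Human-readable display text.
    level : int
        Depth in the tree; the root is level 1.
    children : tuple of str
        Ordered ids of the node's children (empty for leaves).
    """

    id: str
    label: str
    level: int
    children: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComparisonBlock:
    """A sibling set to be compared pairwise (block id = parent node id)."""

    parent_id: str
    item_ids: tuple[str, ...]

    @property
    def block_id(self) -> str:
        return self.parent_id

    @property
    def size(self) -> int:
        return len(self.item_ids)

    def n_pairs(self) -> int:
        k = self.size
        return k * (k - 1) // 2


class Hierarchy:
    """The full decision tree.

    Nodes are stored in insertion order; children order is the order given
    in each node's ``children`` tuple, which also fixes item order in
    comparison blocks and output tables.
    """

    def __init__(self, root: str, nodes: Iterable[HierarchyNode]):
        self.root = root
        self._node_list = list(nodes)
        self.nodes: dict[str, HierarchyNode] = {}
        self._duplicate_ids: list[str] = []
        for node in self._node_list:
            if node.id in self.nodes:
                self._duplicate_ids.append(node.id)
            else:
                self.nodes[node.id] = node

    # -- structure ---------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hierarchy):
            return NotImplemented
        return self.root == other.root and self._node_list == other._node_list

    def node(self, node_id: str) -> HierarchyNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise HierarchyError(f"unknown node id {node_id!r}") from None

    def children(self, node_id: str) -> tuple[HierarchyNode, ...]:
        return tuple(self.node(cid) for cid in self.node(node_id).children)

    def parent_of(self, node_id: str) -> str | None:
        for node in self._node_list:
            if node_id in node.children:
                return node.id
        return None

    def walk(self) -> Iterator[HierarchyNode]:
        """Depth-first traversal from the root, children in declared order."""
        stack = [self.root]
        while stack:
            node = self.node(stack.pop(0))
            yield node
            stack = list(node.children) + stack

    def level_nodes(self, level: int) -> tuple[HierarchyNode, ...]:
        return tuple(n for n in self.walk() if n.level == level)

    def leaves(self) -> tuple[HierarchyNode, ...]:
        """Level-3 leaf nodes (children of level-2 categories), in tree order."""
        return tuple(n for n in self.walk() if n.level == 3)

    def blocks(self) -> tuple[ComparisonBlock, ...]:
        """Comparison blocks in tree order; only sibling sets with >= 2 items."""
        out = []
        for node in self.walk():
            if len(node.children) >= 2:
                out.append(ComparisonBlock(node.id, node.children))
        return tuple(out)

    def block(self, block_id: str) -> ComparisonBlock:
        for b in self.blocks():
            if b.block_id == block_id:
                return b
        raise HierarchyError(f"no comparison block with id {block_id!r}")

    # -- config round-trip -------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "Hierarchy":
        """Build from a mapping with keys ``root``, ``labels``, ``children``.

        ``children`` maps parent id -> ordered list of child ids; ids absent
        from ``children`` are leaves. ``labels`` maps id -> display text and
        may be partial (the id doubles as label).
        """
        root = config["root"]
        children: Mapping[str, list] = config.get("children", {})
        labels: Mapping[str, str] = config.get("labels", {})

        nodes: list[HierarchyNode] = []
        seen: set[str] = set()

        def add(node_id: str, level: int) -> None:
            kids = tuple(children.get(node_id, ()))
            nodes.append(
                HierarchyNode(
                    id=node_id,
                    label=str(labels.get(node_id, node_id)),
                    level=level,
                    children=kids,
                )
            )
            if node_id in seen:
                return  # duplicate surfaces through validate_hierarchy
            seen.add(node_id)
            for kid in kids:
                add(kid, level + 1)

        add(root, 1)
        return cls(root, nodes)

    @classmethod
    def from_yaml(cls, path) -> "Hierarchy":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def to_config(self) -> dict:
        return {
            "root": self.root,
            "labels": {n.id: n.label for n in self.walk()},
            "children": {
                n.id: list(n.children) for n in self.walk() if n.children
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


def build_default_hierarchy() -> Hierarchy:
    """The packaged default tree for rare-disease health information.

    One goal, four level-2 categories (medical issues, research, social help
    offers, current events) and nine level-3 elements; ``current_events`` has
    no sub-elements.
    """
    return Hierarchy.from_config(
        {
            "root": "health_information",
            "labels": {
                "health_information": "Importance of health information on rare diseases",
                "medical_issues": "Medical issues",
                "diagnosis": "Diagnosis",
                "therapy": "Therapy",
                "general_disease_pattern": "General disease pattern",
                "research": "Research",
                "current_studies": "Current studies",
                "study_results": "Study results",
                "registers": "Registers",
                "social_help_offers": "Social help offers",
                "psychosocial_counseling": "Psychosocial counseling",
                "self_help_counseling": "Self-help counseling",
                "sociolegal_advice": "Sociolegal advice",
                "current_events": "Current events",
            },
            "children": {
                "health_information": [
                    "medical_issues",
                    "research",
                    "social_help_offers",
                    "current_events",
                ],
                "medical_issues": ["diagnosis", "therapy", "general_disease_pattern"],
                "research": ["current_studies", "study_results", "registers"],
                "social_help_offers": [
                    "psychosocial_counseling",
                    "self_help_counseling",
                    "sociolegal_advice",
                ],
            },
        }
    )


def validate_hierarchy(h: Hierarchy) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations: list[str] = []
    for dup in h._duplicate_ids:
        violations.append(f"duplicate node id {dup!r}")

    if h.root not in h.nodes:
        violations.append(f"root node {h.root!r} is not defined")
        return violations
    root_node = h.nodes[h.root]
    if root_node.level != 1:
        violations.append(f"root node {h.root!r} has level {root_node.level}, expected 1")

    reachable: set[str] = set()
    stack = [h.root]
    while stack:
        nid = stack.pop()
        if nid in reachable:
            continue
        reachable.add(nid)
        node = h.nodes.get(nid)
        if node is None:
            violations.append(f"child id {nid!r} has no node definition")
            continue
        for cid in node.children:
            child = h.nodes.get(cid)
            if child is not None and child.level != node.level + 1:
                violations.append(
                    f"node {cid!r} has level {child.level}, expected "
                    f"{node.level + 1} (child of {nid!r})"
                )
            stack.append(cid)

    for node in h._node_list:
        if node.id not in reachable:
            violations.append(f"node {node.id!r} is not reachable from the root")
        if node.level not in (1, 2, 3):
            violations.append(f"node {node.id!r} has unsupported level {node.level}")
        if node.level == 3 and node.children:
            violations.append(f"level-3 node {node.id!r} must not have children")
    return violations


def enumerate_comparisons(h: Hierarchy) -> list[tuple[str, str, str]]:
    """All pairwise-comparison tasks induced by the hierarchy.

    Returns ``(block_id, item_a, item_b)`` triples, blocks in tree order and
    pairs in lexicographic order within each block. Raises
    :class:`HierarchyError` if the hierarchy is structurally invalid.
    """
    problems = validate_hierarchy(h)
    if problems:
        raise HierarchyError("; ".join(problems))
    out: list[tuple[str, str, str]] = []
    for block in h.blocks():
        for a, b in combinations(sorted(block.item_ids), 2):
            out.append((block.block_id, a, b))
    return out
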