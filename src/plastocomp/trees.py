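"""Minimal rooted-tree container with branch lengths.

Used by the evolver and the codon-model likelihood, which need a
postorder node list and a mutable branch-length vector.  Newick text is
parsed directly; conversion helpers accept scikit-bio TreeNode output
(from neighbor joining).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    name: str
    length: float = 0.0  # branch above this node
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    index: int = -1  # postorder index

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree; ``nodes`` is in postorder with the root last."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: list[TreeNode] = []
        self._assign(root)

    def _assign(self, node: TreeNode) -> None:
        for ch in node.children:
            ch.parent = node
            self._assign(ch)
        node.index = len(self.nodes)
        self.nodes.append(node)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def branch_lengths(self) -> list[float]:
        return [n.length for n in self.nodes[:-1]]  # root has no branch

    def set_branch_lengths(self, lengths) -> None:
        for n, b in zip(self.nodes[:-1], lengths):
            n.length = float(b)

    def total_length(self) -> float:
        return sum(self.branch_lengths())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + (
                    node.name or ""
                )
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a newick string with branch lengths (no quoted labels)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0
    counter = [0]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode(name="")
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {text[pos]!r} at {pos}")
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        node.name = text[start:pos].strip()
        if not node.name and not node.children:
            raise ValueError(f"unnamed leaf at position {pos}")
        if not node.name:
            counter[0] += 1
            node.name = f"__internal_{counter[0]}"
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if text[pos] != ";":
        raise ValueError(f"trailing characters after tree at position {pos}")
    return Tree(root)
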