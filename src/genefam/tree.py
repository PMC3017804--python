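"""Minimal phylogenetic tree structure with Newick round-tripping.

Trees are binary except possibly at the root.  Bootstrap supports live on
internal nodes (conventionally rendered as internal node labels), branch
lengths on the edge above each node.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class NewickError(ValueError):
    pass


@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> set[str]:
        return {leaf.label for leaf in self.leaves()}

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set.

        Canonicalized against the full leaf set so the encoding does not
        depend on rooting.
        """
        all_leaves = frozenset(self.leaf_labels())
        parts: set[frozenset[str]] = set()
        for node in self.preorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_labels())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return parts


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    if a.leaf_labels() != b.leaf_labels():
        raise ValueError("trees have different leaf sets")
    pa, pb = a.bipartitions(), b.bipartitions()
    return len(pa ^ pb)


def reroot_at_edge(root: TreeNode, target: TreeNode) -> TreeNode:
    """New root on the edge above ``target``; supports stay attached to
    the bipartition they measure (they shift one step along the reversed
    path, since a node's support annotates its parent edge)."""
    parent: dict[int, TreeNode] = {}
    for node in root.preorder():
        for child in node.children:
            parent[id(child)] = node

    if id(target) not in parent:
        return root

    def rehang(node: TreeNode, coming_from: TreeNode) -> TreeNode:
        """Rebuild ``node`` as seen from ``coming_from`` (its new parent)."""
        kept = [c for c in node.children if c is not coming_from]
        up = parent.get(id(node))
        new_node = TreeNode(label=node.label,
                            length=coming_from.length,
                            support=coming_from.support,
                            children=list(kept))
        if up is not None:
            new_node.children.append(rehang(up, node))
        elif len(kept) == 1 and not kept[0].is_leaf:
            # old binary root vanishes: splice its remaining child up,
            # merging the two half-edges
            only = kept[0]
            new_node.children = list(only.children)
            new_node.length = (new_node.length or 0.0) + (only.length or 0.0)
            if new_node.support is None:
                new_node.support = only.support
        return new_node

    upper = rehang(parent[id(target)], target)
    return TreeNode(children=[target, upper])


def reroot_balanced_weak(root: TreeNode, max_support: int = 50) -> TreeNode:
    """Reroot on the most balanced weakly supported internal edge.

    Deep splits among anciently diverged groups are resolved arbitrarily
    and carry low bootstrap support; rooting there turns each group into
    a proper clade.  Falls back to the most balanced internal edge when
    every edge is well supported.
    """
    n_total = len(root.leaves())
    candidates = []
    for node in root.preorder():
        if node is root or node.is_leaf:
            continue
        size = len(node.leaves())
        balance = min(size, n_total - size)
        support = node.support if node.support is not None else max_support
        candidates.append((balance, -support, min(node.leaf_labels()), node))
    if not candidates:
        return root
    _, _, _, best = max(candidates, key=lambda c: (c[0], c[1], c[2]))
    return reroot_at_edge(root, best)


def _fmt_length(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_newick(root: TreeNode) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            text = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            text = f"({inner}){label}"
        if node.length is not None:
            text += f":{_fmt_length(node.length)}"
        return text

    return render(root) + ";"


def parse_newick(text: str) -> TreeNode:
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("newick string must end with ';'")
    pos = 0

    def error(msg: str):
        raise NewickError(f"{msg} at position {pos}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if text[pos] != ")":
                error("unbalanced parentheses")
            pos += 1
            label = read_token()
            if label:
                node.support = int(label)
        else:
            node.label = read_token()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            node.length = float(read_token())
        return node

    def read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos]

    root = parse_node()
    if pos != len(text) - 1 or text[pos] != ";":
        error("trailing characters or unbalanced parentheses")
    return root
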