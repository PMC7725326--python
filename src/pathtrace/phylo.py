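"""Rooted species/strain phylogenies.

The tree is purely topological: branch lengths and support values in the
Newick input are parsed and discarded, because the downstream parsimony
reconstruction only uses parent/child relations.  Multifurcations are
retained.  Each node carries a presence/absence ``state`` and an ``event``
label that the reconstruction step fills in.

Pangenomes enter the tree as "virtual genome" leaves: for every block of
strains, one extra leaf is attached as an additional child of the root of
the smallest clade containing all the block's strains.
"""

from __future__ import annotations

import copy
from enum import Enum
from typing import Iterable, Iterator, Mapping

import dendropy

from .errors import MissingDataError, NewickParseError


class State(Enum):
    UNASSIGNED = "UNASSIGNED"
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"


class Event(Enum):
    NONE = "NONE"
    GAIN = "GAIN"
    LOSS = "LOSS"


class TreeNode:
    """A node of a rooted tree: ordered children, optional name, state."""

    __slots__ = ("name", "children", "parent", "state", "event", "id")

    def __init__(self, name: str = ""):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.state: State = State.UNASSIGNED
        self.event: Event = Event.NONE
        self.id: str = name

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r}, children={len(self.children)})"


class PhyloTree:
    """Rooted, possibly multifurcating tree over named genome leaves.

    Node identifiers are stable for a given topology: leaves use their
    names, internal nodes use their Newick label when present and unique,
    otherwise a preorder-generated ``nK`` label.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_ids()
        self.validate()

    # -- construction / bookkeeping -------------------------------------

    def _assign_ids(self) -> None:
        used = {leaf.name for leaf in self.iter_leaves()}
        counter = 0
        for node in self.iter_preorder():
            if node.is_leaf:
                node.id = node.name
            elif node.name and node.name not in used:
                node.id = node.name
                used.add(node.name)
            else:
                counter += 1
                while f"n{counter}" in used:
                    counter += 1
                node.id = f"n{counter}"
                used.add(node.id)

    def validate(self) -> None:
        names = [leaf.name for leaf in self.iter_leaves()]
        if any(not n for n in names):
            raise NewickParseError("tree contains an unnamed leaf")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise NewickParseError(f"duplicate leaf names: {sorted(dupes)}")
        for node in self.iter_preorder():
            for child in node.children:
                if child.parent is not node:
                    raise NewickParseError("inconsistent parent pointers")

    # -- traversal -------------------------------------------------------

    def iter_preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator[TreeNode]:
        # iterative post-order keeps very deep caterpillar trees safe
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def iter_leaves(self) -> Iterator[TreeNode]:
        for node in self.iter_preorder():
            if node.is_leaf:
                yield node

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.iter_leaves()]

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.iter_preorder())

    def node_by_id(self, node_id: str) -> TreeNode:
        for node in self.iter_preorder():
            if node.id == node_id:
                return node
        raise MissingDataError(f"no node with id {node_id!r}")

    def leaves_under(self, node: TreeNode) -> list[str]:
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.append(cur.name)
            else:
                stack.extend(reversed(cur.children))
        return out

    def mrca(self, leaf_names: Iterable[str]) -> TreeNode:
        wanted = set(leaf_names)
        by_name = {leaf.name: leaf for leaf in self.iter_leaves()}
        missing = wanted - set(by_name)
        if missing:
            raise MissingDataError(
                f"leaves not in tree: {sorted(missing)}"
            )
        node: TreeNode = by_name[next(iter(wanted))]
        while not wanted <= set(self.leaves_under(node)):
            assert node.parent is not None
            node = node.parent
        return node

    def copy(self) -> "PhyloTree":
        return PhyloTree(copy.deepcopy(self.root))

    def reset_states(self) -> None:
        for node in self.iter_preorder():
            node.state = State.UNASSIGNED
            node.event = Event.NONE

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            label = _quote_label(node.name)
            if node.is_leaf:
                return label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}"

        return render(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def write_node_table(self, path) -> None:
        """TSV of (child, parent, state, event) rows, preorder."""
        with open(path, "w") as fh:
            fh.write("node\tparent\tstate\tevent\n")
            for node in self.iter_preorder():
                parent = node.parent.id if node.parent else ""
                fh.write(
                    f"{node.id}\t{parent}\t{node.state.value}\t{node.event.value}\n"
                )


def _quote_label(label: str) -> str:
    if not label:
        return ""
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _check_syntax(text: str) -> None:
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string", position=0)
    if not stripped.endswith(";"):
        raise NewickParseError("Newick string must end in ';'",
                               position=len(text))
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", position=pos)
    if depth != 0:
        raise NewickParseError("unbalanced '(' — missing ')'",
                               position=len(text))


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Branch lengths and support values are accepted and discarded; internal
    node labels are preserved.  Duplicate leaf names are an error.
    """
    _check_syntax(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            name = str(dnode.taxon.label)
        else:
            name = str(dnode.label) if dnode.label else ""
        node = TreeNode(name)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def attach_pangenome_leaves(
    tree: PhyloTree,
    blocks: Mapping[str, str],
    png_names: Mapping[str, str] | None = None,
) -> PhyloTree:
    """Return a copy of ``tree`` with one virtual pangenome leaf per block.

    Each block's leaf is added as an extra child of the root of the
    smallest clade containing all the block's member strains.  A block
    with a single member attaches to that leaf's parent.  The virtual
    leaf is named ``png_names[block]`` (default ``"<block>-png"``).
    """
    new_tree = tree.copy()
    existing = set(new_tree.leaf_names)
    members_by_block: dict[str, list[str]] = {}
    for genome, block in blocks.items():
        members_by_block.setdefault(block, []).append(genome)

    for block, members in members_by_block.items():
        name = (png_names or {}).get(block, f"{block}-png")
        if name in existing:
            raise MissingDataError(
                f"virtual leaf name {name!r} collides with an existing leaf"
            )
        missing = [m for m in members if m not in existing]
        if missing:
            raise MissingDataError(
                f"block {block!r} members missing from tree: {sorted(missing)}"
            )
        anchor = new_tree.mrca(members)
        if anchor.is_leaf:  # single-member block: attach to the leaf's parent
            anchor = anchor.parent if anchor.parent is not None else anchor
            if anchor.is_leaf:
                raise MissingDataError(
                    f"cannot attach virtual leaf for block {block!r}: "
                    "tree is a single leaf"
                )
        anchor.add_child(TreeNode(name))
        existing.add(name)

    return PhyloTree(new_tree.root)
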