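"""Naive recursive reference reconstruction, independent of the package's
optimized single-pass traversal.  Written directly from the four assignment
rules; recomputes every subtree tally from scratch at each node."""

from __future__ import annotations


def _leaves(node):
    if not node.children:
        return [node]
    out = []
    for child in node.children:
        out.extend(_leaves(child))
    return out


def _maximal_clades(node, discrete, value):
    """Count maximal clades under (and including) node whose leaves all carry value."""
    states = [discrete[leaf.name] for leaf in _leaves(node)]
    if all(s == value for s in states):
        return 1
    if not node.children:
        return 0
    return sum(_maximal_clades(c, discrete, value) for c in node.children)


def reference_reconstruct(tree, discrete, gain=5, loss=2, mode="leaf-count"):
    """Return ({node_id: 0/1}, [(parent_id, child_id, 'GAIN'|'LOSS')])."""

    def assign(node):
        if not node.children:
            return {node.id: int(discrete[node.name])}
        states = {}
        for child in node.children:
            states.update(assign(child))
        child_vals = [states[c.id] for c in node.children]
        if len(set(child_vals)) == 1:
            states[node.id] = child_vals[0]
            return states
        leaf_vals = [int(discrete[leaf.name]) for leaf in _leaves(node)]
        n_pres = sum(leaf_vals)
        n_abs = len(leaf_vals) - n_pres
        if mode == "leaf-count":
            p, a = n_pres, n_abs
        else:
            p = sum(_maximal_clades(c, discrete, 1) for c in node.children)
            a = sum(_maximal_clades(c, discrete, 0) for c in node.children)
        s2 = sum(
            1
            for c in node.children
            if any(discrete[leaf.name] == 1 for leaf in _leaves(c))
        )
        if p - a > gain and s2 >= 2:
            states[node.id] = 1
        elif a - p > loss:
            states[node.id] = 0
        else:  # fallback: majority of subtree leaves, tie -> absent
            states[node.id] = 1 if n_pres > n_abs else 0
        return states

    states = assign(tree.root)

    def collect_events(node, acc):
        for child in node.children:
            if states[node.id] != states[child.id]:
                kind = "GAIN" if states[child.id] == 1 else "LOSS"
                acc.append((node.id, child.id, kind))
            collect_events(child, acc)
        return acc

    return states, collect_events(tree.root, [])
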