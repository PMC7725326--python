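"""Bottom-up parsimony reconstruction of ancestral pathway presence.

Given a rooted tree whose leaves carry binary pathway states, every
internal node is assigned PRESENT or ABSENT in a single post-order pass,
GeneTrace-style:

  R1  if all children were assigned the same state, the parent inherits it;
  R2  else if (potential gains - losses) > GAIN and presence occurs in at
      least two children subtrees, the parent is PRESENT;
  R3  else if (potential losses - gains) > LOSS, the parent is ABSENT;
  R4  else majority of the subtree's leaves: PRESENT iff strictly more
      present than absent leaves (exact tie -> ABSENT, the conservative
      completion).

"Potential gains/losses" in R2/R3 are counted either as present/absent
leaves of the subtree (``leaf-count``, the default) or as maximal
uniformly present/absent clades below the node (``event-count``, a
Dollo-style reading).  The R4 fallback always reads subtree leaves; with
clade counting this is what lets the GAIN/LOSS thresholds trade a few
independent origins against many leaf-level observations.  In leaf-count
mode the threshold rules are subsumed by the leaf majority, so that mode
is insensitive to the thresholds by construction.
Gain and loss events are the edges whose endpoint states
differ: parent ABSENT -> child PRESENT is a GAIN ("genesis"), parent
PRESENT -> child ABSENT is a LOSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import MissingDataError, ParameterError
from .phylo import Event, PhyloTree, State, TreeNode

DEFAULT_GAIN = 5
DEFAULT_LOSS = 2

MODES = ("leaf-count", "event-count")


@dataclass
class ReconstructionConfig:
    """GAIN/LOSS thresholds and the counting mode for rules R2/R3."""

    gain_threshold: int = DEFAULT_GAIN
    loss_threshold: int = DEFAULT_LOSS
    mode: str = "leaf-count"

    def __post_init__(self) -> None:
        if self.gain_threshold < 0 or self.loss_threshold < 0:
            raise ParameterError("gain/loss thresholds must be >= 0")
        if self.mode not in MODES:
            raise ParameterError(
                f"unknown mode {self.mode!r}; expected one of {MODES}"
            )


@dataclass
class ReconstructionResult:
    """States per node, events per edge, and the root state."""

    states: dict[str, str]
    events: list[tuple[str, str, str]]  # (parent id, child id, GAIN|LOSS)
    root_state: str

    @property
    def n_gains(self) -> int:
        return sum(1 for *_, e in self.events if e == "GAIN")

    @property
    def n_losses(self) -> int:
        return sum(1 for *_, e in self.events if e == "LOSS")


def reconstruct_ancestral(
    tree: PhyloTree,
    discrete: Mapping[str, int],
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Assign presence/absence to every node; label gain/loss edges.

    ``discrete`` must state 0/1 for every leaf of the tree (virtual
    pangenome leaves included — they are ordinary leaves here).  Node
    states are also written onto the tree's nodes.
    """
    config = config or ReconstructionConfig()
    leaf_names = tree.leaf_names
    missing = [name for name in leaf_names if name not in discrete]
    if missing:
        raise MissingDataError(f"leaves missing from profile: {missing}")

    tree.reset_states()
    # per-node tallies filled bottom-up
    n_present: dict[TreeNode, int] = {}
    n_absent: dict[TreeNode, int] = {}
    all_present: dict[TreeNode, bool] = {}
    all_absent: dict[TreeNode, bool] = {}
    p_clades: dict[TreeNode, int] = {}  # maximal uniformly-present clades
    a_clades: dict[TreeNode, int] = {}

    for node in tree.iter_postorder():
        if node.is_leaf:
            s = int(discrete[node.name])
            if s not in (0, 1):
                raise ParameterError(
                    f"leaf {node.name!r}: state must be 0 or 1, got {s}"
                )
            node.state = State.PRESENT if s else State.ABSENT
            n_present[node] = s
            n_absent[node] = 1 - s
            all_present[node] = bool(s)
            all_absent[node] = not s
            p_clades[node] = s
            a_clades[node] = 1 - s
            continue

        kids = node.children
        n_present[node] = sum(n_present[c] for c in kids)
        n_absent[node] = sum(n_absent[c] for c in kids)
        all_present[node] = all(all_present[c] for c in kids)
        all_absent[node] = all(all_absent[c] for c in kids)
        p_clades[node] = 1 if all_present[node] else sum(p_clades[c] for c in kids)
        a_clades[node] = 1 if all_absent[node] else sum(a_clades[c] for c in kids)

        child_states = {c.state for c in kids}
        if len(child_states) == 1:  # R1: uniform children
            node.state = child_states.pop()
            continue

        if config.mode == "leaf-count":
            p, a = n_present[node], n_absent[node]
        else:  # event-count: maximal homogeneous clades below this node
            p = sum(p_clades[c] for c in kids)
            a = sum(a_clades[c] for c in kids)
        s2 = sum(1 for c in kids if n_present[c] >= 1)

        if p - a > config.gain_threshold and s2 >= 2:  # R2
            node.state = State.PRESENT
        elif a - p > config.loss_threshold:  # R3
            node.state = State.ABSENT
        else:  # R4: strict majority of subtree leaves, tie -> ABSENT
            node.state = (
                State.PRESENT
                if n_present[node] > n_absent[node]
                else State.ABSENT
            )

    events: list[tuple[str, str, str]] = []
    for node in tree.iter_preorder():
        for child in node.children:
            if node.state is child.state:
                child.event = Event.NONE
            elif child.state is State.PRESENT:
                child.event = Event.GAIN
                events.append((node.id, child.id, "GAIN"))
            else:
                child.event = Event.LOSS
                events.append((node.id, child.id, "LOSS"))

    states = {node.id: node.state.value for node in tree.iter_preorder()}
    return ReconstructionResult(
        states=states, events=events, root_state=tree.root.state.value
    )


def summarize_history(result: ReconstructionResult, tree: PhyloTree) -> dict:
    """Per-pathway summary: root state, event counts and affected clades."""
    gains, losses = [], []
    for parent_id, child_id, kind in result.events:
        child = tree.node_by_id(child_id)
        entry = {
            "edge": [parent_id, child_id],
            "clade_leaves": tree.leaves_under(child),
        }
        (gains if kind == "GAIN" else losses).append(entry)
    return {
        "root_state": result.root_state,
        "n_gains": len(gains),
        "n_losses": len(losses),
        "gains": gains,
        "losses": losses,
    }


def write_states_tsv(result: ReconstructionResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tstate\n")
        for node_id, state in result.states.items():
            fh.write(f"{node_id}\t{state}\n")


def write_events_tsv(result: ReconstructionResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\tevent\n")
        for parent_id, child_id, kind in result.events:
            fh.write(f"{parent_id}\t{child_id}\t{kind}\n")
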