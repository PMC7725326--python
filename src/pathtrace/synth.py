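"""Synthetic pangenome ensembles with planted pathway histories.

The generator emulates the block structure of real pangenome homology
matrices: strains are grouped into genus-level blocks, each block forms a
clade of a caterpillar tree, and each pathway is planted PRESENT or
ABSENT per block.  Counts in present cells are Poisson with mean
``lambda_present`` (real matrices show small integers, which Poisson at
lambda 1-3 emulates), thinned by a per-cell ``dropout`` probability;
absent cells carry a spurious single hit with probability ``epsilon``.

The planted truth covers every tree node: a node whose subtree is
uniform takes that state; any mixed node takes the majority state over
all leaves (tie -> present).  This yields exactly one event per maximal
uniform minority clade — the single-origin semantics that
``plant_event`` composes one event at a time.

Everything is reproducible from the integer seed: the matrix is realized
by drawing a fixed set of variates per cell and selecting by planted
state, so planting an event leaves all unaffected cells byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import MissingDataError, ParameterError
from .homology import HomologyMatrix, write_two_column_tsv
from .phylo import PhyloTree, parse_newick
from .profiles import PathwayDefinition, write_pathways_tsv

import pandas as pd


@dataclass
class EnsembleSpec:
    """Parameters of one synthetic ensemble."""

    n_blocks: int = 5
    strains_per_block: list[int] = field(default_factory=lambda: [12] * 5)
    n_pathways: int = 1
    enzymes_per_pathway: list[int] = field(default_factory=lambda: [6])
    planted_states: dict = field(default_factory=dict)  # (pathway, block) -> "present"|"absent"
    lambda_present: float = 3.0
    epsilon: float = 0.0
    dropout: float = 0.0
    seed: int = 0
    balanced: bool = False  # balanced binary block clades instead of polytomies

    def __post_init__(self) -> None:
        if len(self.strains_per_block) != self.n_blocks:
            raise ParameterError(
                f"strains_per_block has {len(self.strains_per_block)} entries "
                f"for {self.n_blocks} blocks"
            )
        if len(self.enzymes_per_pathway) != self.n_pathways:
            raise ParameterError(
                f"enzymes_per_pathway has {len(self.enzymes_per_pathway)} "
                f"entries for {self.n_pathways} pathways"
            )
        if not self.lambda_present > 0:
            raise ParameterError("lambda_present must be > 0")
        for name in ("epsilon", "dropout"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ParameterError(f"{name} must be in [0, 1), got {v}")

    def block_names(self) -> list[str]:
        return [f"B{k + 1:02d}" for k in range(self.n_blocks)]

    def pathway_ids(self) -> list[str]:
        return [f"P{k + 1}" for k in range(self.n_pathways)]


class SyntheticEnsemble:
    """Tree, blocks, homology matrix, pathways and planted truth."""

    def __init__(self, spec: EnsembleSpec):
        self.spec = spec
        self.block_names = spec.block_names()
        self.strains: dict[str, list[str]] = {
            b: [f"{b}s{i + 1:02d}" for i in range(n)]
            for b, n in zip(self.block_names, spec.strains_per_block)
        }
        self.blocks: dict[str, str] = {
            s: b for b, members in self.strains.items() for s in members
        }
        self.leaf_order: list[str] = [
            s for b in self.block_names for s in self.strains[b]
        ]
        self.tree: PhyloTree = parse_newick(self._newick())
        self.pathways: list[PathwayDefinition] = [
            PathwayDefinition(
                pathway_id=pid,
                enzyme_ids=[f"{pid}e{j + 1}" for j in range(n)],
                name=pid,
            )
            for pid, n in zip(spec.pathway_ids(), spec.enzymes_per_pathway)
        ]
        # planted per-leaf states; default present everywhere
        self.leaf_states: dict[str, dict[str, int]] = {}
        for p in self.pathways:
            states = {}
            for block in self.block_names:
                key = (p.pathway_id, block)
                planted = spec.planted_states.get(key, "present")
                for s in self.strains[block]:
                    states[s] = 1 if planted == "present" else 0
            self.leaf_states[p.pathway_id] = states
        self.matrix: HomologyMatrix
        self.truth: dict[str, dict]
        self._realize()

    # -- construction -----------------------------------------------------

    def _newick(self) -> str:
        def clade(block: str) -> str:
            members = self.strains[block]
            if len(members) == 1:
                return members[0]
            if not self.spec.balanced:
                return "(" + ",".join(members) + ")"

            def split(names):
                if len(names) == 1:
                    return names[0]
                mid = len(names) // 2
                return f"({split(names[:mid])},{split(names[mid:])})"

            return split(members)

        clades = [clade(b) for b in self.block_names]
        tree = clades[0]
        for c in clades[1:]:
            tree = f"({tree},{c})"
        return tree + ";"

    def _realize(self) -> None:
        """(Re)draw the count matrix and recompute the truth from leaf states."""
        rng = np.random.default_rng(self.spec.seed)
        n_rows = sum(p.n_enzymes for p in self.pathways)
        n_cols = len(self.leaf_order)
        # fixed draws per cell so planted-state changes leave other cells intact
        pois = rng.poisson(self.spec.lambda_present, size=(n_rows, n_cols))
        u_drop = rng.random(size=(n_rows, n_cols))
        u_spur = rng.random(size=(n_rows, n_cols))

        present = np.zeros((n_rows, n_cols), dtype=bool)
        row = 0
        enzyme_ids: list[str] = []
        for p in self.pathways:
            mask = np.array(
                [self.leaf_states[p.pathway_id][s] for s in self.leaf_order],
                dtype=bool,
            )
            for e in p.enzyme_ids:
                present[row] = mask
                enzyme_ids.append(e)
                row += 1

        counts = np.where(
            present,
            pois * (u_drop >= self.spec.dropout),
            (u_spur < self.spec.epsilon).astype(int),
        )
        df = pd.DataFrame(counts, index=enzyme_ids, columns=self.leaf_order)
        self.matrix = HomologyMatrix(df, blocks=self.blocks)
        self.truth = {
            p.pathway_id: self._truth_for(self.leaf_states[p.pathway_id])
            for p in self.pathways
        }

    def _truth_for(self, leaf_states: Mapping[str, int]) -> dict:
        values = list(leaf_states.values())
        majority = 1 if sum(values) * 2 >= len(values) else 0
        states: dict[str, int] = {}
        for node in self.tree.iter_preorder():
            leaves = [leaf_states[s] for s in self.tree.leaves_under(node)]
            if all(v == leaves[0] for v in leaves):
                states[node.id] = leaves[0]
            else:
                states[node.id] = majority
        events = []
        for node in self.tree.iter_preorder():
            for child in node.children:
                if states[node.id] != states[child.id]:
                    kind = "GAIN" if states[child.id] == 1 else "LOSS"
                    events.append((node.id, child.id, kind))
        return {
            "states": states,
            "events": events,
            "root_state": states[self.tree.root.id],
        }


def generate(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Generate a fully reproducible ensemble from the spec."""
    return SyntheticEnsemble(spec)


def plant_event(
    ensemble: SyntheticEnsemble, pathway_id: str, clade_id: str, event: str
) -> SyntheticEnsemble:
    """Flip the planted state of all leaves under a clade (gain or loss).

    Re-realizes the count matrix deterministically; planting the same
    event twice is a no-op beyond the first.  The expected single event
    appears on the clade's parent edge in the recomputed truth.
    """
    if event not in ("gain", "loss"):
        raise ParameterError(f"event must be 'gain' or 'loss', got {event!r}")
    if pathway_id not in ensemble.leaf_states:
        raise MissingDataError(f"unknown pathway {pathway_id!r}")
    node = ensemble.tree.node_by_id(clade_id)  # raises for unknown clades
    target = 1 if event == "gain" else 0
    states = ensemble.leaf_states[pathway_id]
    changed = False
    for leaf in ensemble.tree.leaves_under(node):
        if states[leaf] != target:
            states[leaf] = target
            changed = True
    if changed:
        ensemble._realize()
    return ensemble


# -- serialization -------------------------------------------------------------


def spec_to_dict(spec: EnsembleSpec) -> dict:
    """JSON/YAML-safe dict; planted-state keys become 'pathway|block'."""
    d = asdict(spec)
    d["planted_states"] = {
        f"{p}|{b}": v for (p, b), v in spec.planted_states.items()
    }
    return d


def spec_from_dict(d: Mapping) -> EnsembleSpec:
    """Inverse of :func:`spec_to_dict` (accepts plain config mappings)."""
    d = dict(d)
    planted = {}
    for key, value in (d.get("planted_states") or {}).items():
        if isinstance(key, str):
            pathway, _, block = key.partition("|")
            planted[(pathway, block)] = value
        else:
            planted[tuple(key)] = value
    d["planted_states"] = planted
    return EnsembleSpec(**d)


def write_ensemble(ensemble: SyntheticEnsemble, out_dir) -> dict:
    """Write matrix, blocks, tree, pathways and truth into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble.matrix.write_tsv(out / "matrix.tsv")
    write_two_column_tsv(ensemble.blocks, out / "blocks.tsv")
    ensemble.tree.write_newick(out / "tree.nwk")
    write_pathways_tsv(ensemble.pathways, out / "pathways.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(ensemble.truth, fh, indent=2, default=list)
    with open(out / "spec.json", "w") as fh:
        json.dump(spec_to_dict(ensemble.spec), fh, indent=2)
    return {
        "matrix": str(out / "matrix.tsv"),
        "blocks": str(out / "blocks.tsv"),
        "tree": str(out / "tree.nwk"),
        "pathways": str(out / "pathways.tsv"),
        "truth": str(out / "truth.json"),
    }


def write_hits(ensemble: SyntheticEnsemble, hits_path, gene_map_path) -> None:
    """Emit a BLAST-outfmt-6-style hits file realizing the count matrix.

    Each cell count c becomes c distinct subject genes of that strain hit
    at a strong e-value, enabling integration tests of homologue counting.
    """
    gene_map: dict[str, str] = {}
    with open(hits_path, "w") as fh:
        for enzyme in ensemble.matrix.enzymes:
            row = ensemble.matrix.counts.loc[enzyme]
            for strain in ensemble.leaf_order:
                c = int(row[strain])
                for k in range(c):
                    gene = f"{strain}_{enzyme}_g{k + 1}"
                    gene_map[gene] = strain
                    fields = [
                        enzyme, gene, "100.0", "300", "0", "0",
                        "1", "300", "1", "300", "1e-50", "500",
                    ]
                    fh.write("\t".join(fields) + "\n")
    # every strain keeps a mapped sentinel gene so empty columns stay resolvable
    for strain in ensemble.leaf_order:
        gene_map.setdefault(f"{strain}_dummy", strain)
    write_two_column_tsv(gene_map, gene_map_path)
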