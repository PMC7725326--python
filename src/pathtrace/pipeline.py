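"""End-to-end runs: hits -> matrix -> profiles -> reconstruction -> output.

A run executes the five method steps in order and leaves every
intermediate plus a machine-readable manifest in the output directory,
so any run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

from . import __version__
from . import biopax as bp
from .errors import PipelineError
from .homology import (
    DEFAULT_EVALUE_CUTOFF,
    HomologyMatrix,
    aggregate_pangenome,
    count_homologues,
    read_blast_tab,
    read_two_column_tsv,
)
from .phylo import attach_pangenome_leaves, read_newick
from .profiles import (
    default_alpha,
    discretize_grid,
    fuzzy_profile_grid,
    read_pathways_tsv,
)
from .reconstruct import (
    ReconstructionConfig,
    reconstruct_ancestral,
    summarize_history,
    write_events_tsv,
    write_states_tsv,
)


@dataclass
class RunConfig:
    """Inputs and parameters of one full run."""

    out_dir: str
    tree: str
    pathways: str | None = None          # pathway TSV
    biopax: str | None = None            # BioPAX L3 template (alternative input)
    hits: str | None = None              # BLAST outfmt 6
    gene_map: str | None = None          # gene -> genome TSV
    matrix: str | None = None            # precomputed matrix TSV (alternative)
    blocks: str | None = None            # genome -> block TSV
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    alpha: float | str = "auto"
    gain: int = 5
    loss: int = 2
    mode: str = "leaf-count"
    aggregate: str = "max"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


@_stage("matrix")
def _build_matrix(config: RunConfig, pathways, blocks):
    if config.matrix:
        matrix = HomologyMatrix.read_tsv(config.matrix, blocks=blocks)
    else:
        if not (config.hits and config.gene_map):
            raise PipelineError(
                "stage 'matrix' failed: need either --matrix or --hits with --gene-map"
            )
        gene_map = read_two_column_tsv(config.gene_map, "gene", "genome")
        enzymes = [e for p in pathways for e in p.enzyme_ids]
        genomes = sorted(set(gene_map.values()))
        matrix = count_homologues(
            read_blast_tab(config.hits), gene_map, enzymes, genomes,
            evalue_cutoff=config.evalue_cutoff, blocks=blocks,
        )
    if blocks:
        matrix = aggregate_pangenome(matrix, blocks, mode=config.aggregate)
    return matrix


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the output directory path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"pathtrace {__version__}"]

    # inputs
    if config.pathways:
        pathways = read_pathways_tsv(config.pathways)
    elif config.biopax:
        definition, _ = bp.extract_proteins(config.biopax)
        pathways = [definition]
    else:
        raise PipelineError("stage 'input' failed: need --pathways or --biopax")
    blocks = (
        read_two_column_tsv(config.blocks, "genome", "block")
        if config.blocks else None
    )

    matrix = _build_matrix(config, pathways, blocks)
    matrix.write_tsv(out / "matrix.tsv")
    log_lines.append(
        "matrix: {n_enzymes} enzymes x {n_genomes} genomes "
        "({n_cells} cells)".format(**matrix.shape_summary())
    )

    # profiles
    try:
        fuzzy = fuzzy_profile_grid(matrix, pathways)
        alpha = (
            default_alpha(fuzzy.to_numpy())
            if config.alpha == "auto" else float(config.alpha)
        )
        discrete = discretize_grid(fuzzy, alpha)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'profiles' failed: {exc}") from exc
    fuzzy.to_csv(out / "fuzzy.tsv", sep="\t", index_label="pathway")
    discrete.to_csv(out / "discrete.tsv", sep="\t", index_label="pathway")
    log_lines.append(f"alpha used: {alpha:.6g} "
                     f"({'auto grand mean' if config.alpha == 'auto' else 'user'})")

    # tree
    try:
        tree = read_newick(config.tree)
        if blocks:
            strain_blocks = {g: b for g, b in blocks.items()
                             if g in set(tree.leaf_names)}
            tree = attach_pangenome_leaves(tree, strain_blocks)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'tree' failed: {exc}") from exc

    # reconstruction
    rc = ReconstructionConfig(
        gain_threshold=config.gain, loss_threshold=config.loss, mode=config.mode
    )
    summaries = {}
    try:
        for p in pathways:
            leaf_states = {
                g: int(discrete.at[p.pathway_id, g])
                for g in discrete.columns
            }
            result = reconstruct_ancestral(tree, leaf_states, rc)
            write_states_tsv(result, out / f"states_{p.pathway_id}.tsv")
            write_events_tsv(result, out / f"events_{p.pathway_id}.tsv")
            summaries[p.pathway_id] = summarize_history(result, tree)
            # per-node annotated BioPAX when a template document is supplied
            if config.biopax:
                node_dir = out / "biopax" / p.pathway_id
                node_dir.mkdir(parents=True, exist_ok=True)
                for node_id, state in result.states.items():
                    doc = bp.load(config.biopax)
                    bp.annotate_states(
                        doc, pathway_state=state.lower(), protein_states=None
                    )
                    bp.write(doc, node_dir / f"{node_id}.owl")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'reconstruct' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "alpha_used": alpha,
        "inputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in (
                ("tree", config.tree), ("pathways", config.pathways),
                ("biopax", config.biopax), ("hits", config.hits),
                ("gene_map", config.gene_map), ("matrix", config.matrix),
                ("blocks", config.blocks),
            )
            if path
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out
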