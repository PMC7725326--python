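"""Enzyme x genome homology matrices.

The matrix ``M_H`` holds, for each query enzyme (row) and target genome
(column), the number of distinct homologous genes detected by a similarity
search at a given e-value cutoff.  Rows are the per-enzyme phylogenetic
profiles; column blocks group strains into pangenomes.

The module consumes BLAST tabular output (outfmt 6); only the query id,
subject id and e-value columns are used.  Running the similarity search
itself is out of scope.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MissingDataError, ParameterError

DEFAULT_EVALUE_CUTOFF = 1e-6

#: outfmt 6 column names (only qseqid, sseqid and evalue are consumed)
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class HomologyMatrix:
    """Non-negative counts of homologues per enzyme (row) x genome (column).

    ``blocks`` optionally maps genomes to pangenome block labels; when
    present, columns are reordered so each block forms a contiguous run
    (blocks in order of first appearance, genomes keeping their relative
    order, unblocked genomes last).
    """

    def __init__(self, counts: pd.DataFrame, blocks: Mapping[str, str] | None = None):
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise FormatError("duplicate enzyme or genome labels")
        try:
            counts = counts.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric cell in matrix: {exc}") from exc
        if counts.size and (counts.to_numpy() < 0).any():
            raise FormatError("matrix contains negative cells")
        if blocks:
            counts = counts[_block_order(list(counts.columns), blocks)]
        self.counts = counts
        self.blocks = dict(blocks) if blocks else None

    # -- basic views -------------------------------------------------------

    @property
    def enzymes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def binary(self) -> np.ndarray:
        """Presence/absence view: cell > 0."""
        return (self.values > 0).astype(int)

    def shape_summary(self) -> dict:
        n, m = self.counts.shape
        return {"n_enzymes": n, "n_genomes": m, "n_cells": n * m}

    def row(self, enzyme: str) -> np.ndarray:
        if enzyme not in self.counts.index:
            raise MissingDataError(f"enzyme {enzyme!r} not in matrix")
        return self.counts.loc[enzyme].to_numpy()

    # -- I/O ----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="enzyme")

    @classmethod
    def read_tsv(cls, path, blocks: Mapping[str, str] | None = None) -> "HomologyMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, engine="python")
        except pd.errors.ParserError as exc:
            raise FormatError(f"ragged or malformed matrix file {path}: {exc}") from exc
        for rownum, (_, row) in enumerate(df.iterrows(), start=2):
            bad = row[pd.to_numeric(row, errors="coerce").isna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric cell in {path} at row {rownum}: {bad.iloc[0]!r}"
                )
        return cls(df, blocks=blocks)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HomologyMatrix)
            and self.counts.equals(other.counts)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n, m = self.counts.shape
        return f"HomologyMatrix({n} enzymes x {m} genomes)"


def _block_order(genomes: Sequence[str], blocks: Mapping[str, str]) -> list[str]:
    block_rank: dict[str, int] = {}
    for g in genomes:
        b = blocks.get(g)
        if b is not None and b not in block_rank:
            block_rank[b] = len(block_rank)
    unblocked = len(block_rank)
    return sorted(
        genomes,
        key=lambda g: (block_rank.get(blocks.get(g, ""), unblocked),
                       genomes.index(g)),
    )


def read_blast_tab(path) -> pd.DataFrame:
    """Read BLAST outfmt-6 tabular output; keep qseqid, sseqid, evalue."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 10], names=["qseqid", "sseqid", "evalue"],
            dtype={0: str, 1: str, 10: float},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed BLAST tabular file {path}: {exc}") from exc
    return df


def _as_hits_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        missing = {"qseqid", "sseqid", "evalue"} - set(hits.columns)
        if missing:
            raise FormatError(f"hits frame missing columns: {sorted(missing)}")
        return hits[["qseqid", "sseqid", "evalue"]].copy()
    rows = list(hits)
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])


def count_homologues(
    hits,
    gene_to_genome: Mapping[str, str],
    enzymes: Sequence[str],
    genomes: Sequence[str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    blocks: Mapping[str, str] | None = None,
) -> HomologyMatrix:
    """Build the homology matrix from similarity-search hits.

    A cell (enzyme i, genome j) counts the DISTINCT subject genes of
    genome j hit by enzyme i with e-value <= ``evalue_cutoff``.  Repeated
    (query, subject) pairs (e.g. multiple HSPs) are deduplicated keeping
    the best e-value.  Subject genes with no entry in ``gene_to_genome``
    are an error; hits whose query is not a listed enzyme, or whose
    genome is not a listed target, are ignored.
    """
    if not evalue_cutoff > 0:
        raise ParameterError(f"evalue_cutoff must be > 0, got {evalue_cutoff}")
    df = _as_hits_frame(hits)
    df = df[df["qseqid"].isin(set(enzymes))]
    unmapped = sorted(set(df["sseqid"]) - set(gene_to_genome))
    if unmapped:
        raise MissingDataError(
            f"subject genes with no genome mapping: {unmapped[:20]}"
            + (" ..." if len(unmapped) > 20 else "")
        )
    # best e-value per (query, subject), then apply the cutoff
    df = df.groupby(["qseqid", "sseqid"], as_index=False)["evalue"].min()
    df = df[df["evalue"] <= evalue_cutoff]
    df["genome"] = df["sseqid"].map(gene_to_genome)
    df = df[df["genome"].isin(set(genomes))]

    counts = pd.DataFrame(0.0, index=list(enzymes), columns=list(genomes))
    if len(df):
        tally = df.groupby(["qseqid", "genome"])["sseqid"].nunique()
        for (enzyme, genome), k in tally.items():
            counts.at[enzyme, genome] = k
    return HomologyMatrix(counts, blocks=blocks)


AGGREGATION_MODES = ("max", "mean", "sum")


def aggregate_pangenome(
    matrix: HomologyMatrix,
    blocks: Mapping[str, str],
    mode: str = "max",
    png_names: Mapping[str, str] | None = None,
) -> HomologyMatrix:
    """Extend the matrix with one virtual pangenome column per block.

    The virtual cell for an enzyme is the max (default), mean or sum of
    its counts over the block's member genomes.  ``max`` approximates a
    search against the non-redundant union of the strain proteomes.
    """
    if mode not in AGGREGATION_MODES:
        raise ParameterError(f"unknown aggregation mode {mode!r}")
    members_by_block: dict[str, list[str]] = {}
    for genome, block in blocks.items():
        if genome in matrix.counts.columns:
            members_by_block.setdefault(block, []).append(genome)
    for block in set(blocks.values()):
        if not members_by_block.get(block):
            raise MissingDataError(f"block {block!r} has no member columns")

    counts = matrix.counts.copy()
    new_blocks = dict(matrix.blocks or {})
    new_blocks.update({g: b for g, b in blocks.items() if g in counts.columns})
    for block, members in members_by_block.items():
        name = (png_names or {}).get(block, f"{block}-png")
        if name in counts.columns:
            raise FormatError(f"virtual column name {name!r} already exists")
        sub = counts[members]
        if mode == "max":
            counts[name] = sub.max(axis=1)
        elif mode == "sum":
            counts[name] = sub.sum(axis=1)
        else:
            counts[name] = sub.mean(axis=1)
        new_blocks[name] = block
    return HomologyMatrix(counts, blocks=new_blocks)


def read_two_column_tsv(path, key_name: str = "key", value_name: str = "value") -> dict:
    """Read a two-column TSV mapping (e.g. gene -> genome, genome -> block)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: expected 2 columns at line {lineno}, got {len(parts)}"
                )
            key, value = parts
            if key in mapping and mapping[key] != value:
                raise FormatError(
                    f"{path}: conflicting {value_name} for {key_name} {key!r} "
                    f"at line {lineno}"
                )
            mapping[key] = value
    return mapping


def write_two_column_tsv(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}\t{value}\n")
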