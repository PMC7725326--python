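"""Fuzzy pathway profiles and their discretization.

A pathway's fuzzy profile is the per-genome arithmetic mean of the
homologue counts over the pathway's n member enzymes:

    f_j = (sum_i h_gij) / n

an unbounded, real-valued likelihood-of-presence score.  The discrete
profile applies a threshold alpha:

    d_j = 1  if f_j >= alpha   (ties at alpha count as presence)
    d_j = 0  if f_j <  alpha

When the user supplies no alpha, the default is the grand mean of all
fuzzy values in the run (optionally per-pathway row means), reflecting
that the appropriate threshold depends on the evolutionary spread of the
target genomes: close strains need a strict threshold, distant taxa a
permissive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MissingDataError, ParameterError
from .homology import HomologyMatrix


@dataclass
class PathwayDefinition:
    """A pathway: identifier, display name and ordered member enzyme IDs."""

    pathway_id: str
    enzyme_ids: list[str]
    name: str = ""
    source_genome: str | None = None

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ParameterError("pathway_id must be non-empty")
        if len(set(self.enzyme_ids)) != len(self.enzyme_ids):
            dupes = sorted(
                {e for e in self.enzyme_ids if self.enzyme_ids.count(e) > 1}
            )
            raise ParameterError(
                f"pathway {self.pathway_id}: duplicate enzyme ids {dupes}"
            )

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_ids)


@dataclass
class PathwayProfile:
    """Fuzzy and discrete presence vectors of one pathway across genomes."""

    pathway_id: str
    genomes: list[str]
    fuzzy: np.ndarray
    discrete: np.ndarray
    alpha: float

    @classmethod
    def from_matrix(
        cls, matrix: HomologyMatrix, pathway: PathwayDefinition, alpha: float
    ) -> "PathwayProfile":
        fuzzy = build_fuzzy_profile(matrix, pathway)
        return cls(
            pathway_id=pathway.pathway_id,
            genomes=matrix.genomes,
            fuzzy=fuzzy,
            discrete=discretize(fuzzy, alpha),
            alpha=alpha,
        )

    def leaf_states(self) -> dict[str, int]:
        return {g: int(d) for g, d in zip(self.genomes, self.discrete)}


def build_fuzzy_profile(
    matrix: HomologyMatrix, pathway: PathwayDefinition
) -> np.ndarray:
    """Mean homologue count over the pathway's enzymes, per genome.

    Every declared enzyme must be a row of the matrix: the denominator is
    the declared pathway size, so silently dropping a missing enzyme would
    bias the profile.
    """
    if not pathway.enzyme_ids:
        raise ParameterError(
            f"pathway {pathway.pathway_id} has no enzymes; cannot profile"
        )
    missing = [e for e in pathway.enzyme_ids if e not in matrix.counts.index]
    if missing:
        raise MissingDataError(
            f"pathway {pathway.pathway_id}: enzymes missing from matrix: {missing}"
        )
    return matrix.counts.loc[pathway.enzyme_ids].mean(axis=0).to_numpy()


def fuzzy_profile_grid(
    matrix: HomologyMatrix, pathways: Sequence[PathwayDefinition]
) -> pd.DataFrame:
    """Pathways x genomes grid of fuzzy values."""
    rows = {p.pathway_id: build_fuzzy_profile(matrix, p) for p in pathways}
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.genomes)


def discretize(fuzzy, alpha: float) -> np.ndarray:
    """Binary presence calls: 1 where fuzzy >= alpha (inclusive boundary)."""
    if not alpha > 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    arr = np.asarray(fuzzy, dtype=float)
    return (arr >= alpha).astype(int)


def discretize_grid(grid: pd.DataFrame, alpha: float) -> pd.DataFrame:
    return pd.DataFrame(
        discretize(grid.to_numpy(), alpha), index=grid.index, columns=grid.columns
    )


def default_alpha(grid, per_pathway: bool = False):
    """Data-driven alpha: the mean fuzzy value over the run.

    Default is the grand mean over all pathway x genome cells (one alpha
    for the whole run); ``per_pathway=True`` instead returns one alpha per
    pathway (row means).
    """
    arr = np.asarray(grid, dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot derive alpha from an empty grid")
    if per_pathway:
        return arr.mean(axis=-1)
    return float(arr.mean())


# -- pathway definition I/O ---------------------------------------------------


def read_pathways_tsv(path) -> list[PathwayDefinition]:
    """Read pathway definitions: one (pathway_id, enzyme_id) row per member.

    An optional third column carries the pathway display name.
    """
    order: list[str] = []
    members: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}: expected >=2 columns at line {lineno}"
                )
            pid, enzyme = parts[0], parts[1]
            if pid not in members:
                members[pid] = []
                order.append(pid)
            members[pid].append(enzyme)
            if len(parts) > 2 and parts[2]:
                names[pid] = parts[2]
    return [
        PathwayDefinition(pathway_id=pid, enzyme_ids=members[pid],
                          name=names.get(pid, pid))
        for pid in order
    ]


def write_pathways_tsv(pathways: Sequence[PathwayDefinition], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            for e in p.enzyme_ids:
                fh.write(f"{p.pathway_id}\t{e}\t{p.name}\n")
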