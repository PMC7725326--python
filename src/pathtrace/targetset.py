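"""Diagnostics for the choice of target genome ensemble.

Whether ancestral pathway inference is well-posed depends on the target
set: scattered single genomes give sharp but uninterpretable contrast,
a lone pangenome gives homogeneous profiles with no contrast, and a
collection of several pangenomes gives both contrast and block-aligned
variation.  Two bounded scores quantify this on the binarized homology
matrix:

* ``matrix_entropy`` — contrast: the normalized Shannon entropy of the
  overall fraction of present cells (0 for a homogeneous matrix, 1 when
  exactly half the cells are present).
* ``matrix_segmentation`` — gradient entropy: how strongly
  column-to-column variation concentrates at few boundaries.  With
  g_j the Hamming distance between adjacent binarized columns and
  p_j = g_j / sum(g), segmentation = 1 - H(p) / log2(m - 1).  A matrix
  whose variation all sits at one block boundary scores 1; variation
  spread evenly over all boundaries scores 0.  A fully homogeneous
  matrix (sum g = 0) is a single perfect segment and scores 1.

A good multi-pangenome target set scores high on both.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError
from .homology import HomologyMatrix


@dataclass
class TargetSetMetrics:
    entropy: float
    segmentation: float
    n_blocks: int
    n_rows: int
    n_cols: int

    def as_dict(self) -> dict:
        return asdict(self)


def _binary(matrix: HomologyMatrix) -> np.ndarray:
    if matrix.counts.size == 0:
        raise ParameterError("matrix is empty")
    return matrix.binary()


def matrix_entropy(matrix: HomologyMatrix) -> float:
    """Normalized binary entropy of the fraction of present cells."""
    b = _binary(matrix)
    q = float(b.mean())
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return float(-q * np.log2(q) - (1 - q) * np.log2(1 - q))


def matrix_segmentation(matrix: HomologyMatrix) -> float:
    """Gradient-entropy segmentation score in [0, 1]."""
    b = _binary(matrix)
    m = b.shape[1]
    if m < 2:
        raise ParameterError("segmentation needs >= 2 columns")
    g = np.abs(np.diff(b, axis=1)).sum(axis=0).astype(float)
    total = g.sum()
    if total == 0:
        return 1.0  # homogeneous matrix: one perfect segment
    if m == 2:
        return 1.0  # single boundary carries all variation by definition
    p = g / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return float(1.0 - h / np.log2(m - 1))


def assess(matrix: HomologyMatrix) -> TargetSetMetrics:
    """Compute both target-set metrics plus shape/block bookkeeping."""
    n, m = matrix.counts.shape
    n_blocks = len(set(matrix.blocks.values())) if matrix.blocks else 0
    return TargetSetMetrics(
        entropy=matrix_entropy(matrix),
        segmentation=matrix_segmentation(matrix),
        n_blocks=n_blocks,
        n_rows=n,
        n_cols=m,
    )
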