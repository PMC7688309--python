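"""Complexity-corrected accessibility scores and cell-fraction statistics.

The model
---------
Each cell j carries a library of C_j distinct molecules from which k_j reads
were drawn (with replacement, assuming unbiased PCR).  The probability that
any one fragment of the library is sequenced at least once is

    s_j = 1 - (1 - 1/C_j)^{k_j}.

If a fragment enters the library proportionally to the accessibility A_i of
its peak and to C_j, the expected count E[O_ij] is proportional to
C_j * s_j * A_i, so the per-peak accessibility can be estimated as

    A_i = Z * (sum_j O_ij) / (sum_j C_j s_j),

with Z the normalization constant chosen so that scores sum to 1e6
(counts-per-million convention).  The denominator is shared across peaks, so
within one cell subset the normalized estimator coincides with the relative
form A_i = 1e6 * sum_j O_ij / sum_ij O_ij; the complexity term matters when
scores computed on different cell subsets (donors, age groups) are compared
on a common scale.

The cell-fraction statistics correct for differential read depth between
cell partitions: m_ij is the fraction of cells of partition S_i with at
least one read in peak p_j; s_ij renormalizes m within the partition across
the background peak set P (to 1e6); RS_ij renormalizes s across partitions
per peak (to 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PeakMatrix

logger = logging.getLogger(__name__)

SCALE = 1.0e6


def filter_cells(matrix: PeakMatrix, min_usable_reads: int = 1000) -> PeakMatrix:
    """Keep cells with usable_reads >= *min_usable_reads* (boundary inclusive).

    The peak set is unchanged; an empty result is allowed and logged.
    """
    keep = [i for i, c in enumerate(matrix.cells) if c.usable_reads >= min_usable_reads]
    if not keep:
        logger.warning("filter_cells: no cell passes usable_reads >= %d", min_usable_reads)
    return matrix.subset_cells(keep)


def sequencing_probability(C, k):
    """Probability s = 1 - (1 - 1/C)^k that a library fragment is sequenced.

    Vectorized over C (complexity, >= 1) and k (read count, >= 0).
    Monotone increasing in k and decreasing in C.
    """
    C = np.asarray(C, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(C < 1):
        raise ValueError("library complexity C must be >= 1")
    if np.any(k < 0):
        raise ValueError("read count k must be >= 0")
    # 1-(1-1/C)^k computed via expm1/log1p for accuracy at large C, k.
    with np.errstate(divide="ignore"):
        log_miss = k * np.log1p(-1.0 / C)
    s = -np.expm1(log_miss)
    # C == 1: a single molecule is sequenced iff k >= 1
    s = np.where(C == 1.0, (k > 0).astype(float), s)
    if s.ndim == 0:
        return float(s)
    return s


def relative_accessibility(matrix: PeakMatrix, cell_subset=None) -> np.ndarray:
    """Relative accessibility A_i = 1e6 * sum_j O_ij / sum_ij O_ij.

    *cell_subset* is an optional array of cell indices; default all cells.
    """
    counts = matrix.counts if cell_subset is None else matrix.counts[:, np.asarray(cell_subset)]
    row = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    total = row.sum()
    if total <= 0:
        raise ValueError("cell subset has no counts; relative accessibility undefined")
    return SCALE * row / total


def complexity_adjusted_accessibility(
    matrix: PeakMatrix, cell_subset=None, normalize: bool = True
) -> np.ndarray:
    """Accessibility estimate A_i = Z * sum_j O_ij / sum_j C_j s_j.

    With ``normalize=True`` (default) Z is chosen so scores sum to 1e6.
    With ``normalize=False`` Z = 1, leaving scores on the per-sequenced-
    molecule scale that is comparable across cell subsets of different
    depth and complexity.
    """
    idx = np.arange(len(matrix.cells)) if cell_subset is None else np.asarray(cell_subset)
    counts = matrix.counts[:, idx]
    C = np.array([matrix.cells[i].library_complexity for i in idx], dtype=float)
    k = np.array([matrix.cells[i].usable_reads for i in idx], dtype=float)
    s = np.atleast_1d(sequencing_probability(C, k))
    col_nonzero = np.asarray(counts.sum(axis=0)).ravel() > 0
    if np.any((s == 0) & col_nonzero):
        raise ValueError("cell with zero sequencing probability has nonzero counts")
    denom = float(np.sum(C * s))
    if denom <= 0:
        raise ValueError("sum_j C_j s_j is zero; scores undefined")
    row = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    A = row / denom
    if normalize:
        total = A.sum()
        if total <= 0:
            raise ValueError("all-zero counts in subset")
        A = SCALE * A / total
    return A


@dataclass
class CellFractionTable:
    """m / s / RS statistics per partition x peak.

    All three arrays are partitions x peaks over the background peak set.
    Entries of RS where no partition has any accessible cell are NaN
    (missing, not zero: an all-zero peak carries no evidence).
    """

    partitions: list[str]
    peak_ids: list[str]
    m: np.ndarray
    s: np.ndarray
    rs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, part in enumerate(self.partitions):
            for j, pid in enumerate(self.peak_ids):
                rows.append(
                    {
                        "partition": part,
                        "peak_id": pid,
                        "m": self.m[i, j],
                        "s": self.s[i, j],
                        "rs": self.rs[i, j],
                    }
                )
        return pd.DataFrame(rows)


def cell_fraction_table(
    matrix: PeakMatrix,
    partitions: dict[str, np.ndarray],
    background_peaks=None,
) -> CellFractionTable:
    """Compute m_ij, s_ij and RS_ij for disjoint cell partitions.

    *partitions* maps partition name -> array of cell indices (disjoint,
    nonempty).  *background_peaks* is an optional array of peak indices
    forming the background set P (default: all peaks — the merged peak set).
    A cell counts as accessible at a peak iff its count is >= 1.
    """
    names = list(partitions)
    all_idx = np.concatenate([np.asarray(partitions[n]) for n in names]) if names else np.array([])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("partitions must be disjoint")
    P = np.arange(matrix.shape[0]) if background_peaks is None else np.asarray(background_peaks)
    binary = matrix.counts[P, :].astype(bool)

    m = np.zeros((len(names), len(P)))
    for i, name in enumerate(names):
        idx = np.asarray(partitions[name])
        if idx.size == 0:
            raise ValueError(f"partition {name!r} has zero cells")
        m[i] = np.asarray(binary[:, idx].sum(axis=1)).ravel() / idx.size

    row_tot = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = SCALE * m / row_tot
    s[np.repeat(row_tot == 0, m.shape[1], axis=1)] = np.nan

    col_tot = np.nansum(s, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = s / col_tot
    rs[:, (col_tot == 0).ravel()] = np.nan

    peak_ids = [matrix.peaks[j].id for j in P]
    return CellFractionTable(names, peak_ids, m, s, rs)
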