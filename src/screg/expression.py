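"""Expression-side statistics: QC, log-normalization, expressing fractions.

A nucleus "expresses" a gene iff at least one UMI is observed for it.  The
fraction statistics and the age-group tests operate on per-donor expressing
fractions; normalization follows the ln(1 + scale * x / total) convention
with scale 10,000.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats


class ExpressionMatrix:
    """UMI counts (genes x nuclei) with nucleus metadata.

    ``meta`` is a DataFrame with one row per nucleus and at least the
    columns barcode, donor_id, age_group, cluster.
    """

    def __init__(self, counts: sp.spmatrix, genes: list[str], meta: pd.DataFrame):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(genes), len(meta)):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(genes)} genes, {len(meta)} nuclei)"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative UMI count")
        self.counts = counts.astype(np.int64)
        self.genes = list(genes)
        self.meta = meta.reset_index(drop=True)
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def shape(self):
        return self.counts.shape

    def gene_row(self, gene: str) -> np.ndarray:
        return np.asarray(self.counts[self._gene_index[gene]].todense()).ravel()

    def subset(self, gene_idx=None, cell_idx=None) -> "ExpressionMatrix":
        gi = np.arange(self.shape[0]) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.shape[1]) if cell_idx is None else np.asarray(cell_idx)
        return ExpressionMatrix(
            self.counts[gi][:, ci],
            [self.genes[i] for i in gi],
            self.meta.iloc[ci],
        )


def qc_expression(
    matrix: ExpressionMatrix,
    min_cells_per_gene: int = 3,
    min_genes: int = 500,
    max_genes: int = 4000,
) -> ExpressionMatrix:
    """Keep genes detected (>= 1 UMI) in >= *min_cells_per_gene* nuclei and
    nuclei with a detected-gene count in [min_genes, max_genes] (inclusive).

    The gene filter is applied before the cell filter, and the pass is
    repeated until a fixed point so that the operation is idempotent
    (removing nuclei can drop a gene below the detection threshold, which
    in turn can change a nucleus's detected-gene count).
    """
    current = matrix
    while True:
        detected = current.counts.astype(bool)
        gene_keep = np.flatnonzero(
            np.asarray(detected.sum(axis=1)).ravel() >= min_cells_per_gene
        )
        detected = detected[gene_keep]
        genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
        cell_keep = np.flatnonzero(
            (genes_per_cell >= min_genes) & (genes_per_cell <= max_genes)
        )
        nxt = current.subset(gene_keep, cell_keep)
        if nxt.shape == current.shape:
            return nxt
        current = nxt


def lognormalize(matrix: ExpressionMatrix, scale: float = 10000.0) -> sp.csr_matrix:
    """Depth-normalize and log-transform: x -> ln(1 + scale * x / total).

    Returns a sparse float matrix aligned with *matrix*.  Zero-total nuclei
    must have been removed by QC beforehand.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("nucleus with zero total UMIs; run QC first")
    out = matrix.counts.tocsc().astype(float)
    for j in range(out.shape[1]):
        sl = slice(out.indptr[j], out.indptr[j + 1])
        out.data[sl] = np.log1p(scale * out.data[sl] / totals[j])
    return out.tocsr()


def expressing_fraction(
    matrix: ExpressionMatrix, gene: str, grouping: str = "cluster"
) -> pd.DataFrame:
    """Fraction of nuclei with >= 1 UMI for *gene*, per level of *grouping*.

    Returns columns group, n_expressing, n_total, fraction at full
    precision; display rounding is left to the report layer.
    """
    counts = matrix.gene_row(gene)
    groups = matrix.meta[grouping]
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        idx = np.asarray(idx)
        n_expr = int((counts[idx] >= 1).sum())
        rows.append(
            {
                "gene": gene,
                "group": g,
                "n_expressing": n_expr,
                "n_total": len(idx),
                "fraction": n_expr / len(idx),
            }
        )
    return pd.DataFrame(rows)


def per_donor_fractions(
    matrix: ExpressionMatrix, gene: str, cluster: str | None = None
) -> pd.DataFrame:
    """Per-donor expressing fractions (optionally within one cluster)."""
    sub = matrix
    if cluster is not None:
        sub = matrix.subset(cell_idx=np.flatnonzero(matrix.meta["cluster"] == cluster))
    df = expressing_fraction(sub, gene, grouping="donor_id")
    age = sub.meta.drop_duplicates("donor_id").set_index("donor_id")["age_group"]
    df["age_group"] = df["group"].map(age)
    return df.rename(columns={"group": "donor_id"})


def fraction_age_test(
    donor_fractions: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Unpaired two-tailed t-tests on per-donor fractions between every pair
    of age groups.

    *donor_fractions* needs columns donor_id, age_group, fraction.  Pooled
    (equal-variance) t by default; Welch via ``equal_var=False``.
    """
    groups = {
        g: sub["fraction"].to_numpy()
        for g, sub in donor_fractions.groupby("age_group", observed=True)
    }
    names = [g for g in ("30wkGA", "3yo", "30yo") if g in groups] or sorted(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if len(a) < 2 or len(b) < 2:
                raise ValueError("need >= 2 donors per age group for the t-test")
            if np.ptp(np.concatenate([a, b])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append({"group_a": names[i], "group_b": names[j], "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def median_expressing(normalized: sp.spmatrix, matrix: ExpressionMatrix, gene: str, sample: str):
    """Median normalized expression over a sample's expressing nuclei.

    *normalized* is the matrix from :func:`lognormalize` aligned with
    *matrix*; *sample* selects donor_id.  Returns NaN if no nucleus of the
    sample expresses the gene.
    """
    gi = matrix._gene_index[gene]
    cells = np.flatnonzero(matrix.meta["donor_id"] == sample)
    raw = np.asarray(matrix.counts[gi, cells].todense()).ravel()
    vals = np.asarray(sp.csr_matrix(normalized)[gi, cells].todense()).ravel()
    expressing = raw >= 1
    if not expressing.any():
        return float("nan")
    return float(np.median(vals[expressing]))
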