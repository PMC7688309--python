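"""Ensemble co-accessibility between peaks.

Sparse per-cell counts are aggregated into metacells (a seed cell plus its
k-1 nearest neighbors in TF-IDF/SVD space), then, within genomic windows, a
sparse inverse covariance is estimated with a distance-penalized graphical
lasso:

    maximize  log det T - tr(S T) - sum_{a != b} rho_ab |T_ab|,
    rho_ab = lambda0 * sqrt(d_ab / window_bp),

so that distant pairs are penalized more, mirroring the distance decay of
chromatin contacts.  The co-accessibility score of a pair is the partial
correlation -T_ab / sqrt(T_aa T_bb).

The ensemble runs the model once per cell-type cluster (1 Mb windows) and
five times on random cell subsets (250 kb windows), pools per-pair scores
into an array, and keeps links whose mean score differs from zero by a
one-sample t-test at p < 0.10.  Promoter linking reports retained links
with mean score > 0.05 where exactly one anchor overlaps a protein-coding
promoter (TSS +/- 500 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import pandas as pd
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .io import Peak, PeakMatrix, PeakSet

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """The penalty scale could not be calibrated on the given data."""


@dataclass
class MetacellMatrix:
    """Aggregated binarized counts (peaks x metacells) with member map.

    ``composition`` holds per-metacell member fractions over age groups and
    cell-type clusters; the graphical model conditions on them (plus depth)
    so that group-level covariation is not reported as co-accessibility.
    """

    counts: np.ndarray
    peaks: PeakSet
    members: list[list[int]]
    composition: np.ndarray | None = None

    @property
    def n_metacells(self) -> int:
        return self.counts.shape[1]


@dataclass
class CoaccessLink:
    """An unordered peak pair with per-run co-accessibility scores."""

    peak_a: Peak
    peak_b: Peak
    scores: np.ndarray
    t_stat: float | None = None
    t_p: float | None = None
    retained: bool = False

    def __post_init__(self):
        if (self.peak_a.chrom, self.peak_a.start) > (self.peak_b.chrom, self.peak_b.start):
            self.peak_a, self.peak_b = self.peak_b, self.peak_a
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_runs(self) -> int:
        return len(self.scores)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def distance(self) -> float:
        return abs(self.peak_b.midpoint - self.peak_a.midpoint)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.peak_a.id, self.peak_b.id)))


# ---------------------------------------------------------------------------
# Metacells


def _tfidf_embedding(binary: sp.csr_matrix, n_components: int = 30, seed: int = 0) -> np.ndarray:
    """TF-IDF + truncated SVD embedding of binarized cells x peaks counts."""
    n_cells, n_peaks = binary.shape
    df = np.asarray(binary.sum(axis=0)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + df))
    depth = np.asarray(binary.sum(axis=1)).ravel()
    depth[depth == 0] = 1
    tf = sp.diags(1.0 / depth) @ binary
    tfidf = tf.multiply(idf[None, :]).tocsr()
    k = min(n_components, n_cells - 1, n_peaks - 1)
    if k < 1:
        return np.asarray(tfidf.todense())
    svd = TruncatedSVD(n_components=k, random_state=seed)
    return svd.fit_transform(tfidf)


def build_metacells(
    matrix: PeakMatrix,
    k_neighbors: int = 50,
    seed: int = 0,
    embedding: np.ndarray | None = None,
    overlap_cap: float = 0.10,
    embed_peak_idx: np.ndarray | None = None,
) -> MetacellMatrix:
    """Aggregate cells into metacells of exactly *k_neighbors* members.

    Seed cells are drawn without replacement in random order; each
    candidate metacell is the seed plus its k-1 nearest neighbors by cosine
    distance in the embedding, and is rejected if it shares more than
    ``overlap_cap`` of its members with an already accepted metacell.
    Aggregated values are sums of binarized cell counts.

    *embed_peak_idx* restricts the internally computed TF-IDF embedding to
    a subset of peaks; scoring peaks that did not shape the neighborhoods
    (cross-fitting) avoids correlations induced by grouping cells on the
    very counts being tested.
    """
    n_cells = matrix.shape[1]
    if n_cells < k_neighbors:
        raise ValueError(f"{n_cells} cells < k_neighbors={k_neighbors}")
    binary = matrix.counts.astype(bool).astype(np.int8)
    if embedding is None:
        embed_rows = binary if embed_peak_idx is None else binary[np.asarray(embed_peak_idx)]
        embedding = _tfidf_embedding(embed_rows.T.tocsr(), seed=seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors, metric="cosine")
    nn.fit(embedding)
    _, neigh = nn.kneighbors(embedding)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    accepted: list[np.ndarray] = []
    member_count = np.zeros(n_cells, dtype=int)
    cap = int(np.floor(overlap_cap * k_neighbors))
    used_seed = np.zeros(n_cells, dtype=bool)
    for c in order:
        if used_seed[c]:
            continue
        cand = neigh[c]
        overlap = int((member_count[cand] > 0).sum())
        # approximate pairwise-overlap check via membership counts; exact
        # per-metacell check below only when the cheap bound fails
        if overlap > cap:
            ok = all(len(np.intersect1d(cand, m, assume_unique=False)) <= cap for m in accepted)
            if not ok:
                continue
        accepted.append(np.asarray(cand))
        member_count[cand] += 1
        used_seed[cand] = True

    if not accepted:
        raise ValueError("no metacell could be formed")
    agg = np.column_stack(
        [np.asarray(binary[:, m].sum(axis=1)).ravel() for m in accepted]
    ).astype(float)
    ages = np.array([c.age_group for c in matrix.cells])
    types = np.array([c.cluster for c in matrix.cells])
    donors = np.array([c.donor_id for c in matrix.cells])
    levels = (
        [("age", u) for u in np.unique(ages)[1:]]
        + [("type", u) for u in np.unique(types)[1:]]
        + [("donor", u) for u in np.unique(donors)[1:]]
    )
    arrays = {"age": ages, "type": types, "donor": donors}
    comp = np.zeros((len(accepted), len(levels)))
    for mi, m in enumerate(accepted):
        for li, (kind, u) in enumerate(levels):
            comp[mi, li] = np.mean(arrays[kind][m] == u)
    return MetacellMatrix(
        agg, matrix.peaks, [list(map(int, m)) for m in accepted], composition=comp
    )


# ---------------------------------------------------------------------------
# Distance-penalized graphical lasso (ADMM)


def penalized_inverse_covariance(
    S: np.ndarray,
    penalty: np.ndarray,
    mu: float = 1.0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Solve the graphical lasso with an entry-wise penalty matrix by ADMM.

    Maximizes log det T - tr(S T) - sum_{a!=b} penalty_ab |T_ab|.  The
    returned matrix is the soft-thresholded ADMM iterate, so entries driven
    to zero are exactly zero.  Diagonal entries are never penalized.
    """
    p = S.shape[0]
    pen = np.asarray(penalty, dtype=float).copy()
    np.fill_diagonal(pen, 0.0)
    Theta = np.eye(p)
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(max_iter):
        # Theta step: eigen decomposition of mu (Z - U) - S
        w, Q = np.linalg.eigh(mu * (Z - U) - S)
        theta_eig = (w + np.sqrt(w**2 + 4.0 * mu)) / (2.0 * mu)
        Theta = (Q * theta_eig) @ Q.T
        # Z step: entry-wise soft threshold
        Z_old = Z
        A = Theta + U
        Z = np.sign(A) * np.maximum(np.abs(A) - pen / mu, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U = U + Theta - Z
        r = np.linalg.norm(Theta - Z)
        s_res = mu * np.linalg.norm(Z - Z_old)
        scale = max(1.0, np.linalg.norm(Theta))
        if r / scale < tol and s_res / scale < tol:
            break
    return Z


def partial_correlations(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(theta), 1e-12, None))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return np.clip(pc, -1.0, 1.0)


def _depth_totals(metacells: MetacellMatrix, peak_idx: np.ndarray) -> np.ndarray:
    """Per-metacell depth totals over peaks OUTSIDE the scored window.

    Using out-of-window peaks avoids the compositional closure that exact
    within-window totals would impose (a hard sum constraint manifests as
    spurious negative partial correlations).  Falls back to all peaks when
    the window covers the whole peak set.
    """
    mask = np.ones(metacells.counts.shape[0], dtype=bool)
    mask[peak_idx] = False
    if mask.any():
        totals = metacells.counts[mask, :].sum(axis=0)
    else:
        totals = metacells.counts.sum(axis=0)
    totals = totals.astype(float)
    totals[totals == 0] = 1.0
    return totals


def _normalize_profiles(
    metacells: MetacellMatrix, peak_idx: np.ndarray, totals: np.ndarray
) -> np.ndarray:
    """Depth-normalize then z-score per peak; metacells x peaks."""
    med = np.median(totals)
    X = (metacells.counts[peak_idx, :] / totals[None, :] * med).T
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def window_coaccessibility(
    metacells: MetacellMatrix,
    window: tuple[str, int, int],
    lambda0: float,
    min_metacells: int = 10,
) -> list[tuple[tuple[str, str], float]]:
    """Co-accessibility scores for all peak pairs whose midpoints fall in
    *window* = (chrom, start, end).

    Scores are penalized partial correlations; zero entries of the sparse
    precision matrix yield a score of exactly 0.  Pairs spanning the window
    boundary are not scored by this window.
    """
    chrom, start, end = window
    idx = np.array(
        [
            i
            for i, pk in enumerate(metacells.peaks)
            if pk.chrom == chrom and start <= pk.midpoint < end
        ],
        dtype=int,
    )
    if len(idx) < 2:
        raise ValueError("window holds fewer than 2 peaks")
    if metacells.n_metacells < min_metacells:
        raise ValueError(f"need >= {min_metacells} metacells")
    totals = _depth_totals(metacells, idx)
    X = _normalize_profiles(metacells, idx, totals)
    n = X.shape[0]
    # unpenalized auxiliary nodes: depth plus metacell composition absorb
    # the group-level covariation that is not pairwise co-accessibility
    aux_cols = [np.log1p(totals)]
    if metacells.composition is not None:
        aux_cols.extend(metacells.composition.T)
    aux = []
    for col in aux_cols:
        sd = col.std()
        if sd > 0:
            aux.append((col - col.mean()) / sd)
    n_aux = len(aux)
    if n_aux:
        X = np.column_stack([X] + aux)
    S = (X.T @ X) / n
    mids = np.array([metacells.peaks[i].midpoint for i in idx])
    d = np.abs(mids[:, None] - mids[None, :])
    window_bp = float(end - start)
    penalty = np.zeros((len(idx) + n_aux, len(idx) + n_aux))
    penalty[: len(idx), : len(idx)] = lambda0 * np.sqrt(d / window_bp)
    if lambda0 == 0.0 and np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            "window covariance is near-singular with lambda0 = 0; raise lambda0"
        )
    theta = penalized_inverse_covariance(S, penalty)
    pc = partial_correlations(theta)
    out = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            pa, pb = metacells.peaks[idx[a]], metacells.peaks[idx[b]]
            key = tuple(sorted((pa.id, pb.id)))
            out.append((key, float(pc[a, b])))
    return out


def sliding_windows(peaks: PeakSet, window_bp: float, overlap: float = 0.5):
    """Tile each chromosome with windows of *window_bp* at 50% overlap."""
    spans: dict[str, list[float]] = {}
    for pk in peaks:
        spans.setdefault(pk.chrom, [np.inf, -np.inf])
        spans[pk.chrom][0] = min(spans[pk.chrom][0], pk.start)
        spans[pk.chrom][1] = max(spans[pk.chrom][1], pk.end)
    step = window_bp * (1.0 - overlap)
    windows = []
    for chrom, (lo, hi) in spans.items():
        pos = lo
        while pos < hi:
            windows.append((chrom, int(pos), int(pos + window_bp)))
            pos += step
    return windows


def calibrate_penalty(
    metacells: MetacellMatrix,
    window_bp: float,
    target_far_sparsity: float = 0.05,
    seed: int = 0,
    max_windows: int = 20,
    n_iter: int = 20,
) -> float:
    """Smallest lambda0 (bisection) such that, over a sample of windows, the
    fraction of nonzero partial correlations among pairs farther apart than
    window_bp/2 is <= *target_far_sparsity*."""
    rng = np.random.default_rng(seed)
    windows = sliding_windows(metacells.peaks, window_bp)
    usable = []
    for w in windows:
        chrom, start, end = w
        mids = [
            pk.midpoint
            for pk in metacells.peaks
            if pk.chrom == chrom and start <= pk.midpoint < end
        ]
        if len(mids) < 2:
            continue
        mids = np.array(mids)
        if np.max(mids) - np.min(mids) > window_bp / 2:
            usable.append(w)
    if not usable:
        raise CalibrationError("no window contains a far pair (> window_bp/2)")
    if len(usable) > max_windows:
        usable = [usable[i] for i in rng.choice(len(usable), max_windows, replace=False)]

    def far_fraction(lam: float) -> float:
        nonzero = 0
        total = 0
        for w in usable:
            for (a, b), score in window_coaccessibility(metacells, w, lam):
                pa = metacells.peaks[metacells.peaks.index_of(a)]
                pb = metacells.peaks[metacells.peaks.index_of(b)]
                if abs(pb.midpoint - pa.midpoint) > window_bp / 2:
                    total += 1
                    if score != 0.0:
                        nonzero += 1
        return nonzero / total if total else 0.0

    hi = 0.5
    for _ in range(12):
        if far_fraction(hi) <= target_far_sparsity:
            break
        hi *= 2.0
    lo = 0.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if far_fraction(mid) <= target_far_sparsity:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Ensemble runs and merging


def _peak_halves(peaks: PeakSet) -> np.ndarray:
    """Split peaks into two genome halves per chromosome (for cross-fitting)."""
    half = np.zeros(len(peaks), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for i, pk in enumerate(peaks):
        by_chrom.setdefault(pk.chrom, []).append(i)
    for idx in by_chrom.values():
        idx = sorted(idx, key=lambda i: peaks[i].midpoint)
        for r, i in enumerate(idx):
            if r >= len(idx) // 2:
                half[i] = 1
    return half


def _run_scores(
    mc_by_half: dict[int, MetacellMatrix],
    half: np.ndarray,
    peaks: PeakSet,
    window_bp: float,
    lambda0: float,
) -> dict:
    """One run: mean score per pair over all windows that scored it.

    Each window is scored with the metacell set whose embedding excluded
    the window's (majority) genome half.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for w in sliding_windows(peaks, window_bp):
        chrom, start, end = w
        members = [
            i for i, pk in enumerate(peaks) if pk.chrom == chrom and start <= pk.midpoint < end
        ]
        if len(members) < 2:
            continue
        h = int(round(np.mean(half[members])))
        try:
            pairs = window_coaccessibility(mc_by_half[h], w, lambda0)
        except ValueError:
            continue
        for key, score in pairs:
            sums[key] = sums.get(key, 0.0) + score
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def run_ensemble(
    matrix: PeakMatrix,
    subset_runs: int = 5,
    subset_size: int = 15000,
    seed: int = 0,
    k_neighbors: int = 50,
    cluster_window: float = 1e6,
    subset_window: float = 250_000.0,
    lambda0: float | None = None,
    include_cluster_runs: bool = True,
    target_metacells: int = 300,
) -> list[CoaccessLink]:
    """Ensemble of co-accessibility runs, merged into per-pair score arrays.

    One run per cell-type cluster (1 Mb windows) plus *subset_runs* runs on
    random subsets of min(subset_size, n_cells) cells (250 kb windows).
    Per-cluster and subset scores pool into a single array per link; set
    ``include_cluster_runs=False`` for subset-only arrays.

    Within each run the metacell size is n_run // target_metacells members
    (clamped to [5, k_neighbors]): the precision-matrix estimate needs a
    roughly scale-invariant number of aggregates, and at 15,000 cells this
    rule reproduces k = 50.  Clusters smaller than 10 * the minimum
    metacell size are skipped.
    """
    rng = np.random.default_rng(seed)
    n_cells = matrix.shape[1]

    def members_per_metacell(n: int) -> int:
        return int(np.clip(n // target_metacells, 5, k_neighbors))

    run_specs = []
    if include_cluster_runs:
        clusters = sorted({c.cluster for c in matrix.cells})
        for cl in clusters:
            idx = np.array([i for i, c in enumerate(matrix.cells) if c.cluster == cl])
            if len(idx) < 10 * 5:
                logger.info("cluster %s has %d cells; skipped", cl, len(idx))
                continue
            run_specs.append((idx, cluster_window))
    size = min(subset_size, n_cells)
    for _ in range(subset_runs):
        idx = rng.choice(n_cells, size=size, replace=False)
        run_specs.append((np.sort(idx), subset_window))

    merged: dict[tuple[str, str], list[float]] = {}
    lam = lambda0
    if lam is None:
        cal_mc = build_metacells(
            matrix, k_neighbors=members_per_metacell(n_cells), seed=seed + 999
        )
        lam = calibrate_penalty(cal_mc, subset_window, seed=seed)
        logger.info("calibrated lambda0 = %.4g", lam)
    half = _peak_halves(matrix.peaks)
    for r, (idx, window_bp) in enumerate(run_specs):
        sub = matrix.subset_cells(idx)
        mc_by_half = {
            h: build_metacells(
                sub,
                k_neighbors=members_per_metacell(len(idx)),
                seed=seed + 1000 + r,
                embed_peak_idx=np.flatnonzero(half != h),
            )
            for h in (0, 1)
        }
        for key, score in _run_scores(mc_by_half, half, matrix.peaks, window_bp, lam).items():
            merged.setdefault(key, []).append(score)

    links = []
    for (a, b), scores in sorted(merged.items()):
        pa = matrix.peaks[matrix.peaks.index_of(a)]
        pb = matrix.peaks[matrix.peaks.index_of(b)]
        links.append(CoaccessLink(pa, pb, np.array(scores)))
    return links


def test_links(links: list[CoaccessLink], alpha: float = 0.10, min_runs: int = 2) -> list[CoaccessLink]:
    """One-sample two-sided t-test of the per-run score array against 0.

    Links observed in fewer than *min_runs* runs are dropped.  A
    zero-variance array with nonzero mean is taken as p = 0 (retained);
    with zero mean, p = 1.
    """
    out = []
    for ln in links:
        if ln.n_runs < min_runs:
            continue
        scores = ln.scores
        if np.ptp(scores) == 0.0:
            if scores[0] == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(scores[0]), 0.0
        else:
            t, p = stats.ttest_1samp(scores, 0.0)
        ln.t_stat = float(t)
        ln.t_p = float(p)
        ln.retained = p < alpha
        out.append(ln)
    return out


def link_promoters(
    links: list[CoaccessLink],
    promoters: pd.DataFrame,
    min_score: float = 0.05,
    promoter_halfwidth: int = 500,
) -> pd.DataFrame:
    """Report retained links with mean score > *min_score* (strict) where
    exactly one anchor overlaps a protein-coding gene's promoter
    (TSS +/- promoter_halfwidth)."""
    rows = []
    for g in promoters.itertuples(index=False):
        if g.biotype != "protein_coding":
            logger.info("gene %s has biotype %s; skipped", g.gene, g.biotype)
            continue
        pstart, pend = g.tss - promoter_halfwidth, g.tss + promoter_halfwidth
        for ln in links:
            if not ln.retained or not (ln.mean_score > min_score):
                continue
            hits = [
                pk.chrom == g.chrom and pk.start < pend and pstart < pk.end
                for pk in (ln.peak_a, ln.peak_b)
            ]
            if sum(hits) != 1:
                continue
            promoter_peak, distal_peak = (
                (ln.peak_a, ln.peak_b) if hits[0] else (ln.peak_b, ln.peak_a)
            )
            rows.append(
                {
                    "gene": g.gene,
                    "promoter_peak": promoter_peak.id,
                    "distal_peak": distal_peak.id,
                    "mean_score": ln.mean_score,
                    "n_runs": ln.n_runs,
                    "t_p": ln.t_p,
                    "distance": ln.distance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "promoter_peak", "distal_peak", "mean_score", "n_runs", "t_p", "distance"],
    )
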