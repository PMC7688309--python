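"""Age-dynamic peak detection and temporal clustering.

Genome-wide detection sums cells into per-donor pseudobulk counts within
one cell type and fits, peak by peak, a negative-binomial log-linear model
(group + technical covariates + log-total offset).  Dispersions are
estimated by per-peak profile likelihood and shrunk 50/50 (on the log
scale) toward the trimmed mean across peaks, which stabilizes inference at
n = 3 donors per group; the group effect is assessed by a likelihood-ratio
test with Benjamini-Hochberg correction across peaks.  Peaks significant
in any pairwise age comparison form the age-dynamic union.

The union's loci-by-timepoint relative-accessibility profiles are
clustered by K-means over a K range, selecting K by the Davies-Bouldin
index DB = (1/K) sum_x max_{y != x} (s_x + s_y) / d_xy (lower is better).

Locus-restricted testing uses pooled-variance two-sample t-tests on
per-donor cell-fraction statistics, reported at raw p (no multiplicity
correction in this deliberately targeted mode).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import PeakMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkTable:
    """Per-donor summed counts (peaks x donors) within one cell type."""

    counts: np.ndarray
    peak_ids: list[str]
    donors: pd.DataFrame  # donor_id, age_group, sex, dataset_id, n_cells, total

    @property
    def offsets(self) -> np.ndarray:
        return np.log(self.donors["total"].to_numpy(dtype=float))


def pseudobulk(matrix: PeakMatrix, cell_type: str) -> PseudobulkTable:
    """Sum counts per donor over the cells of *cell_type*.

    Donors contributing zero cells of the type are excluded (logged).  The
    offset of each donor is the log of its total count over all peaks.
    """
    donors: dict[str, list[int]] = {}
    meta: dict[str, dict] = {}
    for i, c in enumerate(matrix.cells):
        if c.cluster != cell_type:
            continue
        donors.setdefault(c.donor_id, []).append(i)
        meta[c.donor_id] = {"age_group": c.age_group, "sex": c.sex}
    all_donors = {c.donor_id for c in matrix.cells}
    for d in sorted(all_donors - set(donors)):
        logger.info("donor %s has no %s cells; excluded from pseudobulk", d, cell_type)
    names = sorted(donors)
    cols = []
    rows = []
    for d in names:
        idx = np.asarray(donors[d])
        colsum = np.asarray(matrix.counts[:, idx].sum(axis=1)).ravel()
        cols.append(colsum)
        rows.append(
            {
                "donor_id": d,
                "age_group": meta[d]["age_group"],
                "sex": meta[d]["sex"],
                "dataset_id": d,
                "n_cells": len(idx),
                "total": int(colsum.sum()),
            }
        )
    counts = np.column_stack(cols) if cols else np.zeros((matrix.shape[0], 0), dtype=int)
    return PseudobulkTable(counts, [p.id for p in matrix.peaks], pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Negative-binomial inference (NB2: var = mu + alpha mu^2)


def _nb_loglik(y, mu, alpha):
    a_inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + a_inv)
            - gammaln(a_inv)
            - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - a_inv * np.log1p(alpha * mu)
        )
    )


def _fit_nb_glm(y, X, offset, alpha, max_iter=50, tol=1e-8):
    """IRLS fit of an NB log-linear model with fixed dispersion.

    Returns (beta, mu, loglik).
    """
    n, p = X.shape
    beta = np.zeros(p)
    # start from log of mean rate
    rate = max(np.mean(y / np.exp(offset)), 1e-8)
    beta[0] = np.log(rate)
    eta = X @ beta + offset
    mu = np.exp(eta)
    ll = -np.inf
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        ll_old = ll
        while True:
            eta = X @ (beta + step * (beta_new - beta)) + offset
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            ll = _nb_loglik(y, np.clip(mu, 1e-10, None), alpha)
            if np.isfinite(ll) and (ll >= ll_old - 1e-12 or step < 1e-4):
                break
            step /= 2.0
        beta = beta + step * (beta_new - beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
    return beta, mu, ll


def _profile_dispersion(y, X, offset, bounds=(-8.0, 4.0)):
    """Log dispersion maximizing the Cox-Reid adjusted profile likelihood.

    The adjustment (-1/2 log det X'WX) removes most of the downward bias of
    the plain profile MLE when the mean model consumes a large share of the
    few pseudobulk replicates.
    """

    def neg(loga):
        alpha = float(np.exp(loga))
        _, mu, ll = _fit_nb_glm(y, X, offset, alpha)
        w = mu / (1.0 + alpha * mu)
        sign, logdet = np.linalg.slogdet((X.T * w) @ X)
        if sign <= 0:
            return -ll
        return -(ll - 0.5 * logdet)

    res = optimize.minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": 0.05}
    )
    return float(res.x)


def _common_dispersion(counts, peak_indices, X, offset, bounds=(-8.0, 4.0)) -> float:
    """Common log dispersion: maximizer of the summed Cox-Reid APL."""

    def neg(loga):
        alpha = float(np.exp(loga))
        total = 0.0
        for i in peak_indices:
            y = counts[i].astype(float)
            _, mu, ll = _fit_nb_glm(y, X, offset, alpha)
            w = mu / (1.0 + alpha * mu)
            sign, logdet = np.linalg.slogdet((X.T * w) @ X)
            total += ll - (0.5 * logdet if sign > 0 else 0.0)
        return -total

    res = optimize.minimize_scalar(neg, bounds=bounds, method="bounded", options={"xatol": 0.02})
    return float(res.x)


def _design(donors: pd.DataFrame, groupA, groupB, covariates):
    """Build (X_full, X_reduced, y-mask) for one pairwise comparison.

    Columns are added in order intercept, covariates, group; any column that
    does not increase the design rank (or would exhaust residual df) is
    dropped — a dataset_id that is one-per-donor disappears here.
    """
    sel = donors["age_group"].isin([groupA, groupB]).to_numpy()
    sub = donors.loc[sel]
    if (sub["age_group"] == groupA).sum() < 2 or (sub["age_group"] == groupB).sum() < 2:
        raise ValueError("need >= 2 donors per group")
    n = len(sub)
    cols_red = [np.ones(n)]
    for cov in covariates:
        if cov not in sub.columns:
            continue
        dummies = pd.get_dummies(sub[cov], drop_first=True, dtype=float)
        for c in dummies.columns:
            cand = dummies[c].to_numpy()
            trial = np.column_stack(cols_red + [cand])
            if (
                np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(np.column_stack(cols_red))
                and trial.shape[1] <= n - 2  # keep df for group + residual
            ):
                cols_red.append(cand)
            else:
                logger.debug("covariate column %s=%s dropped (collinear)", cov, c)
    group = (sub["age_group"] == groupB).to_numpy(dtype=float)
    X_red = np.column_stack(cols_red)
    X_full = np.column_stack(cols_red + [group])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_red):
        raise ValueError("group indicator collinear with covariates")
    return X_full, X_red, sel


def nb_pairwise_test(
    pb: PseudobulkTable,
    groupA: str,
    groupB: str,
    covariates: tuple[str, ...] = ("sex", "dataset_id"),
    shrink_weight: float = 0.5,
    common_subsample: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-peak NB LRT for groupA vs groupB with shrunk dispersions.

    Per-peak Cox-Reid dispersion estimates are shrunk 50/50 (log scale)
    toward the common dispersion (maximizer of the summed adjusted profile
    likelihood over a subsample of peaks) and floored at it: with three
    donors per group the per-peak estimate is too noisy downward, and an
    underestimated dispersion is the dominant source of false positives.

    Returns a DataFrame (peak_id, log_fc, p, fdr) over peaks with any
    nonzero count in the compared donors; log_fc is the natural-log fold
    change of groupB relative to groupA.
    """
    X_full, X_red, sel = _design(pb.donors, groupA, groupB, covariates)
    counts = pb.counts[:, sel]
    offset = np.log(pb.donors.loc[sel, "total"].to_numpy(dtype=float))
    nonzero = counts.sum(axis=1) > 0
    idx = np.flatnonzero(nonzero)
    if idx.size == 0:
        return pd.DataFrame(columns=["peak_id", "log_fc", "p", "fdr"])

    log_disp = np.array(
        [_profile_dispersion(counts[i].astype(float), X_full, offset) for i in idx]
    )
    rng = np.random.default_rng(seed)
    sub = idx if idx.size <= common_subsample else rng.choice(idx, common_subsample, replace=False)
    common = _common_dispersion(counts, sub, X_full, offset)
    shrunk = np.exp(
        np.maximum((1.0 - shrink_weight) * log_disp + shrink_weight * common, common)
    )

    rows = []
    for k, i in enumerate(idx):
        y = counts[i].astype(float)
        alpha = float(shrunk[k])
        beta_full, _, ll_full = _fit_nb_glm(y, X_full, offset, alpha)
        _, _, ll_red = _fit_nb_glm(y, X_red, offset, alpha)
        lr = max(0.0, 2.0 * (ll_full - ll_red))
        p = stats.chi2.sf(lr, df=1)
        rows.append({"peak_id": pb.peak_ids[i], "log_fc": float(beta_full[-1]), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def age_dynamic_union(results: list[pd.DataFrame], fdr: float = 0.05) -> set[str]:
    """Union over pairwise comparisons of peaks with FDR < *fdr*."""
    union: set[str] = set()
    for df in results:
        union |= set(df.loc[df["fdr"] < fdr, "peak_id"])
    return union


# ---------------------------------------------------------------------------
# Davies-Bouldin K selection


@dataclass
class DBSelection:
    k: int
    labels: np.ndarray
    db_by_k: dict[int, float]


def db_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with Euclidean metric.

    s_x is the mean distance of cluster x's members to its centroid; d_xy
    the centroid distance; R_xy = (s_x + s_y)/d_xy; DB the mean over
    clusters of the worst R.  Coincident centroids give DB = +inf.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    centroids = np.array([points[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [
            np.mean(np.linalg.norm(points[labels == u] - centroids[k], axis=1))
            for k, u in enumerate(uniq)
        ]
    )
    K = len(uniq)
    worst = np.empty(K)
    for x in range(K):
        r_best = -np.inf
        for y in range(K):
            if y == x:
                continue
            d = np.linalg.norm(centroids[x] - centroids[y])
            r = np.inf if d == 0 else (scatter[x] + scatter[y]) / d
            r_best = max(r_best, r)
        worst[x] = r_best
    return float(np.mean(worst))


def select_k_kmeans(
    profiles: np.ndarray,
    k_range: tuple[int, int] = (5, 8),
    seed: int = 0,
    restarts: int = 20,
) -> DBSelection:
    """K-means over unit-sum-scaled rows; K = argmin Davies-Bouldin.

    *k_range* is inclusive; ties break toward the smaller K.  Rows are
    scaled to unit sum before clustering (profile shape, not magnitude).
    """
    profiles = np.asarray(profiles, dtype=float)
    k_lo, k_hi = k_range
    if profiles.shape[0] < k_hi:
        raise ValueError(f"{profiles.shape[0]} rows < max K {k_hi}")
    row_sums = profiles.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("profiles must have positive row sums")
    X = profiles / row_sums

    best = None
    db_by_k = {}
    for K in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
        labels = km.fit_predict(X)
        db = db_index(X, labels)
        db_by_k[K] = db
        if best is None or db < best[0] - 1e-12:
            best = (db, K, labels)
    return DBSelection(k=best[1], labels=best[2], db_by_k=db_by_k)


# ---------------------------------------------------------------------------
# Locus-restricted t-tests


def locus_ttest(
    fractions: pd.DataFrame,
    age_pairs: list[tuple[str, str]] | None = None,
    value_col: str = "s",
) -> pd.DataFrame:
    """Equal-variance two-sample t-tests on per-donor fraction statistics.

    *fractions* needs columns peak_id, donor_id, age_group and the value
    column (default the within-donor score s).  Raw p-values are reported
    (locus-restricted mode is deliberately uncorrected).  Zero pooled
    variance gives p = 1 for equal means, p = 0 otherwise.
    """
    if age_pairs is None:
        ages = [a for a in ("30wkGA", "3yo", "30yo") if a in set(fractions["age_group"])]
        age_pairs = list(itertools.combinations(ages, 2))
    rows = []
    for peak_id, sub in fractions.groupby("peak_id", sort=True):
        for ga, gb in age_pairs:
            a = sub.loc[sub["age_group"] == ga, value_col].to_numpy(dtype=float)
            b = sub.loc[sub["age_group"] == gb, value_col].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"peak {peak_id}: need >= 2 donors per group")
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                if a[0] == b[0]:
                    t, p = 0.0, 1.0
                else:
                    t = np.inf * np.sign(a.mean() - b.mean())
                    p = 0.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {
                    "peak_id": peak_id,
                    "group_a": ga,
                    "group_b": gb,
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < 0.05),
                }
            )
    return pd.DataFrame(rows)
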