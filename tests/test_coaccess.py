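import numpy as np
import pytest

from screg import coaccess
from screg.coaccess import (
    CalibrationError,
    CoaccessLink,
    MetacellMatrix,
    build_metacells,
    calibrate_penalty,
    link_promoters,
    partial_correlations,
    penalized_inverse_covariance,
    window_coaccessibility,
)
from screg.io import Peak
from conftest import make_cells, make_matrix, make_peaks
import pandas as pd


# ---------------------------------------------------------------------------
# Independent oracle: proximal-gradient (ISTA) solver for the same objective


def _ista_glasso(S, penalty, steps=30000, lr=None):
    """Proximal-gradient solve of min -logdet T + tr(ST) + sum rho|T_od|."""
    p = S.shape[0]
    pen = penalty.copy()
    np.fill_diagonal(pen, 0.0)
    T = np.eye(p)
    if lr is None:
        lr = 0.1 / np.linalg.norm(S, 2) ** 2
    for _ in range(steps):
        grad = S - np.linalg.inv(T)
        A = T - lr * grad
        Z = np.sign(A) * np.maximum(np.abs(A) - lr * pen, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        # backtrack to stay positive definite
        w = np.linalg.eigvalsh(Z)
        if w.min() <= 1e-10:
            lr *= 0.5
            continue
        T = Z
    return T


class TestPenalizedSolver:
    @pytest.mark.parametrize("p,seed", [(2, 0), (3, 1), (4, 2), (4, 3)])
    def test_matches_independent_proximal_gradient_oracle(self, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, p))
        X[:, -1] += 0.7 * X[:, 0]  # induce structure
        X = (X - X.mean(0)) / X.std(0)
        S = X.T @ X / len(X)
        penalty = rng.uniform(0.02, 0.2, size=(p, p))
        penalty = (penalty + penalty.T) / 2
        ours = partial_correlations(penalized_inverse_covariance(S, penalty, tol=1e-9))
        oracle = partial_correlations(_ista_glasso(S, penalty))
        assert np.allclose(ours, oracle, atol=1e-3)

    def test_scores_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 6))
        S = X.T @ X / 40
        pc = partial_correlations(penalized_inverse_covariance(S, np.full((6, 6), 0.05)))
        assert np.allclose(pc, pc.T)
        assert np.all(np.abs(pc) <= 1.0)


def _metacells_from_profiles(profiles, gap=4000):
    """profiles: peaks x metacells array placed on evenly spaced peaks."""
    n_peaks = profiles.shape[0]
    return MetacellMatrix(
        counts=np.asarray(profiles, dtype=float),
        peaks=make_peaks(n_peaks, gap=gap),
        members=[[i] for i in range(profiles.shape[1])],
    )


class TestWindowCoaccessibility:
    def test_identical_profiles_score_high(self):
        # two identical peaks next to each other plus independent company
        # (with only the pair present, depth normalization is degenerate)
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0, size=200) + 1.0
        noise = rng.poisson(5.0, size=(28, 200)).astype(float) + 1.0
        profiles = np.vstack([base, base, noise])
        mc = _metacells_from_profiles(profiles, gap=500)
        out = dict(window_coaccessibility(mc, ("chr1", 0, 250000), lambda0=0.05))
        assert out[("p0", "p1")] > 0.9

    def test_independent_profiles_score_near_zero(self):
        rng = np.random.default_rng(1)
        profiles = rng.poisson(5.0, size=(30, 200)).astype(float) + 1.0
        mc = _metacells_from_profiles(profiles, gap=500)
        # window holds the first 10 peaks; the rest estimate depth
        out = dict(window_coaccessibility(mc, ("chr1", 0, 10000), lambda0=0.05))
        assert abs(out[("p0", "p1")]) < 0.1

    def test_no_self_pairs_and_window_restriction(self):
        rng = np.random.default_rng(2)
        profiles = rng.poisson(4.0, size=(5, 50)).astype(float)
        mc = _metacells_from_profiles(profiles, gap=4000)
        out = window_coaccessibility(mc, ("chr1", 0, 10**6), lambda0=0.2)
        keys = [k for k, _ in out]
        assert all(a != b for a, b in keys)
        assert len(keys) == len(set(keys)) == 10  # 5 choose 2

    def test_too_few_metacells_rejected(self):
        profiles = np.ones((2, 5))
        mc = _metacells_from_profiles(profiles)
        with pytest.raises(ValueError):
            window_coaccessibility(mc, ("chr1", 0, 10**6), lambda0=0.1)


class TestCalibratePenalty:
    def _independent_metacells(self, n_peaks=30, n_mc=150, seed=0):
        rng = np.random.default_rng(seed)
        profiles = rng.poisson(4.0, size=(n_peaks, n_mc)).astype(float)
        return _metacells_from_profiles(profiles, gap=9000)

    def test_far_sparsity_satisfied_after_calibration(self):
        mc = self._independent_metacells()
        window_bp = 125000.0
        lam = calibrate_penalty(mc, window_bp, seed=0)
        nonzero = far = 0
        for w in coaccess.sliding_windows(mc.peaks, window_bp):
            try:
                pairs = window_coaccessibility(mc, w, lam)
            except ValueError:
                continue
            for (a, b), score in pairs:
                pa = mc.peaks[mc.peaks.index_of(a)]
                pb = mc.peaks[mc.peaks.index_of(b)]
                if abs(pb.midpoint - pa.midpoint) > window_bp / 2:
                    far += 1
                    nonzero += score != 0.0
        assert far > 0
        assert nonzero / far <= 0.05 + 1e-9

    def test_penalty_monotonicity(self):
        mc = self._independent_metacells(seed=3)
        w = ("chr1", 0, 200000)

        def n_nonzero(lam):
            return sum(s != 0.0 for _, s in window_coaccessibility(mc, w, lam))

        lam = 0.1
        assert n_nonzero(2 * lam) <= n_nonzero(lam)

    def test_no_far_pair_raises(self):
        profiles = np.ones((1, 30))
        mc = _metacells_from_profiles(profiles)
        with pytest.raises(CalibrationError):
            calibrate_penalty(mc, 125000.0)


class TestBuildMetacells:
    def test_identical_cells_aggregate_to_k_times_value(self):
        counts = np.tile(np.array([[1], [0], [2]]), (1, 100))
        m = make_matrix(counts, cells=make_cells(100))
        mc = build_metacells(m, k_neighbors=50, seed=0)
        assert all(len(mm) == 50 for mm in mc.members)
        # binarized: peak0 -> 50, peak1 -> 0, peak2 -> 50
        assert np.all(mc.counts[0] == 50)
        assert np.all(mc.counts[1] == 0)
        assert np.all(mc.counts[2] == 50)

    def test_determinism(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(0.5, size=(40, 200))
        m = make_matrix(counts)
        a = build_metacells(m, k_neighbors=20, seed=5)
        b = build_metacells(m, k_neighbors=20, seed=5)
        assert a.members == b.members

    def test_separated_populations_not_mixed(self):
        rng = np.random.default_rng(8)
        n = 150
        pop1 = rng.binomial(1, 0.8, size=(20, n)) * rng.poisson(2, size=(20, n))
        pop2 = rng.binomial(1, 0.05, size=(20, n))
        top = np.concatenate([pop1, np.zeros_like(pop2)], axis=1)
        bottom = np.concatenate([np.zeros_like(pop1), pop2 * 0 + rng.binomial(1, 0.8, size=(20, n))], axis=1)
        counts = np.vstack([top, bottom]).astype(int)
        m = make_matrix(counts, cells=make_cells(2 * n))
        mc = build_metacells(m, k_neighbors=30, seed=0)
        for members in mc.members:
            members = np.asarray(members)
            frac1 = np.mean(members < n)
            assert frac1 in (0.0, 1.0)

    def test_too_few_cells_rejected(self):
        m = make_matrix(np.ones((3, 10), dtype=int))
        with pytest.raises(ValueError):
            build_metacells(m, k_neighbors=50)


class TestTestLinks:
    def _link(self, scores):
        a = Peak("chr1", 0, 100, "a")
        b = Peak("chr1", 5000, 5100, "b")
        return CoaccessLink(a, b, np.asarray(scores, dtype=float))

    def test_hand_computed_t_statistic(self):
        (ln,) = coaccess.test_links([self._link([0.2, 0.25, 0.18, 0.22, 0.21])])
        assert ln.t_stat == pytest.approx(18.316, abs=0.01)
        assert ln.t_p < 0.001
        assert ln.retained

    def test_zero_mean_not_retained(self):
        (ln,) = coaccess.test_links([self._link([0.1, -0.1, 0.05, -0.05, 0.0])])
        assert ln.t_stat == pytest.approx(0.0, abs=1e-12)
        assert not ln.retained

    def test_single_observation_dropped(self):
        assert coaccess.test_links([self._link([0.3])]) == []

    def test_zero_variance_nonzero_mean_retained(self):
        (ln,) = coaccess.test_links([self._link([0.2, 0.2, 0.2])])
        assert ln.t_p == 0.0 and ln.retained

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(9)
        links = [self._link(rng.normal(0.05, 0.1, size=5)) for _ in range(50)]
        strict = {ln.pair for ln in coaccess.test_links(list(links), alpha=0.05) if ln.retained}
        loose = {ln.pair for ln in coaccess.test_links(list(links), alpha=0.20) if ln.retained}
        assert strict <= loose


class TestLinkPromoters:
    def _setup(self, mean):
        a = Peak("chr1", 900, 1300, "prom_peak")  # overlaps promoter at tss=1000
        b = Peak("chr1", 50000, 50400, "distal")
        ln = CoaccessLink(a, b, np.full(4, mean))
        ln.retained = True
        ln.t_p = 0.01
        promoters = pd.DataFrame(
            [{"gene": "g1", "chrom": "chr1", "tss": 1000, "strand": "+", "biotype": "protein_coding"}]
        )
        return ln, promoters

    def test_above_threshold_reported(self):
        ln, prom = self._setup(0.06)
        out = link_promoters([ln], prom)
        assert list(out["gene"]) == ["g1"]
        assert out["distal_peak"].iloc[0] == "distal"

    def test_exactly_at_threshold_excluded(self):
        ln, prom = self._setup(0.05)
        assert link_promoters([ln], prom).empty

    def test_both_anchors_in_promoter_excluded(self):
        a = Peak("chr1", 600, 900, "a")
        b = Peak("chr1", 1100, 1400, "b")
        ln = CoaccessLink(a, b, np.full(4, 0.2))
        ln.retained = True
        prom = pd.DataFrame(
            [{"gene": "g1", "chrom": "chr1", "tss": 1000, "strand": "-", "biotype": "protein_coding"}]
        )
        assert link_promoters([ln], prom).empty

    def test_non_coding_gene_skipped(self):
        ln, prom = self._setup(0.2)
        prom["biotype"] = "lincRNA"
        assert link_promoters([ln], prom).empty

    def test_unretained_excluded(self):
        ln, prom = self._setup(0.2)
        ln.retained = False
        assert link_promoters([ln], prom).empty


@pytest.fixture(scope="module")
def small_cohort():
    from screg.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_peaks=60,
        cells_per_donor=80,
        n_coaccess_modules=2,
        module_size=3,
        n_dynamic_peaks=10,
        n_genes=8,
        genome_length=500_000,
        n_nuclei_per_donor=20,
    )
    return simulate_cohort(cfg, 5)


class TestRunEnsemble:

    def test_determinism_and_run_count(self, small_cohort):
        m, _, _ = small_cohort
        links1 = coaccess.run_ensemble(m, seed=4, subset_runs=2)
        links2 = coaccess.run_ensemble(m, seed=4, subset_runs=2)
        assert [ln.pair for ln in links1] == [ln.pair for ln in links2]
        assert all(np.allclose(a.scores, b.scores) for a, b in zip(links1, links2))
        n_clusters = len({c.cluster for c in m.cells})
        assert all(ln.n_runs <= n_clusters + 2 for ln in links1)
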