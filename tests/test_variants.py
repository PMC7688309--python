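import itertools

import numpy as np
import pandas as pd
import pytest

from screg.io import PWM, VariantRecord
from screg.variants import (
    KmerWeightTable,
    _BASE_INDEX,
    _SCALE,
    _int_score_matrix,
    delta_null_test,
    delta_score,
    filter_variants,
    is_common,
    overlap_annotate,
    pwm_best_hits,
    revcomp,
    scan_variant_motifs,
)
from conftest import make_peaks


def consensus_pwm(consensus, p=1.0):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = p
    return PWM(consensus, mat)


class TestFilters:
    def test_singletons_removed(self):
        vs = [
            VariantRecord("chr1", 10, "A", "C", 1),
            VariantRecord("chr1", 20, "A", "C", 2),
        ]
        assert [v.pos for v in filter_variants(vs)] == [20]

    def test_indel_length_rule(self):
        vs = [
            VariantRecord("chr1", 10, "A", "ACGTT", 5),  # 4-bp insertion: out
            VariantRecord("chr1", 20, "A", "ACGT", 5),  # 3-bp insertion: kept
            VariantRecord("chr1", 30, "ACGTT", "A", 5),  # 4-bp deletion: out
            VariantRecord("chr1", 40, "G", "T", 5),  # SNV always passes
        ]
        assert [v.pos for v in filter_variants(vs)] == [20, 40]

    def test_empty_input(self):
        assert filter_variants([]) == []


class TestIsCommon:
    def test_one_common_population_suffices(self):
        v = VariantRecord("chr1", 10, "G", "A", 12, {"eas": 0.005, "eur": 0.45})
        assert is_common(v) is True

    def test_boundary_is_strict(self):
        v = VariantRecord("chr1", 10, "G", "A", 12, {"eur": 0.01, "eas": 0.01})
        assert is_common(v) is False

    def test_frequency_is_folded(self):
        v = VariantRecord("chr1", 10, "G", "A", 12, {"eur": 0.995})
        assert is_common(v) is False
        v2 = VariantRecord("chr1", 10, "G", "A", 12, {"eur": 0.9})
        assert is_common(v2) is True

    def test_missing_data_is_missing(self):
        assert is_common(VariantRecord("chr1", 10, "G", "A", 12, {})) is None


class TestPWMBestHits:
    def test_point_mass_consensus_probability(self):
        pwm = consensus_pwm("ACG")
        hits = pwm_best_hits("TTACGTT", pwm, p_threshold=0.02)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].score_bits == pytest.approx(6.0)
        assert fwd[0].p == pytest.approx(1 / 64)

    def test_reverse_strand_scores_identically(self):
        pwm = consensus_pwm("ACG")
        hits = pwm_best_hits(revcomp("TTACGTT"), pwm, p_threshold=0.02)
        rev = [h for h in hits if h.strand == "-"]
        assert len(rev) == 1
        assert rev[0].score_bits == pytest.approx(6.0)
        assert rev[0].p == pytest.approx(1 / 64)

    def test_no_hits_below_threshold(self):
        pwm = consensus_pwm("AAAA")
        assert pwm_best_hits("CCCCCCCC", pwm, p_threshold=1e-4) == []

    def test_offsets_with_n_skipped(self):
        pwm = consensus_pwm("ACG")
        hits = pwm_best_hits("ANACGT", pwm, p_threshold=0.02)
        assert all(h.offset >= 2 for h in hits)

    @pytest.mark.parametrize("width,seed", [(4, 0), (6, 1)])
    def test_exact_p_matches_brute_force_enumeration(self, width, seed):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet(np.full(4, 0.7), size=width)
        bg = rng.dirichlet(np.full(4, 5.0))
        pwm = PWM("r", mat, bg)
        ints = _int_score_matrix(pwm)
        # brute force: enumerate all 4^w words with background probabilities
        scores = {}
        for word in itertools.product(range(4), repeat=width):
            s = int(sum(ints[i, b] for i, b in enumerate(word)))
            pr = float(np.prod([bg[b] for b in word]))
            scores[s] = scores.get(s, 0.0) + pr
        uniq = sorted(scores)
        for probe in uniq[:: max(1, len(uniq) // 7)]:
            brute_tail = sum(p for s, p in scores.items() if s >= probe)
            seq = "".join(
                "ACGT"[b]
                for b in max(
                    (w for w in itertools.product(range(4), repeat=width)
                     if sum(ints[i, c] for i, c in enumerate(w)) == probe),
                    key=lambda w: 0,
                )
            )
            hits = pwm_best_hits(seq, pwm, p_threshold=1.1)
            fwd = [h for h in hits if h.strand == "+" and h.offset == 0]
            assert fwd[0].p == pytest.approx(brute_tail, rel=1e-9)


GENOME = {"chr1": "TTTTTTTTTTACGTTTTTTTTTTTTTTTTTTT"}
#                   0123456789^ pos0=10 is 'A' (1-based 11)


class TestScanVariantMotifs:
    def test_disrupting_variant_detected_on_ref_only(self):
        pwm = consensus_pwm("ACG")
        v = VariantRecord("chr1", 12, "C", "T", 5)  # breaks ACG at pos0 10-12
        res = scan_variant_motifs(v, GENOME, [pwm], p_threshold=0.02)
        assert res["ref_hits"] and not res["alt_hits"]
        assert res["allelic_binding"] is True

    def test_either_allele_rule(self):
        pwm = consensus_pwm("ACG")
        v = VariantRecord("chr1", 11, "A", "G", 5)  # alt creates GCG: no hit
        res = scan_variant_motifs(v, GENOME, [pwm], p_threshold=0.02)
        assert res["allelic_binding"] is True  # ref allele still hits

    def test_no_placement_no_binding(self):
        pwm = consensus_pwm("GGGG")
        v = VariantRecord("chr1", 20, "T", "A", 5)
        res = scan_variant_motifs(v, GENOME, [pwm], p_threshold=1e-4)
        assert res["allelic_binding"] is False

    def test_out_of_bounds_rejected(self):
        pwm = consensus_pwm("ACG")
        v = VariantRecord("chr1", 1000, "A", "C", 5)
        with pytest.raises(ValueError):
            scan_variant_motifs(v, GENOME, [pwm])


def _delta_genome(seq="T" * 40):
    return {"chr1": seq}


class TestDeltaScore:
    def _table(self, weights, k=11):
        return KmerWeightTable(weights, k=k, use_revcomp=False)

    def _full_table(self, genome, variant, k=11, value=0.0):
        """Table covering both allele windows with constant weight."""
        from screg.variants import _window_kmers

        weights = {}
        for allele in (variant.ref, variant.alt):
            for km in _window_kmers(genome, variant, allele, k):
                weights[km] = value
        return weights

    def test_all_zero_weights_zero_delta(self):
        genome = _delta_genome("TACGTACGTACGTACGTACGTACGTACGTACG")
        v = VariantRecord("chr1", 16, "A", "C", 5)
        table = self._table(self._full_table(genome, v))
        assert delta_score(v, genome, table) == 0.0

    def test_single_ref_only_kmer_weight(self):
        from screg.variants import _window_kmers

        genome = _delta_genome("TACGTACGTACGTACGTACGTACGTACGTACG")
        v = VariantRecord("chr1", 16, "A", "C", 5)
        weights = self._full_table(genome, v)
        ref_only = set(_window_kmers(genome, v, v.ref, 11)) - set(
            _window_kmers(genome, v, v.alt, 11)
        )
        km = sorted(ref_only)[0]
        weights[km] = 2.5
        assert delta_score(v, genome, self._table(weights)) == pytest.approx(-2.5)

    def test_antisymmetry_under_allele_swap(self):
        rng = np.random.default_rng(0)
        genome = _delta_genome("".join(rng.choice(list("ACGT"), 60)))
        v = VariantRecord("chr1", 30, genome["chr1"][29], "A" if genome["chr1"][29] != "A" else "G", 5)
        weights = self._full_table(genome, v)
        for km in weights:
            weights[km] = float(rng.standard_normal())
        sw = VariantRecord("chr1", 30, v.alt, v.ref, 5)
        table = self._table(weights)
        assert delta_score(v, genome, table) == pytest.approx(
            -delta_score(sw, genome, table), rel=1e-12
        )

    def test_missing_kmer_named_in_error(self):
        genome = _delta_genome("TACGTACGTACGTACGTACGTACGTACGTACG")
        v = VariantRecord("chr1", 16, "A", "C", 5)
        with pytest.raises(ValueError, match="[ACGT]{11}"):
            delta_score(v, genome, self._table({"A" * 11: 1.0}))

    def test_indel_rejected(self):
        v = VariantRecord("chr1", 16, "AC", "A", 5)
        with pytest.raises(ValueError):
            delta_score(v, _delta_genome(), self._table({"A" * 11: 1.0}))


class TestDeltaNullTest:
    def _setup(self, n_var=40, seed=0):
        rng = np.random.default_rng(seed)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        variants = []
        for _ in range(n_var):
            pos0 = int(rng.integers(20, 4980))
            ref = genome["chr1"][pos0]
            alt = "ACGT"[(_BASE_INDEX[ref] + 1) % 4]
            variants.append(VariantRecord("chr1", pos0 + 1, ref, alt, 5))
        from screg.variants import _window_kmers

        weights = {}
        for v in variants:
            for allele in (v.ref, v.alt):
                for km in _window_kmers(genome, v, allele, 11):
                    weights[km] = float(rng.standard_normal())
        table = KmerWeightTable(weights, use_revcomp=False)
        return genome, variants, table

    def test_equal_weights_give_missing_z(self):
        genome, variants, table = self._setup()
        for km in table.weights:
            table.weights[km] = 1.0
        res = delta_null_test(variants, genome, table, n_perm=20, seed=0)
        assert res["z"].isna().all()

    def test_determinism(self):
        genome, variants, table = self._setup(seed=1)
        a = delta_null_test(variants, genome, table, n_perm=30, seed=7)
        b = delta_null_test(variants, genome, table, n_perm=30, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_significant_set_shrinks_with_fdr(self):
        genome, variants, table = self._setup(seed=2)
        res_strict = delta_null_test(variants, genome, table, n_perm=50, seed=1, fdr=0.01)
        res_loose = delta_null_test(variants, genome, table, n_perm=50, seed=1, fdr=0.2)
        strict = set(res_strict.loc[res_strict["significant"], "variant"])
        loose = set(res_loose.loc[res_loose["significant"], "variant"])
        assert strict <= loose


class TestOverlapAnnotate:
    def test_boundary_convention(self):
        peaks = make_peaks(1)  # p0: [1000, 1400)
        inside_first = VariantRecord("chr1", 1001, "A", "C", 5)  # pos0 = 1000
        outside_end = VariantRecord("chr1", 1401, "A", "C", 5)  # pos0 = 1400
        at_end = VariantRecord("chr1", 1400, "A", "C", 5)  # pos0 = 1399: inside
        out = overlap_annotate([inside_first, outside_end, at_end], peaks)
        assert set(out["variant"]) == {inside_first.key, at_end.key}

    def test_cell_types_and_ppa_carried(self):
        peaks = make_peaks(1)
        v = VariantRecord("chr1", 1100, "A", "C", 5, ppa=0.42)
        out = overlap_annotate([v], peaks, {"p0": ["AT2", "club"]})
        assert out["cell_types"].iloc[0] == "AT2,club"
        assert out["ppa"].iloc[0] == 0.42

    def test_variant_between_peaks_unannotated(self):
        peaks = make_peaks(2)
        v = VariantRecord("chr1", 2000, "A", "C", 5)
        assert overlap_annotate([v], peaks).empty
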