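"""Differential peaks and motif enrichment: BH step-up, hypergeometric
oracle for the Fisher test, fold-change semantics, null validity and
planted-motif power."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synprom.diffenrich import (
    bh_adjust,
    motif_enrichment,
    select_differential_peaks,
    _two_proportion_chi2,
)
from synprom.formats import CountMatrix
from synprom.simulate import plant_motifs, random_library, simulate_background


def hypergeom_tail(n_t, N_t, n_b, N_b):
    """Oracle: P(X >= n_t) for X ~ Hypergeom drawing N_t of N_t+N_b items
    of which n_t+n_b are marked — the one-sided Fisher p by enumeration."""
    K = n_t + n_b
    N = N_t + N_b
    denom = comb(N, N_t)
    return sum(
        comb(K, k) * comb(N - K, N_t - k) for k in range(n_t, min(K, N_t) + 1)
    ) / denom


def make_cm(target_counts, ref_counts):
    n = len(target_counts)
    counts = pd.DataFrame(
        {"t1": target_counts, "r1": ref_counts},
        index=[f"pk{i}" for i in range(n)],
    )
    return CountMatrix(counts, {"t1": "target", "r1": "reference"})


class TestBH:
    def test_step_up_formula(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_on_random_vectors(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=40)
        got = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(got, ref)

    def test_q_at_least_p(self):
        p = np.random.default_rng(3).uniform(size=30)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestTwoProportionChi2:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scipy_chi2_contingency(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (rng.integers(1, 200, size=25) for _ in range(4))
        got = _two_proportion_chi2(a, b, c, d)
        for i in range(25):
            ref = stats.chi2_contingency(
                [[a[i], b[i]], [c[i], d[i]]], correction=True
            ).pvalue
            assert got[i] == pytest.approx(ref, rel=1e-10)


class TestSelectDifferentialPeaks:
    def test_log2_fc_uses_half_count_stabilizer(self):
        # equal library sizes; CPM means are proportional to raw counts
        cm = make_cm([40, 30, 30], [10, 60, 30])
        res = {r.peak_id: r for r in select_differential_peaks(cm)}
        cpm = 1e6 / 100  # both libraries total 100
        expected = np.log2((40 * cpm + 0.5) / (10 * cpm + 0.5))
        assert res["pk0"].log2_fc == pytest.approx(expected)

    def test_identical_conditions_all_unchanged(self):
        cm = make_cm([40, 10, 50], [40, 10, 50])
        assert all(r.call == "unchanged" for r in select_differential_peaks(cm))

    def test_label_swap_negates_fold_changes(self):
        rng = np.random.default_rng(8)
        t, r = rng.integers(5, 400, size=30), rng.integers(5, 400, size=30)
        fwd = select_differential_peaks(make_cm(t, r))
        rev = select_differential_peaks(make_cm(r, t))
        swap = {"target_specific": "reference_specific",
                "reference_specific": "target_specific",
                "unchanged": "unchanged"}
        for a, b in zip(fwd, rev):
            assert a.log2_fc == pytest.approx(-b.log2_fc)
            assert b.call == swap[a.call]

    def test_strong_peak_called_target_specific(self):
        t = [1000] + [50] * 40
        r = [50] * 41
        res = select_differential_peaks(make_cm(t, r))
        assert res[0].call == "target_specific"
        assert all(x.call == "unchanged" for x in res[1:])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            select_differential_peaks(make_cm([0, 0], [0, 0]))

    def test_single_condition_rejected(self):
        counts = pd.DataFrame({"t1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="reference"):
            CountMatrix(counts, {"t1": "target"})


class TestMotifEnrichment:
    def test_p_equals_hypergeometric_tail_small_tables(self):
        """Exhaustive sweep of 2x2 tables with margins <= 12 against the
        enumeration oracle (the scipy call must realize the exact
        hypergeometric tail)."""
        for N_t in range(1, 13):
            for N_b in range(1, 13):
                for n_t in range(N_t + 1):
                    for n_b in range(N_b + 1):
                        p = stats.fisher_exact(
                            [[n_t, N_t - n_t], [n_b, N_b - n_b]],
                            alternative="greater",
                        )[1]
                        assert p == pytest.approx(
                            hypergeom_tail(n_t, N_t, n_b, N_b), abs=1e-12
                        )

    def test_identical_sets_null(self, library8):
        peaks = simulate_background(40, 60, seed=9)
        res = motif_enrichment(library8, peaks, peaks)
        for r in res:
            assert r.n_target == r.n_bg
            assert r.p_value >= 0.5
            if r.n_bg > 0:
                assert r.fold_enrichment == pytest.approx(1.0)

    def test_absent_motif_degenerate_table(self, library8):
        # sequences with no chance of a hit: all-N windows are skipped
        from synprom.formats import GenomicInterval, PeakSet

        ivs = [GenomicInterval(f"p{i}", 0, 20, f"p{i}") for i in range(5)]
        peaks = PeakSet("n", ivs, ["N" * 20] * 5)
        res = motif_enrichment(library8, peaks, peaks)
        for r in res:
            assert (r.n_target, r.n_bg) == (0, 0)
            assert r.p_value == pytest.approx(1.0)
            assert r.fold_enrichment == pytest.approx(1.0)  # haldane-corrected

    def test_results_sorted_by_p_then_id(self, library8):
        tgt = simulate_background(30, 80, seed=10, label="t")
        bg = simulate_background(30, 80, seed=11, label="b")
        res = motif_enrichment(library8, tgt, bg)
        keys = [(r.p_value, r.motif_id) for r in res]
        assert keys == sorted(keys)

    def test_planted_motif_detected_with_power(self):
        """A motif planted at 0.6 vs 0.05 (N = 200/side) reaches q < 0.05
        in >= 95% of seeded replicates."""
        lib = random_library(5, seed=77)
        pwm = lib[0]
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            tgt = simulate_background(200, 200, seed=500 + 2 * rep, label="t")
            bg = simulate_background(200, 200, seed=500 + 2 * rep + 1, label="b")
            tgt, _ = plant_motifs(tgt, pwm, 0.6, seed=900 + rep)
            bg, _ = plant_motifs(bg, pwm, 0.05, seed=1900 + rep)
            res = {r.motif_id: r for r in motif_enrichment(lib, tgt, bg)}
            if res[pwm.id].q_value < 0.05:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_null_type_one_error_not_anticonservative(self):
        """With no planting, the empirical fraction of p < 0.05 must not
        exceed the nominal rate beyond binomial sampling slack (the exact
        test is valid; discreteness makes it conservative)."""
        lib = random_library(20, seed=13)
        ps = []
        for rep in range(8):
            tgt = simulate_background(150, 150, seed=3000 + 2 * rep, label="t")
            bg = simulate_background(150, 150, seed=3000 + 2 * rep + 1, label="b")
            ps.extend(r.p_value for r in motif_enrichment(lib, tgt, bg))
        ps = np.asarray(ps)
        n = len(ps)
        upper = stats.binom.ppf(0.999, n, 0.05) / n
        assert (ps < 0.05).mean() <= upper

    def test_empty_inputs_rejected(self, library8):
        peaks = simulate_background(5, 30, seed=1)
        from synprom.formats import PeakSet

        empty = PeakSet("e", [], [])
        with pytest.raises(ValueError):
            motif_enrichment([], peaks, peaks)
        with pytest.raises(ValueError):
            motif_enrichment(library8, empty, peaks)
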