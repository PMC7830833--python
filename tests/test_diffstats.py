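"""Frequency tables and pairwise Gst'' differentiation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverepi import (FourStateMatrix, condition_frequencies,
                      genotype_frequencies, gst_double_prime_pair,
                      pairwise_gst_double_prime, pool_frequencies)


def brute_force_gst(freq_a, freq_b):
    """Independent evaluation of the two-population Gst'' formula."""
    pa, pb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    hs = np.mean([1 - (pa**2).sum(), 1 - (pb**2).sum()])
    ht = 1 - (((pa + pb) / 2) ** 2).sum()
    k = 2
    if ht == 0:
        return 0.0
    return k * (ht - hs) / ((k * ht - hs) * (1 - hs))


class TestConditionFrequencies:
    def test_counts_over_scored_individuals(self):
        df = pd.DataFrame({"L0": ["I", "I", "II", "IV"]},
                          index=["a", "b", "c", "d"])
        m = FourStateMatrix(df, pd.Series("p0", index=df.index))
        f = condition_frequencies(m)
        np.testing.assert_allclose(f.freqs["L0"].loc["p0"],
                                   [0.50, 0.25, 0.00, 0.25])
        assert f.n["L0"]["p0"] == 4

    def test_fixed_state(self):
        df = pd.DataFrame({"L0": ["III"] * 3}, index=list("abc"))
        m = FourStateMatrix(df, pd.Series("p0", index=df.index))
        f = condition_frequencies(m)
        np.testing.assert_allclose(f.freqs["L0"].loc["p0"], [0, 0, 1, 0])

    def test_missing_individual_reduces_denominator(self):
        df = pd.DataFrame({"L0": ["I", "I", "II", np.nan]},
                          index=["a", "b", "c", "d"])
        m = FourStateMatrix(df, pd.Series("p0", index=df.index))
        f = condition_frequencies(m)
        np.testing.assert_allclose(f.freqs["L0"].loc["p0"],
                                   [2 / 3, 1 / 3, 0, 0])
        assert f.n["L0"]["p0"] == 3

    def test_population_never_scored_is_an_error(self):
        df = pd.DataFrame({"L0": ["I", np.nan]}, index=["a", "b"])
        m = FourStateMatrix(df, pd.Series(["p0", "p1"], index=df.index))
        with pytest.raises(ValueError, match="p1"):
            condition_frequencies(m)


class TestGenotypeFrequencies:
    def _table(self, genos, pops=None):
        rows = []
        for k, (a1, a2) in enumerate(genos):
            rows.append({"individual": f"i{k}",
                         "population": (pops or ["p0"] * len(genos))[k],
                         "ms1_a1": a1, "ms1_a2": a2})
        return pd.DataFrame(rows)

    def test_allele_copy_counting(self):
        f = genotype_frequencies(self._table([("A", "A"), ("A", "B")]))
        assert f.freqs["ms1"].loc["p0", "A"] == pytest.approx(0.75)
        assert f.freqs["ms1"].loc["p0", "B"] == pytest.approx(0.25)
        assert f.n["ms1"]["p0"] == 4

    def test_all_heterozygous(self):
        f = genotype_frequencies(self._table([("A", "B")] * 3))
        np.testing.assert_allclose(f.freqs["ms1"].loc["p0"], [0.5, 0.5])

    def test_missing_genotype_reduces_copy_count(self):
        f = genotype_frequencies(self._table([("A", "A"), ("A", "B"), (None, None)]))
        assert f.n["ms1"]["p0"] == 4

    def test_half_genotype_rejected(self):
        with pytest.raises(ValueError, match="half genotype"):
            genotype_frequencies(self._table([("A", None)]))


class TestGstClosedForms:
    def test_identical_populations_give_zero(self):
        p = np.array([[0.3, 0.3, 0.2, 0.2]])
        c = gst_double_prime_pair(p, p.copy())
        assert c.gst_dp == pytest.approx(0.0, abs=1e-12)
        assert c.hs == pytest.approx(c.ht, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        c = gst_double_prime_pair(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        assert c.gst_dp == pytest.approx(1.0, abs=1e-12)
        assert (c.hs, c.ht) == (pytest.approx(0.0), pytest.approx(0.5))

    def test_partial_overlap_case(self):
        c = gst_double_prime_pair(np.array([[0.8, 0.2]]), np.array([[0.2, 0.8]]))
        assert c.hs == pytest.approx(0.32, abs=1e-12)
        assert c.ht == pytest.approx(0.5, abs=1e-12)
        assert c.gst_dp == pytest.approx(0.36 / (0.68 * 0.68), abs=1e-12)

    def test_degenerate_pair_warns_and_reports_zero(self):
        fixed = np.array([[1.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            c = gst_double_prime_pair(fixed, fixed.copy())
        assert c.gst_dp == 0.0


class TestGstProperties:
    def test_matrix_symmetric_zero_diagonal_in_unit_interval(self, small_dataset):
        f = condition_frequencies(small_dataset.species["gudgeon"].epi)
        d, comps = pairwise_gst_double_prime(f)
        a = d.data
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 0)
        assert ((a >= -1e-12) & (a <= 1 + 1e-12)).all()
        for c in comps.values():
            assert -1e-12 <= c.hs <= c.ht <= 1 + 1e-12

    def test_state_relabelling_invariance(self, rng):
        for _ in range(10):
            pa = rng.dirichlet(np.ones(4), size=3)
            pb = rng.dirichlet(np.ones(4), size=3)
            perm = rng.permutation(4)
            c1 = gst_double_prime_pair(pa, pb)
            c2 = gst_double_prime_pair(pa[:, perm], pb[:, perm])
            assert c1.gst_dp == pytest.approx(c2.gst_dp, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_two_allele_single_locus_matches_brute_force(self, p1, p2):
        c = gst_double_prime_pair(np.array([[p1, 1 - p1]]), np.array([[p2, 1 - p2]]))
        assert c.gst_dp == pytest.approx(
            brute_force_gst([p1, 1 - p1], [p2, 1 - p2]), abs=1e-12)

    def test_monotone_in_frequency_gap_on_a_grid(self):
        """On symmetric two-allele pairs (0.5+d, 0.5-d), Gst'' grows with d."""
        gaps = np.linspace(0.0, 0.5, 11)
        vals = [brute_force_gst([0.5 + d, 0.5 - d], [0.5 - d, 0.5 + d])
                for d in gaps]
        ours = [gst_double_prime_pair(np.array([[0.5 + d, 0.5 - d]]),
                                      np.array([[0.5 - d, 0.5 + d]])).gst_dp
                for d in gaps]
        np.testing.assert_allclose(ours, vals, atol=1e-12)
        assert all(b > a - 1e-12 for a, b in zip(ours, ours[1:]))

    def test_averaging_order_differs_from_per_locus_ratio(self, rng):
        """HS/HT are averaged across loci before the ratio; the per-locus
        sensitivity mode must differ on heterogeneous loci."""
        pa = np.array([[0.9, 0.1], [0.5, 0.5]])
        pb = np.array([[0.1, 0.9], [0.5, 0.5]])
        across = gst_double_prime_pair(pa, pb).gst_dp
        per_locus = gst_double_prime_pair(pa, pb,
                                          locus_aggregation="per_locus").gst_dp
        assert across != pytest.approx(per_locus, abs=1e-6)

    def test_monomorphic_locus_dilutes_both_components(self):
        poly_only = gst_double_prime_pair(np.array([[1.0, 0.0]]),
                                          np.array([[0.0, 1.0]]))
        with_mono = gst_double_prime_pair(np.array([[1.0, 0.0], [1.0, 0.0]]),
                                          np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert with_mono.ht == pytest.approx(poly_only.ht / 2)
        assert with_mono.gst_dp == pytest.approx(1.0)  # hs still 0

    def test_nei_unbiased_differs_from_plugin_and_needs_n(self, small_dataset):
        f = condition_frequencies(small_dataset.species["gudgeon"].epi)
        d_p, _ = pairwise_gst_double_prime(f, estimator="plugin")
        d_u, _ = pairwise_gst_double_prime(f, estimator="nei_unbiased")
        assert not np.allclose(d_p.data, d_u.data)
        pool = small_dataset.species["gudgeon"].snp_pool
        with pytest.raises(ValueError, match="sample size"):
            pairwise_gst_double_prime(pool, estimator="nei_unbiased")

    def test_pool_frequencies_validated(self):
        bad = pd.DataFrame({"snp1": [0.5, 1.2]}, index=["p0", "p1"])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            pool_frequencies(bad)

    def test_three_marker_kinds_share_one_engine(self, small_dataset):
        sp = small_dataset.species["gudgeon"]
        for f in (condition_frequencies(sp.epi),
                  genotype_frequencies(sp.genotypes), sp.snp_pool):
            d, _ = pairwise_gst_double_prime(f)
            assert list(d.ids) == small_dataset.config.sites[: len(d.ids)]
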