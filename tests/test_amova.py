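"""Distance-based AMOVA against a brute-force nested-ANOVA oracle."""

import numpy as np
import pandas as pd
import pytest

from riverepi import (FourStateMatrix, amova_two_level,
                      individual_distance_matrix)
from riverepi.msaflp import STATES
from tests.conftest import random_four_state


def nested_anova_oracle(m: FourStateMatrix):
    """Indicator-coded nested ANOVA, fully independent of the distance path.

    Each (locus, state) becomes an indicator coordinate scaled by
    1/sqrt(2), so squared Euclidean distance equals the mismatch count;
    the classical per-coordinate ANOVA sums then give the variance
    components directly.
    """
    cols = []
    for locus in m.states.columns:
        for s in STATES:
            cols.append((m.states[locus] == s).to_numpy(float) / np.sqrt(2))
    x = np.column_stack(cols)
    pops = m.populations
    labels = sorted(pops.unique())
    N, P = x.shape[0], len(labels)
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_within = 0.0
    sizes = []
    for p in labels:
        xp = x[(pops == p).to_numpy()]
        sizes.append(len(xp))
        ss_within += ((xp - xp.mean(axis=0)) ** 2).sum()
    sizes = np.array(sizes, float)
    ss_among = ss_total - ss_within
    df_a, df_w = P - 1, N - P
    s2w = ss_within / df_w
    n0 = (N - (sizes**2).sum() / N) / df_a
    s2a = (ss_among / df_a - s2w) / n0
    return ss_among, ss_within, ss_total, s2a, s2w


class TestDistanceMetrics:
    def test_identical_epi_rows_have_zero_distance(self):
        df = pd.DataFrame([["I", "II"], ["I", "II"]], index=["a", "b"],
                          columns=["L0", "L1"])
        m = FourStateMatrix(df, pd.Series("p", index=df.index))
        d = individual_distance_matrix(m)
        assert d["a", "b"] == 0.0

    def test_epi_mismatch_count(self):
        states = [["I"] * 10, ["II", "III", "IV"] + ["I"] * 7]
        df = pd.DataFrame(states, index=["a", "b"],
                          columns=[f"L{k}" for k in range(10)])
        m = FourStateMatrix(df, pd.Series("p", index=df.index))
        assert individual_distance_matrix(m)["a", "b"] == 3.0

    def test_microsat_single_shared_copy(self):
        g = pd.DataFrame({"individual": ["a", "b"], "population": ["p", "p"],
                          "ms1_a1": ["A", "A"], "ms1_a2": ["A", "B"]})
        assert individual_distance_matrix(g, metric="microsat")["a", "b"] == 1.0

    def test_microsat_fixed_difference_counts_two_copies(self):
        g = pd.DataFrame({"individual": ["a", "b"], "population": ["p", "p"],
                          "ms1_a1": ["A", "B"], "ms1_a2": ["A", "B"]})
        assert individual_distance_matrix(g, metric="microsat")["a", "b"] == 2.0

    def test_missing_loci_rescaled_to_full_locus_count(self):
        df = pd.DataFrame([["I", "II", np.nan, "I"],
                           ["II", "II", "I", np.nan]],
                          index=["a", "b"], columns=list("wxyz"))
        m = FourStateMatrix(df, pd.Series("p", index=df.index))
        # compared loci: w (mismatch), x (match) -> mean 0.5 * 4 loci = 2
        assert individual_distance_matrix(m)["a", "b"] == pytest.approx(2.0)

    def test_no_comparable_locus_is_an_error(self):
        df = pd.DataFrame([["I", np.nan], [np.nan, "I"]],
                          index=["a", "b"], columns=["L0", "L1"])
        m = FourStateMatrix(df, pd.Series("p", index=df.index))
        with pytest.raises(ValueError, match="share no scored locus"):
            individual_distance_matrix(m)

    def test_pool_frequencies_rejected_by_type(self, small_dataset):
        with pytest.raises(TypeError, match="individual-level"):
            individual_distance_matrix(small_dataset.species["gudgeon"].snp_pool)


class TestAmovaComponents:
    def test_oracle_equivalence_on_random_data(self, rng):
        m = random_four_state(rng, n_pops=2, n_per_pop=6, n_loci=8)
        d = individual_distance_matrix(m)
        res = amova_two_level(d, m.populations, n_perm=9, seed=1)
        ssa, ssw, sst, s2a, s2w = nested_anova_oracle(m)
        assert res.ss_among == pytest.approx(ssa, abs=1e-9)
        assert res.ss_within == pytest.approx(ssw, abs=1e-9)
        assert res.ss_total == pytest.approx(sst, abs=1e-9)
        assert res.sigma2_among == pytest.approx(s2a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(s2w, abs=1e-9)

    def test_oracle_equivalence_unbalanced_pops(self, rng):
        m = random_four_state(rng, n_pops=3, n_per_pop=4, n_loci=12)
        # drop two individuals to unbalance group sizes
        keep = m.states.index[:-2]
        m2 = FourStateMatrix(m.states.loc[keep], m.populations.loc[keep])
        d = individual_distance_matrix(m2)
        res = amova_two_level(d, m2.populations, n_perm=9, seed=1)
        ssa, ssw, sst, s2a, s2w = nested_anova_oracle(m2)
        assert res.sigma2_among == pytest.approx(s2a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(s2w, abs=1e-9)

    def test_two_monomorphic_populations_give_phi_one(self):
        df = pd.DataFrame([["I", "II"]] * 4 + [["III", "IV"]] * 4,
                          index=[f"i{k}" for k in range(8)],
                          columns=["L0", "L1"])
        pops = pd.Series(["a"] * 4 + ["b"] * 4, index=df.index)
        m = FourStateMatrix(df, pops)
        res = amova_two_level(individual_distance_matrix(m), pops,
                              n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_variation_among == pytest.approx(100.0)
        assert res.ss_within == pytest.approx(0.0, abs=1e-12)

    def test_ss_and_df_additivity(self, rng):
        m = random_four_state(rng, n_pops=3, n_per_pop=5, n_loci=10)
        res = amova_two_level(individual_distance_matrix(m), m.populations,
                              n_perm=9, seed=0)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
        assert res.df_among + res.df_within == len(m.individuals) - 1

    def test_doubling_distances_scales_ss_not_phi(self, rng):
        from skbio import DistanceMatrix
        m = random_four_state(rng, n_pops=2, n_per_pop=6, n_loci=10)
        d = individual_distance_matrix(m)
        d2 = DistanceMatrix(2 * d.data, ids=d.ids)
        r1 = amova_two_level(d, m.populations, n_perm=99, seed=5)
        r2 = amova_two_level(d2, m.populations, n_perm=99, seed=5)
        assert r2.ss_total == pytest.approx(2 * r1.ss_total)
        assert r2.sigma2_among == pytest.approx(2 * r1.sigma2_among)
        assert r2.phi_st == pytest.approx(r1.phi_st, abs=1e-12)
        assert r2.p_value == r1.p_value

    def test_relabelling_invariance(self, rng):
        m = random_four_state(rng, n_pops=3, n_per_pop=4, n_loci=10)
        d = individual_distance_matrix(m)
        renamed = m.populations.map({"p0": "x", "p1": "y", "p2": "z"})
        r1 = amova_two_level(d, m.populations, n_perm=49, seed=3)
        r2 = amova_two_level(d, renamed, n_perm=49, seed=3)
        assert r1.phi_st == pytest.approx(r2.phi_st, abs=1e-12)

    def test_negative_component_reported_then_clamped_for_display(self, rng):
        # exchangeable data often yields a slightly negative among component
        found = None
        for seed in range(30):
            m = random_four_state(np.random.default_rng(seed),
                                  n_pops=3, n_per_pop=4, n_loci=5)
            res = amova_two_level(individual_distance_matrix(m),
                                  m.populations, n_perm=9, seed=0)
            if res.sigma2_among < 0:
                found = res
                break
        assert found is not None
        assert found.pct_variation_among < 0
        assert found.clamped().sigma2_among == 0.0
        assert found.clamped().pct_variation_among == 0.0


class TestAmovaPermutation:
    def test_p_in_half_open_unit_interval_and_reproducible(self, rng):
        m = random_four_state(rng, n_pops=2, n_per_pop=6, n_loci=10)
        d = individual_distance_matrix(m)
        r1 = amova_two_level(d, m.populations, n_perm=99, seed=11)
        r2 = amova_two_level(d, m.populations, n_perm=99, seed=11)
        assert 0 < r1.p_value <= 1
        assert r1.p_value == r2.p_value

    def test_population_of_one_rejected(self):
        df = pd.DataFrame([["I"], ["II"], ["I"]], index=["a", "b", "c"],
                          columns=["L0"])
        pops = pd.Series(["p0", "p0", "p1"], index=df.index)
        m = FourStateMatrix(df, pops)
        with pytest.raises(ValueError, match="fewer than 2"):
            amova_two_level(individual_distance_matrix(m), pops)

    def test_all_zero_distances_flagged_degenerate(self):
        df = pd.DataFrame([["I", "II"]] * 6, index=[f"i{k}" for k in range(6)],
                          columns=["L0", "L1"])
        pops = pd.Series(["a"] * 3 + ["b"] * 3, index=df.index)
        m = FourStateMatrix(df, pops)
        res = amova_two_level(individual_distance_matrix(m), pops, n_perm=9)
        assert res.degenerate
        assert np.isnan(res.phi_st)

    def test_structured_data_detected(self, small_dataset):
        sp = small_dataset.species["gudgeon"]
        d = individual_distance_matrix(sp.epi)
        res = amova_two_level(d, sp.epi.populations, n_perm=199, seed=2)
        assert res.p_value <= 0.05
        assert res.phi_st > 0
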