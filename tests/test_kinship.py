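"""KING-style kinship: counts, the two estimators, and the pair table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faroh.genotype_io import MISSING, merge_cohort
from faroh.kinship import (
    PairCounts,
    kinship_matrix,
    kinship_robust,
    kinship_within,
    pair_counts,
)
from faroh.synthetic_data import AlleleFreqModel, CohortSpec, simulate_cohort

from conftest import make_matrix


def brute_counts(gi, gj):
    """Site-by-site tally oracle for pair_counts."""
    het_i = het_j = both = opp = shared = 0
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        shared += 1
        het_i += a == 1
        het_j += b == 1
        both += a == 1 and b == 1
        opp += (a, b) in ((0, 2), (2, 0))
    return het_i, het_j, both, opp, shared


class TestPairCounts:
    def test_clone_counts(self):
        g = np.array([[1] * 1000 + [0] * 250 + [2] * 250] * 2, dtype=np.int8)
        m = make_matrix(["a", "b"], 1, range(10, 15010, 10), g)
        c = pair_counts(m, "a", "b")
        assert (c.n_both_het, c.n_opp_hom, c.m_shared) == (1000, 0, 1500)

    def test_opposite_homozygotes(self):
        g = np.array([[0] * 100, [2] * 100], dtype=np.int8)
        m = make_matrix(["a", "b"], 1, range(10, 1010, 10), g)
        c = pair_counts(m, "a", "b")
        assert c.n_opp_hom == 100 and c.n_het_i == c.n_het_j == 0

    def test_matches_brute_tally(self):
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, size=(2, 2000)).astype(np.int8)
        g[rng.random(g.shape) < 0.15] = MISSING
        m = make_matrix(["a", "b"], 1, range(10, 20010, 10), g)
        c = pair_counts(m, "a", "b")
        assert (
            c.n_het_i, c.n_het_j, c.n_both_het, c.n_opp_hom, c.m_shared
        ) == brute_counts(g[0], g[1])

    def test_no_shared_markers_is_error(self):
        g = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
        m = make_matrix(["a", "b"], 1, [10, 20], g)
        with pytest.raises(ValueError, match="shared"):
            pair_counts(m, "a", "b")

    def test_identical_pair_rejected(self):
        m = make_matrix(["a", "b"], 1, [10], [[1], [1]])
        with pytest.raises(ValueError):
            pair_counts(m, "a", "a")


class TestEstimators:
    def test_within_clone_limit(self):
        c = PairCounts(1000, 1000, 1000, 0, 1500)
        r = kinship_within(c)
        assert r.phi == 0.5 and r.relatedness == 1.0

    def test_within_maximal_discordance(self):
        c = PairCounts(500, 500, 0, 500, 2000)
        assert kinship_within(c).phi == -1.0

    def test_within_direct_evaluation(self):
        c = PairCounts(5000, 6000, 3000, 200, 20000)
        assert kinship_within(c).phi == pytest.approx(2600 / 11000)

    def test_robust_clone_limit(self):
        c = PairCounts(1000, 1000, 1000, 0, 1500)
        assert kinship_robust(c).phi == 0.5

    def test_robust_direct_evaluation(self):
        c = PairCounts(5000, 6000, 3000, 200, 20000)
        assert kinship_robust(c).phi == pytest.approx(0.21)

    def test_zero_denominators_flagged(self):
        with pytest.raises(ValueError):
            kinship_within(PairCounts(0, 0, 0, 10, 100))
        with pytest.raises(ValueError):
            kinship_robust(PairCounts(0, 5, 0, 10, 100))

    @given(
        st.integers(1, 5000), st.integers(0, 5000), st.integers(0, 5000)
    )
    def test_equal_het_counts_reduce_to_within(self, het, both, opp):
        """With N_Aa^i = N_Aa^j the robust estimator equals the within-family
        form algebraically."""
        both = min(both, het)
        m_shared = het + opp + both + 10_000
        c = PairCounts(het, het, both, opp, m_shared)
        assert kinship_robust(c).phi == pytest.approx(
            kinship_within(c).phi, abs=1e-12
        )

    @given(
        st.integers(1, 5000), st.integers(1, 5000),
        st.integers(0, 5000), st.integers(0, 5000),
    )
    def test_robust_symmetric_and_bounded_by_within(self, hi, hj, both, opp):
        both = min(both, hi, hj)
        m_shared = hi + hj + both + opp + 10_000
        c = PairCounts(hi, hj, both, opp, m_shared)
        c_swapped = PairCounts(hj, hi, both, opp, m_shared)
        assert kinship_robust(c).phi == kinship_robust(c_swapped).phi
        # guards against inflation: when het rates differ and the numerator
        # is positive, the robust estimate never exceeds the within estimate
        if hi != hj and both - 2 * opp > 0:
            assert kinship_robust(c).phi <= kinship_within(c).phi + 1e-12


class TestKinshipMatrix:
    def test_pair_count_combinatorics(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(8, 300)).astype(np.int8)
        m = make_matrix([f"s{k}" for k in range(8)], 1, range(10, 3010, 10), g)
        assert len(kinship_matrix(m)) == 28
        assert len(kinship_matrix(m.subset_samples(["s0", "s1"]))) == 1

    def test_failed_pair_flagged_not_dropped(self):
        g = np.array([[1, MISSING], [MISSING, 1], [1, 1]], dtype=np.int8)
        m = make_matrix(["a", "b", "c"], 1, [10, 20], g)
        out = kinship_matrix(m, marker_set="pairwise-shared")
        assert len(out) == 3
        bad = out[(out.id1 == "a") & (out.id2 == "b")].iloc[0]
        assert bad.error != "" and np.isnan(bad.phi)

    def test_pairwise_mode_invariant_to_extra_samples(self, private_shared_cohort):
        """Pairwise-shared estimates depend only on the two genomes, so
        adding cohort members cannot move them; complete-case estimates
        change with the marker set."""
        merged = merge_cohort(private_shared_cohort.per_sample_matrices())
        small = merged.subset_samples(merged.samples[:3])
        big_pw = kinship_matrix(merged, marker_set="pairwise-shared")
        small_pw = kinship_matrix(small, marker_set="pairwise-shared")
        key = ["id1", "id2"]
        joined = small_pw.merge(big_pw, on=key, suffixes=("_s", "_b"))
        assert np.allclose(joined.phi_s, joined.phi_b, equal_nan=True)

    def test_complete_case_uses_smaller_marker_set(self):
        # site at pos 20 is called only in (a, b): pairwise-shared keeps it,
        # complete-case drops it for every pair
        g = np.array(
            [[1, 1], [1, 1], [1, MISSING]], dtype=np.int8
        )
        m = make_matrix(["a", "b", "c"], 1, [10, 20], g)
        pw = kinship_matrix(m, marker_set="pairwise-shared")
        cc = kinship_matrix(m, marker_set="complete-case")
        ab = ("a", "b")
        assert int(pw.set_index(["id1", "id2"]).loc[ab, "m_shared"]) == 2
        assert int(cc.set_index(["id1", "id2"]).loc[ab, "m_shared"]) == 1

    def test_unrelated_pairs_center_on_zero(self):
        spec = CohortSpec(
            seed=31, n_samples=8, chrom_lengths_mb=(30.0,),
            founder_g=None, segments_per_sample=0.0,
            allele_freq=AlleleFreqModel(rare_fraction=0.0),
        )
        m = simulate_cohort(spec).matrix
        out = kinship_matrix(m, estimator="robust")
        phis = out.phi.to_numpy()
        se = phis.std(ddof=1) / np.sqrt(len(phis))
        assert abs(phis.mean()) < 3 * max(se, 1e-3)
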