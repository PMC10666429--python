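"""VCF reading/writing, site filtering, merging, HWE and QC."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

from faroh.genotype_io import (
    MISSING,
    QCSpec,
    ReferenceMismatchError,
    SiteFilterSpec,
    apply_qc,
    hwe_exact_p,
    load_vcf,
    merge_cohort,
    write_vcf,
)
from faroh.synthetic_data import CohortSpec, simulate_cohort

from conftest import make_matrix

VCF_3RECORDS = """\
##fileformat=VCFv4.1
##contig=<ID=1>
##FILTER=<ID=MaxSB,Description="strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DPU,Number=1,Type=Integer,Description="depth used">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\t.\tA\tG\t40\t{filt40}\t.\tGT:DPU\t0/1:30
1\t200\t.\tC\tT\t20\tPASS\t.\tGT:DPU\t1/1:30
1\t300\t.\tG\tGA\t50\tPASS\t.\tGT:DPU\t0/1:30
"""


def _write(tmp_path, text, name="in.vcf"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestLoadVCF:
    def test_basic_keeps_only_high_qual_snps(self, tmp_path):
        path = _write(tmp_path, VCF_3RECORDS.format(filt40="PASS"))
        m = load_vcf(path, SiteFilterSpec("basic"))
        assert m.n_sites == 1
        assert m.sites.loc[0, "pos"] == 100 and m.genotypes[0, 0] == 1

    def test_advanced_requires_pass(self, tmp_path):
        path = _write(tmp_path, VCF_3RECORDS.format(filt40="MaxSB"))
        m = load_vcf(path, SiteFilterSpec("advanced"))
        assert m.n_sites == 0

    def test_advanced_depth_sets_missing(self, tmp_path):
        text = VCF_3RECORDS.format(filt40="PASS").replace("0/1:30", "0/1:5")
        m = load_vcf(_write(tmp_path, text), SiteFilterSpec("advanced"))
        # only surviving record fails DPU>10 for its single genotype -> dropped
        assert m.n_sites == 0

    def test_synthetic_low_qual_fraction(self, tmp_path):
        """Sites at QUAL <= 30 in the generator manifest are exactly the
        records the basic filter drops."""
        spec = CohortSpec(
            seed=5, n_samples=2, chrom_lengths_mb=(1.0,),
            founder_g=None, segments_per_sample=0.0,
            qual_low_fraction=0.05, filter_fail_fraction=0.0,
        )
        cohort = simulate_cohort(spec, out_dir=tmp_path, layout="multi-sample")
        m = load_vcf(cohort.vcf_paths[0], SiteFilterSpec("basic"))
        assert m.n_sites == cohort.truth.manifest["n_qual_pass"]

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(Exception):
            load_vcf(str(tmp_path / "nope.vcf"))


class TestMerge:
    def test_union_semantics(self):
        m1 = make_matrix(["a"], 1, [100, 200], [[0, 1]])
        m2 = make_matrix(["b"], 1, [200, 300], [[2, 1]])
        merged = merge_cohort([m1, m2])
        assert merged.n_sites == 3
        assert merged.genotypes[0].tolist() == [0, 1, MISSING]
        assert merged.genotypes[1].tolist() == [MISSING, 2, 1]
        assert np.allclose(merged.missing_rates(), 1 / 3)

    def test_full_sharing_no_missing(self):
        mats = [
            make_matrix([f"s{k}"], 1, [10, 20, 30], [[0, 1, 2]]) for k in range(8)
        ]
        merged = merge_cohort(mats)
        assert merged.missing_rates().sum() == 0
        assert merged.n_sites == 3

    def test_ref_conflict_fatal(self):
        m1 = make_matrix(["a"], 1, [100], [[0]], ref="A")
        m2 = make_matrix(["b"], 1, [100], [[0]], ref="C")
        with pytest.raises(ReferenceMismatchError):
            merge_cohort([m1, m2])

    def test_associative_up_to_sample_order(self):
        m1 = make_matrix(["a"], 1, [1000, 2000], [[0, 1]])
        m2 = make_matrix(["b"], 1, [2000, 3000], [[1, 2]])
        m3 = make_matrix(["c"], 1, [1000, 3000], [[2, 0]])
        two_step = merge_cohort([merge_cohort([m1, m2]), m3])
        one_step = merge_cohort([m1, m2, m3])
        assert_frame_equal(two_step.sites, one_step.sites)
        assert np.array_equal(two_step.genotypes, one_step.genotypes)

    def test_manifest_bookkeeping(self, private_shared_cohort):
        merged = merge_cohort(private_shared_cohort.per_sample_matrices())
        man = private_shared_cohort.truth.manifest
        assert merged.n_sites == man["union_size"]
        n_called = (merged.genotypes != MISSING).sum(axis=0)
        for k, expect in man["call_rate_bins"].items():
            assert int((n_called == k).sum()) == expect


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Independent oracle: exact rational enumeration of all heterozygote
    configurations conditional on the allele counts."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_r) * math.factorial(hom_c) * math.factorial(h),
        )
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


class TestHWE:
    @pytest.mark.parametrize(
        "counts,expected",
        [((8, 0, 0), 1.0), ((0, 1, 0), 1.0), ((0, 0, 5), 1.0)],
    )
    def test_degenerate_configurations(self, counts, expected):
        assert hwe_exact_p(*counts) == expected

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @pytest.mark.parametrize(
        "counts",
        [(3, 4, 1), (1, 1, 1), (0, 8, 0), (5, 0, 5), (10, 3, 2), (2, 9, 2)],
    )
    def test_matches_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration(*counts), rel=1e-9
        )

    @given(
        st.tuples(
            st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)
        ).filter(lambda c: sum(c) > 0)
    )
    def test_enumeration_agreement_up_to_40_alleles(self, counts):
        p = hwe_exact_p(*counts)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_enumeration(*counts), rel=1e-9)


class TestApplyQC:
    def test_partial_call_site_removed_at_n8(self):
        """With n=8 and geno_max=0.1, a 7/8-called site (rate 0.125) must go;
        every survivor has call rate exactly 1."""
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        g[0, 5] = MISSING  # sample 0 stays below mind (1/20), site 5 at 1/8
        m = make_matrix([f"s{k}" for k in range(8)], 1, range(10, 210, 10), g)
        out, log = apply_qc(m, QCSpec(hwe_p_min=0.0))
        assert out.n_sites == 19
        assert log.n_sites_geno_removed == 1
        assert not log.samples_removed
        assert (out.site_missing_rates() == 0).all()

    def test_clean_matrix_unchanged(self):
        g = np.array([[0, 1, 2], [1, 1, 0], [2, 1, 1], [0, 1, 2]], dtype=np.int8)
        m = make_matrix(["a", "b", "c", "d"], 1, [10, 20, 30], g)
        out, log = apply_qc(m)
        assert out.n_sites == 3 and not log.samples_removed

    def test_high_missing_sample_dropped(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(4, 100)).astype(np.int8)
        g[0, :15] = MISSING  # 15% missing
        m = make_matrix(["bad", "b", "c", "d"], 1, range(10, 1010, 10), g)
        out, log = apply_qc(m)
        assert log.samples_removed == ["bad"]
        assert out.samples == ["b", "c", "d"]

    def test_hwe_filter_removes_extreme_site(self):
        # 20 samples, one site all-het (strong HWE violation), one in HWE
        g = np.ones((20, 2), dtype=np.int8)
        g[:10, 1] = 0
        g[10:15, 1] = 2
        m = make_matrix([f"s{k}" for k in range(20)], 1, [10, 20], g)
        assert hwe_exact_p(0, 20, 0) < 1e-4
        out, log = apply_qc(m, QCSpec(hwe_p_min=1e-4))
        assert log.n_sites_hwe_removed == 1
        assert out.sites["pos"].tolist() == [20]

    def test_all_samples_removed_is_fatal(self):
        g = np.full((2, 10), MISSING, dtype=np.int8)
        g[:, 0] = 1
        m = make_matrix(["a", "b"], 1, range(10, 110, 10), g)
        with pytest.raises(ValueError, match="mind_max"):
            apply_qc(m)


def test_vcf_roundtrip(tmp_path):
    """write_vcf -> load_vcf preserves genotypes and site metadata exactly."""
    spec = CohortSpec(
        seed=9, n_samples=3, chrom_lengths_mb=(20.0, 10.0),
        founder_g=50.0, segments_per_sample=3.0,
        qual_low_fraction=0.0, filter_fail_fraction=0.0,
    )
    cohort = simulate_cohort(spec)
    path = str(tmp_path / "m.vcf")
    write_vcf(cohort.matrix, path)
    back = load_vcf(path, SiteFilterSpec("basic"))
    assert back.samples == cohort.matrix.samples
    assert np.array_equal(back.genotypes, cohort.matrix.genotypes)
    assert_frame_equal(back.sites, cohort.matrix.sites, check_dtype=False)
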