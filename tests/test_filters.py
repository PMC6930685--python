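import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_call, make_cohort
from rnamut.filters import (
    FilterParams,
    germline_filter,
    hypermutated_filter,
    rank_bias_tests,
    recurrence_filter,
    region_mask_filter,
    run_filter_cascade,
    seq_error_filter,
    splice_distance_filter,
    vaf_filter,
    variant_distance_filter,
)
from rnamut.io_formats import (
    ExonRecord,
    ExonSet,
    GermlineSet,
    MutationCatalog,
    RegionMask,
)


class TestRegionMask:
    @pytest.mark.parametrize("chrom", ["chrX", "chrY", "chrM", "chrMT", "GL000195.1", "X"])
    def test_blacklisted_chromosomes(self, chrom):
        assert not region_mask_filter(make_call(chrom=chrom), {}).passed

    @pytest.mark.parametrize("chrom", ["chr1", "chr22", "5"])
    def test_primary_chromosomes_pass(self, chrom):
        assert region_mask_filter(make_call(chrom=chrom), {}).passed

    def test_masked_position_fails_with_label(self):
        masks = {"common_snp": RegionMask("common_snp", {"chr1": [(90, 110)]})}
        v = region_mask_filter(make_call(pos=100), masks)
        assert not v.passed and v.name == "common_snp"
        assert region_mask_filter(make_call(pos=110), masks).passed


class TestGermline:
    def test_allele_specific(self):
        gs = GermlineSet()
        gs.add("i1", "chr1", 100, "A", "G")
        assert not germline_filter(make_call(pos=100, alt="G"), gs, "i1").passed
        assert germline_filter(make_call(pos=100, alt="T"), gs, "i1").passed

    def test_unknown_individual_lenient_vs_strict(self):
        gs = GermlineSet()
        gs.add("i1", "chr1", 100, "A", "G")
        v = germline_filter(make_call(pos=100, alt="G"), gs, "i2")
        assert v.passed and "germline_unavailable" in v.flags
        with pytest.raises(KeyError, match="i2"):
            germline_filter(make_call(pos=100, alt="G"), gs, "i2", strict=True)


class TestSpliceDistance:
    exons = ExonSet([ExonRecord("chr1", 100, 200, "g1", "+")])

    @pytest.mark.parametrize("pos", [100, 103, 106, 193, 199])
    def test_within_7bp_fails(self, pos):
        assert not splice_distance_filter(make_call(pos=pos), self.exons).passed

    @pytest.mark.parametrize("pos", [107, 150, 192])
    def test_at_or_beyond_7bp_passes(self, pos):
        assert splice_distance_filter(make_call(pos=pos), self.exons).passed

    def test_no_annotation_passes_flagged(self):
        v = splice_distance_filter(make_call(chrom="chr9"), self.exons)
        assert v.passed and "no_exon_annotation" in v.flags


def exact_binom_upper_tail(n, c, p):
    """P(X >= n) with X ~ Binomial(c, p), by direct summation."""
    return sum(
        math.comb(c, j) * p**j * (1 - p) ** (c - j) for j in range(n, c + 1)
    )


class TestSeqError:
    def test_spec_example_pass(self):
        v = seq_error_filter(make_call(alt_count=6, ref_count=34))
        assert v.passed
        assert v.p_value == pytest.approx(3.8e-12, rel=0.1)

    def test_spec_example_high_coverage_fail(self):
        v = seq_error_filter(make_call(alt_count=6, ref_count=9994))
        assert not v.passed
        assert v.p_value == pytest.approx(0.93, abs=0.01)

    def test_zero_alt_fails(self):
        v = seq_error_filter(make_call(alt_count=0, ref_count=100))
        assert not v.passed and v.p_value == 1.0

    def test_matches_exact_enumeration(self):
        for c, n in [(40, 6), (100, 3), (250, 7), (500, 6), (60, 60)]:
            v = seq_error_filter(make_call(alt_count=n, ref_count=c - n))
            assert v.p_value == pytest.approx(exact_binom_upper_tail(n, c, 0.001), rel=1e-9)


class TestRankBias:
    def test_unbiased_attributes_pass(self):
        verdicts = rank_bias_tests(make_call(seed=1))
        assert all(v.passed for v in verdicts.values())

    def test_read_position_bias_fails(self):
        call = make_call(alt_read_positions=[5] * 10, seed=1)
        v = rank_bias_tests(call)
        assert not v["read_position"].passed
        assert v["strand"].passed

    def test_strand_bias_fails(self):
        call = make_call(alt_strands=["+"] * 10, ref_strands=["+"] * 45 + ["-"] * 45)
        assert not rank_bias_tests(call)["strand"].passed

    def test_base_quality_bias_fails(self):
        call = make_call(alt_bq=[30] * 10, ref_bq=[37] * 90)
        assert not rank_bias_tests(call)["base_quality"].passed

    def test_mapping_quality_bias_fails(self):
        call = make_call(alt_mq=[20] * 10, ref_mq=[255] * 90)
        assert not rank_bias_tests(call)["mapping_quality"].passed

    def test_constant_attribute_is_uninformative(self):
        call = make_call(alt_mq=[255] * 10, ref_mq=[255] * 90)
        v = rank_bias_tests(call)["mapping_quality"]
        assert v.passed and v.p_value == 1.0

    def test_empty_group_untestable(self):
        call = make_call(alt_count=0, alt_read_positions=[], alt_strands=[], alt_bq=[], alt_mq=[])
        v = rank_bias_tests(call)
        assert all(x.passed and "untestable" in x.flags for x in v.values())


class TestVariantDistance:
    def test_identical_offsets_fail(self):
        call = make_call(
            alt_read_positions=[12] * 15,
            ref_read_positions=list(np.random.default_rng(0).integers(1, 77, 85)),
        )
        assert not variant_distance_filter(call, seed=0).passed

    def test_uniform_offsets_pass(self):
        rng = np.random.default_rng(42)
        call = make_call(
            alt_read_positions=list(rng.integers(1, 77, 15)),
            ref_read_positions=list(rng.integers(1, 77, 85)),
        )
        assert variant_distance_filter(call, seed=0).passed

    def test_single_alt_read_untestable(self):
        call = make_call(alt_count=1, alt_read_positions=[5])
        v = variant_distance_filter(call)
        assert v.passed and "untestable" in v.flags

    def test_deterministic_per_call(self):
        call = make_call(seed=3)
        a = variant_distance_filter(call, seed=7)
        b = variant_distance_filter(call, seed=7)
        assert a.passed == b.passed and a.p_value == b.p_value


class TestVaf:
    def test_boundary_exact(self):
        # 7/10 is exactly 0.7: retained (strictly-greater rule)
        assert vaf_filter(make_call(alt_count=7, ref_count=3)).passed
        assert not vaf_filter(make_call(alt_count=36, ref_count=14)).passed  # 0.72
        # 0.7 has no exact float representation; exact rationals must still work
        empty = dict(
            alt_read_positions=[], ref_read_positions=[], alt_strands=[],
            ref_strands=[], alt_bq=[], ref_bq=[], alt_mq=[], ref_mq=[],
        )
        big = make_call(alt_count=7_000_001, ref_count=2_999_999, **empty)
        assert vaf_filter(big).passed is False
        assert vaf_filter(make_call(alt_count=700, ref_count=300, **empty)).passed


def _catalog_rows(spec):
    """spec: list of (sample, chrom, pos, ref, alt)."""
    return MutationCatalog(
        pd.DataFrame(
            [
                {
                    "sample": s,
                    "individual": f"i_{s}",
                    "tissue": "",
                    "chrom": c,
                    "pos": p,
                    "ref": r,
                    "alt": a,
                    "coverage": 100,
                    "alt_count": 10,
                    "vaf": 0.1,
                    "flags": "",
                }
                for s, c, p, r, a in spec
            ]
        )
    )


class TestRecurrence:
    def test_tissue_recurrence_boundary(self):
        cohort = make_cohort(n_samples=5)  # one tissue of 5 samples
        # identity in exactly 2/5 = 40 % of the tissue: removed (>= rule)
        cat = _catalog_rows(
            [
                ("sample000", "chr1", 10, "A", "T"),
                ("sample001", "chr1", 10, "A", "T"),
                ("sample000", "chr2", 99, "C", "G"),
            ]
        )
        filtered, tissue_removed, _ = recurrence_filter(cat, cohort, 0.40, 1.0)
        assert ("chr1", 10, "A", "T") in tissue_removed
        assert len(filtered) == 1
        assert filtered.df.iloc[0]["chrom"] == "chr2"

    def test_below_threshold_survives(self):
        cohort = make_cohort(n_samples=6)
        cat = _catalog_rows(
            [
                ("sample000", "chr1", 10, "A", "T"),
                ("sample001", "chr1", 10, "A", "T"),  # 2/6 = 33 % < 40 %
            ]
        )
        filtered, tissue_removed, cohort_removed = recurrence_filter(cat, cohort, 0.40, 0.40)
        assert not tissue_removed and not cohort_removed
        assert len(filtered) == 2

    def test_cohort_recurrence_boundary(self):
        cohort = make_cohort(n_samples=50)
        # 2/50 = 4 % exactly: removed
        cat = _catalog_rows(
            [
                ("sample000", "chr1", 10, "A", "T"),
                ("sample049", "chr1", 10, "A", "T"),
                ("sample001", "chr3", 5, "G", "C"),
            ]
        )
        filtered, _, cohort_removed = recurrence_filter(cat, cohort, 2.0, 0.04)
        assert ("chr1", 10, "A", "T") in cohort_removed
        assert len(filtered) == 1

    def test_removal_applies_to_every_sample(self):
        cohort = make_cohort(n_samples=5)
        cat = _catalog_rows(
            [(f"sample{i:03d}", "chr1", 10, "A", "T") for i in range(4)]
        )
        filtered, _, _ = recurrence_filter(cat, cohort, 0.40, 1.0)
        assert len(filtered) == 0


class TestHypermutated:
    def test_outlier_removed_upper_tail_only(self):
        cohort = make_cohort(n_samples=30, seed=5)
        rng = np.random.default_rng(5)
        base = 500 + 1e-5 * cohort.covariates["seq_depth"].to_numpy()
        counts = pd.Series(base + rng.normal(0, 20, 30), index=cohort.covariates.index)
        counts.iloc[3] += 5000.0  # hypermutated
        counts.iloc[7] -= 5000.0  # low outlier: must NOT be excluded
        excluded, resid = hypermutated_filter(counts, cohort.covariates)
        assert excluded == {counts.index[3]}
        assert resid.loc[counts.index[3]] > 1500

    def test_singular_design_names_pair(self):
        cov = make_cohort(12).covariates.copy()
        cov["bmi"] = 2.0 * cov["age"]
        counts = pd.Series(1.0, index=cov.index)
        with pytest.raises(ValueError, match="age.*bmi|bmi.*age"):
            hypermutated_filter(counts, cov)

    def test_missing_covariates_rejected(self):
        cov = make_cohort(12).covariates.drop(columns=["bmi"])
        with pytest.raises(ValueError, match="bmi"):
            hypermutated_filter(pd.Series(1.0, index=cov.index), cov)


class TestCascade:
    def _setup(self):
        cohort = make_cohort(30)
        exons = ExonSet([ExonRecord("chr1", 0, 10_000, "g1", "+")])
        calls = {s: [] for s in cohort.samples}
        clean = make_call(sample="sample000", pos=500, seed=10)
        biased = make_call(sample="sample000", pos=600, alt_strands=["+"] * 10, seed=11)
        flagged = make_call(sample="sample001", pos=700, seed=12)
        flagged.flags.add("no_ref_allele")
        calls["sample000"] = [clean, biased]
        calls["sample001"] = [flagged]
        return cohort, exons, calls

    def test_cascade_keeps_clean_call_and_accounts_attrition(self):
        cohort, exons, calls = self._setup()
        catalog, attrition = run_filter_cascade(
            calls, {}, GermlineSet(), exons, cohort, FilterParams(seed=1)
        )
        assert len(catalog) == 1
        assert catalog.df.iloc[0]["pos"] == 500
        assert catalog.df.iloc[0]["tissue"] == "tissue0"
        row = attrition.loc["sample000"]
        assert row["region_mask"] == 1.0
        assert row["strand_bias"] == 0.5  # biased call dropped here
        assert row["hypermutated_sample"] == 0.5
        # no_ref_allele candidates are dropped before accounting starts
        assert (attrition.loc["sample001"] == 1.0).all()

    def test_cascade_idempotent(self):
        cohort, exons, calls = self._setup()
        catalog1, _ = run_filter_cascade(
            calls, {}, GermlineSet(), exons, cohort, FilterParams(seed=1)
        )
        kept = {
            (r.sample, r.pos, r.alt) for r in catalog1.df.itertuples(index=False)
        }
        surviving = {
            s: [c for c in cs if (s, c.pos, c.alt) in kept] for s, cs in calls.items()
        }
        catalog2, _ = run_filter_cascade(
            surviving, {}, GermlineSet(), exons, cohort, FilterParams(seed=1)
        )
        assert catalog1 == catalog2
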