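"""Germline exclusion and the 13-filter artifact cascade.

Candidate variants surviving the two-allele scan are screened against:
region masks (blacklisted chromosome classes, common SNPs, RNA-edit sites),
per-individual germline variants, splice-junction proximity (< 7 bp from an
exon end), a binomial sequencing-error model (p = 0.001, alpha = 1e-4),
four Mann-Whitney rank-bias tests (read position, mapping quality, base
quality, strand), a variant-distance test on alternate-read positions, a
VAF ceiling of 0.7, tissue-level (>= 40 % of samples in a tissue) and
cohort-level (>= 4 % of all samples) recurrence, and finally removal of
hyper-mutated samples (regression residual > 1500).

Every filter is conjunctive, so the retained set does not depend on order;
the per-filter attrition table does, and follows the sequence above.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rnamut.caller import CandidateVariant
from rnamut.io_formats import (
    ExonSet,
    GermlineSet,
    MutationCatalog,
    RegionMask,
)

PRIMARY_CHROMS = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

BIAS_TESTS = ("read_position", "mapping_quality", "base_quality", "strand")

FILTER_ORDER = [
    "blacklist",
    "common_snp",
    "rna_edit",
    "germline",
    "splice_distance",
    "seq_error",
    "read_position_bias",
    "mapping_quality_bias",
    "base_quality_bias",
    "strand_bias",
    "variant_distance",
    "vaf",
    "tissue_recurrence",
    "cohort_recurrence",
    "hypermutated_sample",
]


@dataclass
class FilterVerdict:
    """Outcome of one filter on one call."""

    name: str
    passed: bool
    flags: set[str] = field(default_factory=set)
    p_value: float | None = None


@dataclass
class FilterParams:
    """Every tunable threshold of the cascade, with the pipeline defaults."""

    p_err: float = 0.001
    seq_error_alpha: float = 1e-4
    bias_alpha: float = 0.05
    splice_min_dist: int = 7
    max_vaf: float = 0.7
    vd_alpha: float = 0.05
    vd_n_sim: int = 1000
    tissue_frac: float = 0.40
    cohort_frac: float = 0.04
    resid_max: float = 1500.0
    seed: int = 0
    germline_strict: bool = False


@dataclass
class CohortContext:
    """Sample-to-tissue/individual mapping plus regression covariates."""

    sample_tissue: dict[str, str]
    sample_individual: dict[str, str]
    covariates: pd.DataFrame | None = None  # index sample; seq_depth, age, sex, bmi

    def __post_init__(self) -> None:
        missing = set(self.sample_tissue) ^ set(self.sample_individual)
        if missing:
            raise ValueError(f"samples without both tissue and individual: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_tissue)

    def tissues(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.sample_tissue.items():
            out.setdefault(t, []).append(s)
        return out


def _is_blacklisted_chrom(chrom: str) -> bool:
    return chrom not in PRIMARY_CHROMS


def region_mask_filter(call: CandidateVariant, masks: Mapping[str, RegionMask]) -> FilterVerdict:
    """Fail calls on masked chromosome classes or inside any region mask.

    Sex chromosomes, the mitochondrial genome and non-primary scaffolds fail
    as ``blacklist`` regardless of interval content.
    """
    if _is_blacklisted_chrom(call.chrom):
        return FilterVerdict("blacklist", False)
    for label in ("blacklist", "common_snp", "rna_edit"):
        mask = masks.get(label)
        if mask is not None and mask.contains(call.chrom, call.pos):
            return FilterVerdict(label, False)
    return FilterVerdict("region_mask", True)


def germline_filter(
    call: CandidateVariant,
    germline: GermlineSet,
    individual: str,
    strict: bool = False,
) -> FilterVerdict:
    """Fail a call matching a germline alt allele of the same individual.

    Matching is allele-specific: a different alternate base at a germline
    site passes. Unknown individuals error in strict mode, otherwise pass
    with a ``germline_unavailable`` flag.
    """
    if not germline.has_individual(individual):
        if strict:
            raise KeyError(f"individual {individual!r} absent from germline set")
        return FilterVerdict("germline", True, flags={"germline_unavailable"})
    hit = germline.matches(individual, call.chrom, call.pos, call.alt)
    return FilterVerdict("germline", not hit)


def splice_distance_filter(
    call: CandidateVariant, exons: ExonSet, min_dist: int = 7
) -> FilterVerdict:
    """Fail calls closer than ``min_dist`` bp to the nearest exon boundary."""
    d = exons.distance_to_nearest_end(call.chrom, call.pos)
    if d is None:
        return FilterVerdict("splice_distance", True, flags={"no_exon_annotation"})
    return FilterVerdict("splice_distance", d >= min_dist)


def seq_error_filter(
    call: CandidateVariant, p_err: float = 0.001, alpha: float = 1e-4
) -> FilterVerdict:
    """Binomial sequencing-error test.

    P(X >= n) with X ~ Binomial(c, p_err): the chance that sequencing errors
    alone produce the observed alternate support. Fail iff that probability
    exceeds ``alpha``.
    """
    c, n = call.coverage, call.alt_count
    if not (0 <= n <= c):
        raise ValueError(f"invalid counts n={n}, c={c}")
    p = float(stats.binom.sf(n - 1, c, p_err))  # upper tail including n
    return FilterVerdict("seq_error", p <= alpha, p_value=p)


def _mwu(alt_vals: Sequence[float], ref_vals: Sequence[float]) -> float:
    alt = np.asarray(alt_vals, dtype=float)
    ref = np.asarray(ref_vals, dtype=float)
    if np.ptp(np.concatenate([alt, ref])) == 0:
        return 1.0  # identical constant values carry no rank information
    res = stats.mannwhitneyu(alt, ref, alternative="two-sided", method="auto")
    return float(res.pvalue)


def rank_bias_tests(call: CandidateVariant, alpha: float = 0.05) -> dict[str, FilterVerdict]:
    """Two-sided Mann-Whitney tests of alt- vs ref-read attributes.

    One verdict per attribute (read position, mapping quality, base quality,
    strand coded 0/1). An empty group makes a test untestable: it passes
    with an ``untestable`` flag.
    """
    attr_pairs = {
        "read_position": (call.alt_read_positions, call.ref_read_positions),
        "mapping_quality": (call.alt_mapping_qualities, call.ref_mapping_qualities),
        "base_quality": (call.alt_base_qualities, call.ref_base_qualities),
        "strand": (
            [1.0 if s == "+" else 0.0 for s in call.alt_strands],
            [1.0 if s == "+" else 0.0 for s in call.ref_strands],
        ),
    }
    out: dict[str, FilterVerdict] = {}
    for name, (alt_vals, ref_vals) in attr_pairs.items():
        if len(alt_vals) < 1 or len(ref_vals) < 1:
            out[name] = FilterVerdict(f"{name}_bias", True, flags={"untestable"})
            continue
        p = _mwu(alt_vals, ref_vals)
        out[name] = FilterVerdict(f"{name}_bias", p >= alpha, p_value=p)
    return out


def _call_seed(seed: int, call: CandidateVariant) -> int:
    key = f"{call.sample}:{call.chrom}:{call.pos}:{call.alt}".encode()
    return (seed + zlib.crc32(key)) % (2**31)


def variant_distance_filter(
    call: CandidateVariant,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> FilterVerdict:
    """Two-tailed test of the mean pairwise distance between alt-read positions.

    Alternate reads that consistently carry the variant at the same offset
    within the read (mean pairwise distance near zero) or at implausibly
    spread offsets indicate mapping artifacts. The null distribution draws
    the same number of positions uniformly from the observed read-position
    range and is simulated ``n_sim`` times.
    """
    positions = np.asarray(call.alt_read_positions, dtype=float)
    n = len(positions)
    if n < 2:
        return FilterVerdict("variant_distance", True, flags={"untestable"})

    def mean_pairwise(x: np.ndarray) -> float:
        diff = np.abs(x[:, None] - x[None, :])
        return float(diff.sum() / (len(x) * (len(x) - 1)))

    stat = mean_pairwise(positions)
    support = np.concatenate(
        [positions, np.asarray(call.ref_read_positions, dtype=float)]
    )
    lo, hi = int(support.min()), int(support.max())
    rng = np.random.default_rng(_call_seed(seed, call))
    sims = np.empty(n_sim)
    for i in range(n_sim):
        sims[i] = mean_pairwise(rng.integers(lo, hi + 1, size=n).astype(float))
    frac_le = float(np.mean(sims <= stat))
    frac_ge = float(np.mean(sims >= stat))
    passed = frac_le >= alpha / 2 and frac_ge >= alpha / 2
    return FilterVerdict("variant_distance", passed, p_value=2 * min(frac_le, frac_ge))


def vaf_filter(call: CandidateVariant, max_vaf: float = 0.7) -> FilterVerdict:
    """Fail calls with VAF strictly greater than ``max_vaf`` (exact rational)."""
    vaf = Fraction(call.alt_count, call.coverage)
    return FilterVerdict("vaf", vaf <= Fraction(str(max_vaf)))


def recurrence_filter(
    catalog: MutationCatalog,
    cohort: CohortContext,
    tissue_frac: float = 0.40,
    cohort_frac: float = 0.04,
) -> tuple[MutationCatalog, set[tuple], set[tuple]]:
    """Remove systematically recurrent mutation identities everywhere.

    A mutation identity (chrom, pos, ref, alt) called in at least
    ``tissue_frac`` of the samples of any one tissue, or in at least
    ``cohort_frac`` of all samples, is removed from every sample in every
    tissue. Thresholds compare exact rationals, so boundary fractions are
    unambiguous. Returns (filtered catalog, tissue-level identities removed,
    cohort-level identities removed).
    """
    df = catalog.df
    tissue_cut = tissue_frac if isinstance(tissue_frac, Fraction) else Fraction(str(tissue_frac))
    cohort_cut = cohort_frac if isinstance(cohort_frac, Fraction) else Fraction(str(cohort_frac))
    tissues = cohort.tissues()
    n_all = len(cohort.samples)

    key_cols = ["chrom", "pos", "ref", "alt"]
    tissue_removed: set[tuple] = set()
    cohort_removed: set[tuple] = set()
    if not df.empty:
        calls = df.drop_duplicates(subset=["sample"] + key_cols)
        calls = calls.assign(tissue=calls["sample"].map(cohort.sample_tissue))
        for key, grp in calls.groupby(key_cols, sort=False):
            per_tissue = grp.groupby("tissue")["sample"].nunique()
            for tissue, cnt in per_tissue.items():
                denom = len(tissues.get(tissue, []))
                if denom and Fraction(int(cnt), denom) >= tissue_cut:
                    tissue_removed.add(key)
                    break
            if n_all and Fraction(grp["sample"].nunique(), n_all) >= cohort_cut:
                cohort_removed.add(key)
    removed = tissue_removed | cohort_removed
    if removed:
        keys = df[key_cols].apply(tuple, axis=1)
        df = df[~keys.isin(removed)]
    return MutationCatalog(df.reset_index(drop=True)), tissue_removed, cohort_removed


def hypermutated_filter(
    counts: pd.Series,
    covariates: pd.DataFrame,
    resid_max: float = 1500.0,
) -> tuple[set[str], pd.Series]:
    """Identify hyper-mutated samples by regression residual.

    Mutation counts are regressed (OLS) on sequencing depth, age, sex
    (coded 0/1) and BMI; samples whose residual exceeds ``resid_max`` are
    excluded entirely. There is no lower-tail exclusion. Returns the
    excluded sample set and the residuals.
    """
    required = ["seq_depth", "age", "sex", "bmi"]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing columns: {missing}")
    samples = counts.index
    X = covariates.loc[samples, required].astype(float)
    if len(samples) < len(required) + 2:
        raise ValueError(
            f"need at least {len(required) + 2} samples to fit, got {len(samples)}"
        )
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise ValueError(f"singular design: covariates {pair[0]} and {pair[1]} are collinear")
    beta, *_ = np.linalg.lstsq(design, counts.to_numpy(dtype=float), rcond=None)
    resid = pd.Series(counts.to_numpy(dtype=float) - design @ beta, index=samples)
    excluded = set(resid.index[resid > resid_max])
    return excluded, resid


def _call_record(call: CandidateVariant, individual: str, tissue: str) -> dict:
    return {
        "sample": call.sample,
        "individual": individual,
        "tissue": tissue,
        "chrom": call.chrom,
        "pos": call.pos,
        "ref": call.ref,
        "alt": call.alt,
        "coverage": call.coverage,
        "alt_count": call.alt_count,
        "vaf": call.vaf,
        "flags": ",".join(sorted(call.flags)),
    }


def run_filter_cascade(
    candidates: Mapping[str, Sequence[CandidateVariant]],
    masks: Mapping[str, RegionMask],
    germline: GermlineSet,
    exons: ExonSet,
    cohort: CohortContext,
    params: FilterParams | None = None,
) -> tuple[MutationCatalog, pd.DataFrame]:
    """Apply every filter in pipeline order with attrition accounting.

    ``candidates`` maps sample id to its candidate variants. The returned
    attrition table has one row per sample and one column per filter step,
    holding the fraction of that sample's candidates surviving after the
    step (sequential application, first-fail short-circuit).
    """
    params = params or FilterParams()
    per_sample_steps = [
        "region_mask",
        "germline",
        "splice_distance",
        "seq_error",
        "read_position_bias",
        "mapping_quality_bias",
        "base_quality_bias",
        "strand_bias",
        "variant_distance",
        "vaf",
    ]
    cohort_steps = ["tissue_recurrence", "cohort_recurrence", "hypermutated_sample"]

    survivors: dict[str, list[CandidateVariant]] = {}
    attrition_rows: dict[str, dict[str, float]] = {}

    for sample in sorted(candidates):
        calls = [c for c in candidates[sample] if "no_ref_allele" not in c.flags]
        n0 = len(calls)
        individual = cohort.sample_individual[sample]
        row: dict[str, float] = {}

        def record(step: str, remaining: list[CandidateVariant]) -> None:
            row[step] = len(remaining) / n0 if n0 else 1.0

        calls = [c for c in calls if region_mask_filter(c, masks).passed]
        record("region_mask", calls)
        calls = [
            c
            for c in calls
            if germline_filter(c, germline, individual, params.germline_strict).passed
        ]
        record("germline", calls)
        calls = [
            c for c in calls if splice_distance_filter(c, exons, params.splice_min_dist).passed
        ]
        record("splice_distance", calls)
        calls = [
            c
            for c in calls
            if seq_error_filter(c, params.p_err, params.seq_error_alpha).passed
        ]
        record("seq_error", calls)
        for test in BIAS_TESTS:
            calls = [c for c in calls if rank_bias_tests(c, params.bias_alpha)[test].passed]
            record(f"{test}_bias", calls)
        calls = [
            c
            for c in calls
            if variant_distance_filter(
                c, params.vd_alpha, params.vd_n_sim, params.seed
            ).passed
        ]
        record("variant_distance", calls)
        calls = [c for c in calls if vaf_filter(c, params.max_vaf).passed]
        record("vaf", calls)

        survivors[sample] = calls
        attrition_rows[sample] = row

    records = [
        _call_record(c, cohort.sample_individual[s], cohort.sample_tissue[s])
        for s, calls in survivors.items()
        for c in calls
    ]
    catalog = MutationCatalog.from_records(records)

    # recurrence applied in two accounted steps: tissue-level then cohort-level
    catalog_t, _, _ = recurrence_filter(catalog, cohort, params.tissue_frac, Fraction(2))
    catalog_tc, _, _ = recurrence_filter(catalog_t, cohort, Fraction(2), params.cohort_frac)
    catalog = catalog_tc

    n_initial = {s: len([c for c in candidates[s] if "no_ref_allele" not in c.flags]) for s in candidates}
    for step, cat in (("tissue_recurrence", catalog_t), ("cohort_recurrence", catalog_tc)):
        per_sample = cat.df.groupby("sample").size()
        for sample in attrition_rows:
            n0 = n_initial[sample]
            attrition_rows[sample][step] = (
                per_sample.get(sample, 0) / n0 if n0 else 1.0
            )

    # hyper-mutated sample exclusion (cohort level)
    excluded: set[str] = set()
    if cohort.covariates is not None and len(cohort.samples) >= 6:
        counts = pd.Series(
            {s: int((catalog.df["sample"] == s).sum()) for s in cohort.samples},
            dtype=float,
        )
        excluded, _ = hypermutated_filter(counts, cohort.covariates, params.resid_max)
        if excluded:
            catalog = MutationCatalog(
                catalog.df[~catalog.df["sample"].isin(excluded)].reset_index(drop=True)
            )
    for sample in attrition_rows:
        n0 = n_initial[sample]
        kept = 0 if sample in excluded else int((catalog.df["sample"] == sample).sum())
        attrition_rows[sample]["hypermutated_sample"] = kept / n0 if n0 else 1.0

    attrition = pd.DataFrame.from_dict(attrition_rows, orient="index")
    attrition = attrition[per_sample_steps + cohort_steps]
    attrition.index.name = "sample"
    return catalog, attrition
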