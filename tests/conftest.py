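"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rnamut.caller import CandidateVariant, ReadObservation
from rnamut.filters import CohortContext


def make_observation(
    chrom="chr1",
    pos=100,
    base="A",
    base_quality=37,
    mapping_quality=255,
    read_position=30,
    strand="+",
    read_name="r0",
    read_key=None,
):
    if read_key is None:
        read_key = (chrom, pos - read_position + 1, "76M", strand, 0)
    return ReadObservation(
        chrom=chrom,
        pos=pos,
        base=base,
        base_quality=base_quality,
        mapping_quality=mapping_quality,
        read_position=read_position,
        strand=strand,
        read_name=read_name,
        read_key=read_key,
    )


def make_call(
    sample="s0",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    alt_count=10,
    ref_count=90,
    alt_read_positions=None,
    ref_read_positions=None,
    alt_strands=None,
    ref_strands=None,
    alt_bq=None,
    ref_bq=None,
    alt_mq=None,
    ref_mq=None,
    seed=0,
):
    """A candidate variant with unbiased attributes unless overridden."""
    rng = np.random.default_rng(seed)
    if alt_read_positions is None:
        alt_read_positions = list(rng.integers(1, 77, alt_count))
    if ref_read_positions is None:
        ref_read_positions = list(rng.integers(1, 77, ref_count))
    if alt_strands is None:
        alt_strands = ["+" if v < 0.5 else "-" for v in rng.random(alt_count)]
    if ref_strands is None:
        ref_strands = ["+" if v < 0.5 else "-" for v in rng.random(ref_count)]
    return CandidateVariant(
        sample=sample,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        coverage=alt_count + ref_count,
        alt_count=alt_count,
        alt_base_qualities=alt_bq if alt_bq is not None else [37] * alt_count,
        ref_base_qualities=ref_bq if ref_bq is not None else [37] * ref_count,
        alt_mapping_qualities=alt_mq if alt_mq is not None else [255] * alt_count,
        ref_mapping_qualities=ref_mq if ref_mq is not None else [255] * ref_count,
        alt_read_positions=[int(v) for v in alt_read_positions],
        ref_read_positions=[int(v) for v in ref_read_positions],
        alt_strands=list(alt_strands),
        ref_strands=list(ref_strands),
    )


def make_cohort(n_samples=30, n_tissues=1, seed=0):
    """A cohort context large enough that singleton calls survive recurrence.

    Cohort recurrence removes identities in >= 4 % of samples, so n >= 26
    keeps 1/n below the threshold; >= 3 samples per tissue keeps singletons
    below the 40 % tissue threshold.
    """
    rng = np.random.default_rng(seed)
    samples = [f"sample{i:03d}" for i in range(n_samples)]
    sample_tissue = {s: f"tissue{i % n_tissues}" for i, s in enumerate(samples)}
    sample_individual = {s: f"indiv{i:03d}" for i, s in enumerate(samples)}
    covariates = pd.DataFrame(
        {
            "seq_depth": rng.normal(50e6, 10e6, n_samples),
            "age": rng.normal(52, 13, n_samples),
            "sex": rng.integers(0, 2, n_samples),
            "bmi": rng.normal(27, 4.5, n_samples),
        },
        index=samples,
    )
    return CohortContext(sample_tissue, sample_individual, covariates)


@pytest.fixture
def cohort30():
    return make_cohort(30)
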