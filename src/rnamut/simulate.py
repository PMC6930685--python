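"""Synthetic data generators for every stage of the pipeline.

Protected donor-level sequencing data cannot be redistributed, so the
package is exercised end-to-end on simulated inputs that reproduce the
statistical structure the caller and the downstream analyses assume:

* read-level pileups with planted somatic clones (chosen VAFs), germline
  heterozygotes (VAF 0.5), RNA-edit positions (A>G), per-base sequencing
  errors at the Phred-30 rate of 0.001, and artifact variants that violate
  exactly one read-level bias (read position, strand, base quality, mapping
  quality, or splice proximity);
* matched DNA pileup summaries for FDR validation;
* expression/covariate cohorts with planted linear effects on mutation load;
* per-exon depth, mutation-count and histone-mark tables with planted
  chromatin effects.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rnamut.caller import ReadObservation
from rnamut.io_formats import ExonRecord, ExonSet, RegionMask

BASES = ("A", "C", "G", "T")

ARTIFACT_BIASES = (
    "read_position",
    "strand",
    "base_quality",
    "mapping_quality",
    "splice_proximal",
)


@dataclass(frozen=True)
class PlantedEvent:
    """One planted variant: somatic clone, germline het, RNA edit or artifact."""

    pos: int
    alt: str
    vaf: float
    kind: str  # 'somatic' | 'germline' | 'rna_edit' | 'artifact'
    bias: str | None = None  # artifact bias class
    samples: tuple[int, ...] | None = None  # None = planted in every sample

    def __post_init__(self) -> None:
        if not (0.0 < self.vaf <= 1.0):
            raise ValueError(f"event VAF must be in (0, 1], got {self.vaf}")
        if self.kind not in ("somatic", "germline", "rna_edit", "artifact"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "artifact" and self.bias not in ARTIFACT_BIASES:
            raise ValueError(f"artifact bias must be one of {ARTIFACT_BIASES}")


@dataclass
class SimConfig:
    """Study conditions for the pileup simulator."""

    n_samples: int = 1
    n_sites: int = 2000
    contig: str = "chr1"
    coverage_mean: float = 100.0
    base_error_rate: float = 0.001
    read_length: int = 76
    seed: int = 0
    events: list[PlantedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0 <= ev.pos < self.n_sites):
                raise ValueError(
                    f"event at pos {ev.pos} outside simulated contig [0, {self.n_sites})"
                )
        seen: dict[tuple[int | None, str], set[int]] = {}
        for ev in self.events:
            samples = ev.samples if ev.samples is not None else (None,)
            for s in samples:
                key = (s, ev.kind)
                # disjointness across classes within a sample
                for (s2, kind2), positions in seen.items():
                    if (s2 == s or s2 is None or s is None) and kind2 != ev.kind:
                        if ev.pos in positions:
                            raise ValueError(
                                f"pos {ev.pos} planted in two event classes for one sample"
                            )
                seen.setdefault(key, set()).add(ev.pos)


@dataclass
class TruthSet:
    """Planted ground truth: what the caller should find and reject."""

    somatic: dict[str, list[PlantedEvent]]
    germline: dict[str, list[PlantedEvent]]
    rna_edit: dict[str, list[PlantedEvent]]
    artifacts: dict[str, list[PlantedEvent]]

    def somatic_keys(self, sample: str) -> set[tuple[int, str]]:
        return {(e.pos, e.alt) for e in self.somatic.get(sample, [])}

    def artifact_keys(self, sample: str, bias: str | None = None) -> set[tuple[int, str]]:
        return {
            (e.pos, e.alt)
            for e in self.artifacts.get(sample, [])
            if bias is None or e.bias == bias
        }


@dataclass
class SimulatedPileups:
    """Simulator output: observations, reference, annotation and truth."""

    observations: dict[str, list[ReadObservation]]
    truth: TruthSet
    reference: str
    contig: str
    exons: ExonSet

    def ref_getter(self, chrom: str, pos: int) -> str:
        if chrom != self.contig or not (0 <= pos < len(self.reference)):
            raise KeyError(f"{chrom}:{pos} outside simulated reference")
        return self.reference[pos]

    def rna_edit_mask(self) -> RegionMask:
        """Mask of planted RNA-edit positions (as length-1 intervals)."""
        mask = RegionMask("rna_edit")
        for events in self.truth.rna_edit.values():
            for ev in events:
                mask.add(self.contig, ev.pos, ev.pos + 1)
        mask._normalize()
        return mask


def _sample_name(i: int) -> str:
    return f"sample{i:03d}"


def _draw_attrs(rng: np.random.Generator, n: int, read_length: int):
    """Null read-level attributes: shared by ref reads and unbiased alt reads.

    Position in read is uniform, strands balanced (non-stranded library).
    Uniquely mapped reads carry one mapping quality (MAPQ 255) and binned
    base-quality scores leave a single bin above the Phred-30 floor, so
    these two attributes are constant under the null.
    """
    read_pos = rng.integers(1, read_length + 1, size=n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    bq = np.full(n, 37)
    mq = np.full(n, 255)
    return read_pos, strand, bq, mq


def _biased_attrs(rng: np.random.Generator, n: int, read_length: int, bias: str | None):
    read_pos, strand, bq, mq = _draw_attrs(rng, n, read_length)
    if bias == "read_position":
        read_pos = np.full(n, 5)
    elif bias == "strand":
        strand = np.full(n, "+")
    elif bias == "base_quality":
        bq = rng.integers(30, 33, size=n)  # just above the quality floor
    elif bias == "mapping_quality":
        mq = rng.integers(15, 25, size=n)
    return read_pos, strand, bq, mq


def simulate_pileups(config: SimConfig) -> SimulatedPileups:
    """Generate per-sample read observations with planted events.

    Per site, coverage is Poisson with the configured mean; a planted event
    contributes Binomial(coverage, VAF) alternate reads, and every remaining
    read is an error with probability 0.001 spread uniformly over the three
    non-reference bases. Read-level attributes (position in read, strand,
    base and mapping quality) are drawn from their null distributions except
    for artifact events, which violate exactly their tagged bias.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    # reference sequence; RNA-edit events require an A at their site
    ref_arr = rng.choice(list(BASES), size=n)
    for ev in config.events:
        if ev.kind == "rna_edit":
            ref_arr[ev.pos] = "A"
    for ev in config.events:  # planted alts must differ from the reference
        if ev.alt == ref_arr[ev.pos]:
            choices = [b for b in BASES if b != ev.alt]
            ref_arr[ev.pos] = choices[rng.integers(len(choices))]
    reference = "".join(ref_arr)

    # single full-length exon on the + strand: only the first and last 7 bp
    # are splice-proximal, so events planted mid-region are clean
    exons = ExonSet([ExonRecord(config.contig, 0, n, "gene1", "+")])

    events_by_sample: dict[int, dict[int, PlantedEvent]] = {
        i: {} for i in range(config.n_samples)
    }
    for ev in config.events:
        targets = ev.samples if ev.samples is not None else range(config.n_samples)
        for i in targets:
            events_by_sample[i][ev.pos] = ev

    observations: dict[str, list[ReadObservation]] = {}
    truth = TruthSet({}, {}, {}, {})
    read_counter = 0

    for i in range(config.n_samples):
        sample = _sample_name(i)
        obs: list[ReadObservation] = []
        for kind, store in (
            ("somatic", truth.somatic),
            ("germline", truth.germline),
            ("rna_edit", truth.rna_edit),
            ("artifact", truth.artifacts),
        ):
            store[sample] = [e for e in events_by_sample[i].values() if e.kind == kind]

        coverages = rng.poisson(config.coverage_mean, size=n)
        for pos in range(n):
            cov = int(coverages[pos])
            if cov == 0:
                continue
            ref = reference[pos]
            event = events_by_sample[i].get(pos)
            n_alt = 0
            if event is not None:
                n_alt = int(rng.binomial(cov, event.vaf))
            n_rest = cov - n_alt
            # sequencing errors among non-event reads
            err_bases = [b for b in BASES if b != ref]
            n_err = int(rng.binomial(n_rest, config.base_error_rate))
            err_choice = rng.integers(0, 3, size=n_err)

            bases = []
            biases = []
            if event is not None and n_alt:
                bases.extend([event.alt] * n_alt)
                biases.extend([event.bias if event.kind == "artifact" else None] * n_alt)
            for e in err_choice:
                bases.append(err_bases[int(e)])
                biases.append(None)
            bases.extend([ref] * (n_rest - n_err))
            biases.extend([None] * (n_rest - n_err))

            groups: dict[str | None, list[int]] = {}
            for idx, b in enumerate(biases):
                groups.setdefault(b, []).append(idx)
            attrs = [None] * len(bases)
            for bias, idxs in groups.items():
                rp, st, bq, mq = _biased_attrs(rng, len(idxs), config.read_length, bias)
                for j, idx in enumerate(idxs):
                    attrs[idx] = (int(rp[j]), str(st[j]), int(bq[j]), int(mq[j]))

            for base, (rp, st, bq, mq) in zip(bases, attrs):
                name = f"read{read_counter}"
                start = max(0, pos - rp + 1)
                # distinct mate starts keep simulated fragments from being
                # mistaken for PCR duplicates under dedup
                obs.append(
                    ReadObservation(
                        chrom=config.contig,
                        pos=pos,
                        base=base,
                        base_quality=bq,
                        mapping_quality=mq,
                        read_position=rp,
                        strand=st,
                        read_name=name,
                        read_key=(
                            config.contig,
                            start,
                            f"{config.read_length}M",
                            st,
                            read_counter,
                        ),
                    )
                )
                read_counter += 1
        observations[sample] = obs

    return SimulatedPileups(observations, truth, reference, config.contig, exons)


def simulate_matched_dna(
    sim: SimulatedPileups,
    dna_coverage_mean: float = 80.0,
    seed: int = 0,
) -> dict[str, dict[tuple[int, str], tuple[int, int]]]:
    """Matched DNA-seq support at every planted site.

    Planted somatic (and germline) events receive Binomial(C_DNA, VAF) DNA
    alternate reads; artifact and RNA-edit events are RNA-only and receive
    zero DNA support. Returns per sample a map (pos, alt) -> (C_DNA, A_DNA).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[tuple[int, str], tuple[int, int]]] = {}
    for sample in sim.observations:
        support: dict[tuple[int, str], tuple[int, int]] = {}
        for ev in sim.truth.somatic.get(sample, []) + sim.truth.germline.get(sample, []):
            c = int(rng.poisson(dna_coverage_mean))
            a = int(rng.binomial(c, ev.vaf)) if c else 0
            support[(ev.pos, ev.alt)] = (c, a)
        for ev in sim.truth.artifacts.get(sample, []) + sim.truth.rna_edit.get(sample, []):
            c = int(rng.poisson(dna_coverage_mean))
            support[(ev.pos, ev.alt)] = (c, 0)
        out[sample] = support
    return out


# ---------------------------------------------------------------------------
# Cohort simulation: expression, covariates and mutation load

COVARIATE_DEFAULTS: dict[str, tuple[float, float]] = {
    # name -> (mean, sd) of the simulated covariate
    "seq_depth": (50e6, 10e6),
    "shannon_diversity": (9.0, 0.5),
    "pax_time": (300.0, 120.0),
    "ischemic_time": (400.0, 200.0),
    "rin": (7.5, 0.8),
    "age": (52.0, 13.0),
    "bmi": (27.0, 4.5),
}


def simulate_cohort(
    n_genes: int,
    n_samples: int,
    planted_gamma: float | np.ndarray = 0.0,
    covariate_betas: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    tissue: str = "tissueA",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, dict]:
    """Simulate an expression matrix, sample metadata and mutation loads.

    Mutation load follows the linear model
    ``load = b0 + sum_n b_n cov_n + sum_g gamma_g z_g + noise`` where ``z_g``
    is the standard-normal latent expression of gene g (TPM is its lognormal
    transform), covariates include sequencing depth, age, sex, BMI and three
    genotype principal components, and noise is Gaussian.

    Returns (expression TPM genes x samples, metadata, loads, truth dict).
    """
    n_cov = 7 + 3  # named covariates + 3 genotype PCs
    if n_samples < n_cov + 2:
        raise ValueError(
            f"n_samples={n_samples} too small for {n_cov} covariates (need >= {n_cov + 2})"
        )
    rng = np.random.default_rng(seed)
    gamma = np.broadcast_to(np.asarray(planted_gamma, dtype=float), (n_genes,)).copy()

    samples = [_sample_name(i) for i in range(n_samples)]
    meta = pd.DataFrame({"sample": samples})
    meta["individual"] = [f"indiv{i:03d}" for i in range(n_samples)]
    meta["tissue"] = tissue
    for name, (mu, sd) in COVARIATE_DEFAULTS.items():
        meta[name] = rng.normal(mu, sd, size=n_samples)
    meta["sex"] = rng.integers(0, 2, size=n_samples)
    for k in (1, 2, 3):
        meta[f"pc{k}"] = rng.normal(0.0, 1.0, size=n_samples)

    z = rng.standard_normal((n_genes, n_samples))
    tpm = np.exp(1.0 * z + 3.0)  # lognormal TPM, median ~e^3 ~ 20
    genes = [f"gene{g:05d}" for g in range(n_genes)]
    expression = pd.DataFrame(tpm, index=genes, columns=samples)

    betas = dict(covariate_betas or {})
    betas.setdefault("seq_depth", 2e-5)  # ~ +1000 mutations per 50M reads
    betas.setdefault("age", 5.0)
    load = np.full(n_samples, 200.0)
    for name, b in betas.items():
        if name not in meta.columns:
            raise KeyError(f"unknown covariate {name!r}")
        load = load + b * meta[name].to_numpy(dtype=float)
    load = load + gamma @ z
    load = load + rng.normal(0.0, noise_sd, size=n_samples)

    truth = {"beta0": 200.0, "betas": betas, "gamma": gamma, "latent": z}
    return expression, meta, load, truth


def simulate_exon_chromatin(
    n_exons: int,
    mark_effects: Mapping[str, float] | None = None,
    depth_effect: float = 0.01,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-exon depth, five histone-mark signals and mutation counts.

    Counts follow ``depth_effect * depth + sum_m effect_m * signal_m + noise``
    so that depth-driven structure is removed by percentile-bin correction
    and planted mark effects remain recoverable.
    """
    marks = ["H3K36me3", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3"]
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"exon": [f"exon{i:05d}" for i in range(n_exons)]})
    df["depth"] = rng.gamma(shape=2.0, scale=500.0, size=n_exons)
    for m in marks:
        df[m] = rng.normal(1.0, 0.5, size=n_exons)
    effects = dict(mark_effects or {})
    counts = depth_effect * df["depth"].to_numpy()
    for m, e in effects.items():
        if m not in marks:
            raise KeyError(f"unknown histone mark {m!r}")
        counts = counts + e * df[m].to_numpy()
    counts = counts + rng.normal(0.0, noise_sd, size=n_exons)
    df["mutations"] = counts
    return df
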