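"""Read deduplication and two-allele candidate detection.

The first stage of the pipeline: collapse PCR duplicates, assemble per-base
pileups with read-level attributes, and emit candidate variants at positions
covered by exactly two distinct base calls with high coverage (>= 40 reads),
high base quality (Phred >= 30 after per-call filtering) and at least six
reads supporting the non-reference allele.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from rnamut.io_formats import VALID_BASES, GenomicSite

ReadKey = tuple[str, int, str, str, int]  # chrom, start, CIGAR, strand, mate start


@dataclass(frozen=True)
class ReadObservation:
    """One base call of one read at one reference position."""

    chrom: str
    pos: int  # 0-based
    base: str
    base_quality: int
    mapping_quality: int
    read_position: int  # 1-based offset within the read
    strand: str  # '+' or '-'
    read_name: str
    read_key: ReadKey

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES and self.base != "N":
            raise ValueError(f"invalid base {self.base!r}")
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be >= 0")


@dataclass
class PileupSite:
    """Per-position tallies of bases with their read-level attributes."""

    chrom: str
    pos: int
    base_qualities: dict[str, list[int]] = field(default_factory=dict)
    mapping_qualities: dict[str, list[int]] = field(default_factory=dict)
    read_positions: dict[str, list[int]] = field(default_factory=dict)
    strands: dict[str, list[str]] = field(default_factory=dict)

    def add(self, obs: ReadObservation) -> None:
        self.base_qualities.setdefault(obs.base, []).append(obs.base_quality)
        self.mapping_qualities.setdefault(obs.base, []).append(obs.mapping_quality)
        self.read_positions.setdefault(obs.base, []).append(obs.read_position)
        self.strands.setdefault(obs.base, []).append(obs.strand)

    def count(self, base: str) -> int:
        return len(self.base_qualities.get(base, ()))

    @property
    def coverage(self) -> int:
        return sum(len(v) for v in self.base_qualities.values())

    @property
    def bases(self) -> list[str]:
        return sorted(b for b in self.base_qualities if self.count(b) > 0)

    def filtered(self, min_qual: int) -> "PileupSite":
        """Copy of this site keeping only base calls with quality >= min_qual."""
        out = PileupSite(self.chrom, self.pos)
        for base, quals in self.base_qualities.items():
            keep = [i for i, q in enumerate(quals) if q >= min_qual]
            if not keep:
                continue
            out.base_qualities[base] = [quals[i] for i in keep]
            out.mapping_qualities[base] = [self.mapping_qualities[base][i] for i in keep]
            out.read_positions[base] = [self.read_positions[base][i] for i in keep]
            out.strands[base] = [self.strands[base][i] for i in keep]
        return out


@dataclass
class CandidateVariant:
    """A two-allele candidate with attached per-allele attribute vectors."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    coverage: int
    alt_count: int
    alt_base_qualities: list[int]
    ref_base_qualities: list[int]
    alt_mapping_qualities: list[int]
    ref_mapping_qualities: list[int]
    alt_read_positions: list[int]
    ref_read_positions: list[int]
    alt_strands: list[str]
    ref_strands: list[str]
    flags: set[str] = field(default_factory=set)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.coverage

    @property
    def site(self) -> GenomicSite:
        return GenomicSite(self.chrom, self.pos, self.ref)


def dedup_reads(observations: Iterable[ReadObservation]) -> list[ReadObservation]:
    """Collapse PCR duplicates: one read retained per alignment signature.

    Reads sharing a ``read_key`` (chrom, aligned start, CIGAR, strand, mate
    start) are duplicates; the one with the highest mean base quality is
    retained, ties broken by lexicographically smallest read name. The
    retained set is independent of input order.
    """
    by_read: dict[tuple[ReadKey, str], list[ReadObservation]] = defaultdict(list)
    for obs in observations:
        by_read[(obs.read_key, obs.read_name)].append(obs)

    best: dict[ReadKey, tuple[float, str]] = {}
    for (key, name), obs_list in by_read.items():
        mean_q = sum(o.base_quality for o in obs_list) / len(obs_list)
        cur = best.get(key)
        # higher quality wins; on equal quality the smaller name wins
        if cur is None or (-mean_q, name) < (-cur[0], cur[1]):
            best[key] = (mean_q, name)

    kept: list[ReadObservation] = []
    for (key, name), obs_list in sorted(by_read.items()):
        if best[key][1] == name:
            kept.extend(obs_list)
    return kept


def build_pileups(observations: Iterable[ReadObservation]) -> dict[tuple[str, int], PileupSite]:
    """Group deduplicated observations into per-position pileups."""
    pileups: dict[tuple[str, int], PileupSite] = {}
    for obs in observations:
        key = (obs.chrom, obs.pos)
        if key not in pileups:
            pileups[key] = PileupSite(obs.chrom, obs.pos)
        pileups[key].add(obs)
    return pileups


def scan_candidates(
    pileups: Mapping[tuple[str, int], PileupSite],
    ref_getter: Callable[[str, int], str],
    sample: str = "",
    min_cov: int = 40,
    min_qual: int = 30,
    min_alt: int = 6,
) -> list[CandidateVariant]:
    """Emit candidates at positions with exactly two high-quality base calls.

    Base calls below ``min_qual`` are discarded before counting. A candidate
    is emitted iff the remaining calls show exactly two distinct bases, total
    coverage >= ``min_cov`` and the non-reference base is supported by at
    least ``min_alt`` reads. Sites where neither observed base matches the
    reference are emitted flagged ``no_ref_allele`` (the rarer base is
    reported as the alternate) for downstream exclusion.
    """
    candidates: list[CandidateVariant] = []
    for key in sorted(pileups):
        site = pileups[key].filtered(min_qual)
        bases = [b for b in site.bases if b != "N"]
        if len(bases) != 2:
            continue
        if site.count(bases[0]) + site.count(bases[1]) < min_cov:
            continue
        ref = ref_getter(site.chrom, site.pos)
        if ref is None:
            raise ValueError(f"no reference base available at {site.chrom}:{site.pos}")
        flags: set[str] = set()
        if ref in bases:
            ref_base = ref
            alt = bases[0] if bases[1] == ref else bases[1]
        else:
            flags.add("no_ref_allele")
            # neither allele is the reference: report the rarer base as alt
            b0, b1 = sorted(bases, key=lambda b: (site.count(b), b))
            alt, ref_base = b0, b1
        alt_n = site.count(alt)
        other_n = site.count(ref_base)
        if alt_n < min_alt:
            continue
        candidates.append(
            CandidateVariant(
                sample=sample,
                chrom=site.chrom,
                pos=site.pos,
                ref=ref,
                alt=alt,
                coverage=alt_n + other_n,
                alt_count=alt_n,
                alt_base_qualities=list(site.base_qualities[alt]),
                ref_base_qualities=list(site.base_qualities[ref_base]),
                alt_mapping_qualities=list(site.mapping_qualities[alt]),
                ref_mapping_qualities=list(site.mapping_qualities[ref_base]),
                alt_read_positions=list(site.read_positions[alt]),
                ref_read_positions=list(site.read_positions[ref_base]),
                alt_strands=list(site.strands[alt]),
                ref_strands=list(site.strands[ref_base]),
                flags=flags,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Pileup TSV dialect (observation level, 1-based positions on disk)

PILEUP_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "base",
    "base_quality",
    "mapping_quality",
    "read_position",
    "strand",
    "read_name",
    "read_start",
    "cigar",
    "mate_start",
]


def write_pileup_tsv(observations: Mapping[str, Sequence[ReadObservation]], path: str) -> None:
    """Write per-sample read observations in the documented TSV dialect."""
    rows = []
    for sample, obs_list in observations.items():
        for o in obs_list:
            rows.append(
                (
                    sample,
                    o.chrom,
                    o.pos + 1,
                    o.base,
                    o.base_quality,
                    o.mapping_quality,
                    o.read_position,
                    o.strand,
                    o.read_name,
                    o.read_key[1] + 1,
                    o.read_key[2],
                    o.read_key[4] + 1,
                )
            )
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str) -> dict[str, list[ReadObservation]]:
    """Read the observation-level pileup TSV dialect back into memory."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "read_name": str, "cigar": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    out: dict[str, list[ReadObservation]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[row.sample].append(
            ReadObservation(
                chrom=row.chrom,
                pos=int(row.pos) - 1,
                base=row.base,
                base_quality=int(row.base_quality),
                mapping_quality=int(row.mapping_quality),
                read_position=int(row.read_position),
                strand=row.strand,
                read_name=row.read_name,
                read_key=(row.chrom, int(row.read_start) - 1, row.cigar, row.strand, int(row.mate_start) - 1),
            )
        )
    return dict(out)


def observations_from_bam(path: str, chrom: str | None = None) -> list[ReadObservation]:
    """Extract read observations from a coordinate-sorted SAM/BAM file.

    Pileup construction is delegated to pysam; duplicate marking present in
    the file is ignored (use :func:`dedup_reads` afterwards).
    """
    import pysam

    obs: list[ReadObservation] = []
    with pysam.AlignmentFile(path) as af:
        for col in af.pileup(contig=chrom, ignore_overlaps=False, min_base_quality=0):
            for pread in col.pileups:
                if pread.is_del or pread.is_refskip or pread.query_position is None:
                    continue
                aln = pread.alignment
                obs.append(
                    ReadObservation(
                        chrom=col.reference_name,
                        pos=col.reference_pos,
                        base=aln.query_sequence[pread.query_position].upper(),
                        base_quality=aln.query_qualities[pread.query_position],
                        mapping_quality=aln.mapping_quality,
                        read_position=pread.query_position + 1,
                        strand="-" if aln.is_reverse else "+",
                        read_name=aln.query_name,
                        read_key=(
                            aln.reference_name,
                            aln.reference_start,
                            aln.cigarstring or "",
                            "-" if aln.is_reverse else "+",
                            aln.next_reference_start if aln.is_paired else -1,
                        ),
                    )
                )
    return obs
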