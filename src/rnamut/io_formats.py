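"""Readers and writers for the external formats the pipeline touches.

All in-memory coordinates are 0-based half-open; conversions to and from the
native conventions of on-disk formats (VCF and GTF 1-based, BED 0-based
half-open) happen only inside this module, so there is a single place to
audit coordinate arithmetic.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGT")

CATALOG_HEADER = "#rnamut_catalog\tv1"
CATALOG_COLUMNS = [
    "sample",
    "individual",
    "tissue",
    "chrom",
    "pos",
    "ref",
    "alt",
    "coverage",
    "alt_count",
    "vaf",
    "flags",
]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single reference position (0-based) with its reference base."""

    chrom: str
    pos: int
    ref: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if self.ref not in VALID_BASES:
            raise ValueError(f"ref must be one of A,C,G,T, got {self.ref!r}")


class RegionMask:
    """A labelled set of genomic intervals supporting point membership queries.

    Point masks (e.g. RNA-edit site lists) are stored as length-1 intervals so
    that a single mask type serves interval and site exclusion alike.
    Overlapping intervals are merged on construction, making membership
    deterministic and equal to a brute-force per-base scan.
    """

    def __init__(self, label: str, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                for start, end in ivs:
                    self.add(chrom, start, end)
        self._normalize()

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end}) on {chrom}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def _normalize(self) -> None:
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def __contains__(self, site: GenomicSite) -> bool:
        return self.contains(site.chrom, site.pos)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)


@dataclass(frozen=True)
class ExonRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


class ExonSet:
    """Per-gene exons with strand, indexed for boundary-distance queries."""

    def __init__(self, exons: Iterable[ExonRecord] = ()):
        self.exons: list[ExonRecord] = list(exons)
        self._by_chrom: dict[str, list[ExonRecord]] = {}
        for ex in self.exons:
            self._by_chrom.setdefault(ex.chrom, []).append(ex)

    def __len__(self) -> int:
        return len(self.exons)

    @property
    def gene_ids(self) -> set[str]:
        return {ex.gene_id for ex in self.exons}

    def distance_to_nearest_end(self, chrom: str, pos: int) -> int | None:
        """Distance (bp) from ``pos`` to the nearest exon boundary.

        Boundaries are the first and last exonic base of every exon on the
        chromosome. Returns ``None`` when the chromosome has no exons.
        """
        exons = self._by_chrom.get(chrom)
        if not exons:
            return None
        best = None
        for ex in exons:
            d = min(abs(pos - ex.start), abs(pos - (ex.end - 1)))
            if best is None or d < best:
                best = d
        return best

    def genes_overlapping(self, chrom: str, pos: int) -> list[ExonRecord]:
        """All exon records whose interval contains ``pos``."""
        exons = self._by_chrom.get(chrom, [])
        return [ex for ex in exons if ex.start <= pos < ex.end]


class GermlineSet:
    """Per-individual germline variant alleles (het or hom-alt only)."""

    def __init__(self) -> None:
        self._records: dict[str, set[tuple[str, int, str, str]]] = {}

    def add(self, individual: str, chrom: str, pos: int, ref: str, alt: str) -> None:
        self._records.setdefault(individual, set()).add((chrom, pos, ref, alt))

    def has_individual(self, individual: str) -> bool:
        return individual in self._records

    def matches(self, individual: str, chrom: str, pos: int, alt: str) -> bool:
        """True iff this individual carries ``alt`` at (chrom, pos)."""
        recs = self._records.get(individual)
        if not recs:
            return False
        return any(r[0] == chrom and r[1] == pos and r[3] == alt for r in recs)

    def variants(self, individual: str) -> set[tuple[str, int, str, str]]:
        return set(self._records.get(individual, set()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())


class MaskFormatError(ValueError):
    pass


def _parse_bed_line(line: str, path: str, lineno: int) -> tuple[str, int, int]:
    fields = line.split()
    if len(fields) < 3:
        raise MaskFormatError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
    chrom, start_s, end_s = fields[0], fields[1], fields[2]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise MaskFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or end <= start:
        raise MaskFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    return chrom, start, end


def _parse_site_line(line: str, path: str, lineno: int) -> tuple[str, int, int]:
    # Site lists (RADAR/DARNED style) are 1-based single positions.
    fields = line.split()
    if len(fields) < 2:
        raise MaskFormatError(f"{path}:{lineno}: expected >= 2 site-list columns")
    chrom, pos_s = fields[0], fields[1]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise MaskFormatError(f"{path}:{lineno}: non-integer position") from exc
    if pos < 1:
        raise MaskFormatError(f"{path}:{lineno}: site positions are 1-based, got {pos}")
    return chrom, pos - 1, pos


def read_region_masks(
    paths: Sequence[str],
    labels: Sequence[str],
    dialects: Sequence[str] | None = None,
) -> dict[str, RegionMask]:
    """Read BED-like interval files or 1-based site lists into region masks.

    Parameters
    ----------
    paths, labels
        One label per file; several files may share a label, in which case
        their intervals are pooled into one mask.
    dialects
        Per-file dialect, ``"bed"`` (0-based half-open intervals, default) or
        ``"sites"`` (1-based single positions, stored as length-1 intervals).

    Chromosomes absent from the data are retained: masks may cover contigs
    the pileups never mention.
    """
    if len(paths) != len(labels):
        raise ValueError("paths and labels must have equal length")
    if dialects is None:
        dialects = ["bed"] * len(paths)
    if len(dialects) != len(paths):
        raise ValueError("dialects must match paths in length")
    masks: dict[str, RegionMask] = {}
    for path, label, dialect in zip(paths, labels, dialects):
        if dialect not in ("bed", "sites"):
            raise ValueError(f"unknown dialect {dialect!r} for {path}")
        mask = masks.setdefault(label, RegionMask(label))
        parse = _parse_bed_line if dialect == "bed" else _parse_site_line
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = parse(line, path, lineno)
                mask.add(chrom, start, end)
    for mask in masks.values():
        mask._normalize()
    return masks


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_exons(gtf_path: str) -> ExonSet:
    """Read exon features from a GENCODE-dialect GTF (1-based inclusive).

    Coordinates are converted to 0-based half-open. Exon records without a
    ``gene_id`` attribute are rejected and counted in ``ExonSet.n_rejected``.
    """
    exons: list[ExonRecord] = []
    n_rejected = 0
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                n_rejected += 1
                continue
            start = int(fields[3]) - 1  # GTF 1-based inclusive -> 0-based half-open
            end = int(fields[4])
            exons.append(ExonRecord(fields[0], start, end, m.group(1), fields[6]))
    es = ExonSet(exons)
    es.n_rejected = n_rejected
    return es


def read_germline(vcf_path: str, individual_id: str) -> GermlineSet:
    """Load one individual's germline alt alleles from a VCF.

    Only genotypes carrying at least one alternate allele (0/1, 1/1, 1/2, ...)
    are stored; 0/0 and missing genotypes are skipped. Positions are converted
    from the VCF's 1-based convention to the internal 0-based one.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    if individual_id not in vcf.samples:
        raise KeyError(
            f"individual {individual_id!r} not found in {vcf_path}; "
            f"samples present: {vcf.samples}"
        )
    sample_idx = vcf.samples.index(individual_id)
    gs = GermlineSet()
    for variant in vcf:
        genotype = variant.genotypes[sample_idx]
        allele_idx = {a for a in genotype[:-1] if isinstance(a, int) and a > 0}
        for ai in allele_idx:
            alt = variant.ALT[ai - 1]
            if len(variant.REF) == 1 and len(alt) == 1:
                gs.add(individual_id, variant.CHROM, variant.POS - 1, variant.REF, alt)
    return gs


class MutationCatalog:
    """All mutation calls across samples, keyed by sample/individual/tissue.

    Thin wrapper around a :class:`pandas.DataFrame` with a fixed column set;
    ``pos`` is 0-based internally and written 1-based on disk.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=CATALOG_COLUMNS)
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        self.df = df[CATALOG_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationCatalog):
            return NotImplemented
        a = self.df.sort_values(CATALOG_COLUMNS[:7]).reset_index(drop=True)
        b = other.df.sort_values(CATALOG_COLUMNS[:7]).reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MutationCatalog":
        df = pd.DataFrame(list(records))
        if df.empty:
            return cls()
        if "flags" not in df.columns:
            df["flags"] = ""
        df["flags"] = df["flags"].fillna("")
        return cls(df)


def write_catalog(catalog: MutationCatalog, path: str) -> None:
    """Write a catalog as versioned-header TSV, 1-based positions on disk."""
    out = catalog.df.copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write(CATALOG_HEADER + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_catalog(path: str) -> MutationCatalog:
    """Read a catalog TSV written by :func:`write_catalog`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != CATALOG_HEADER:
            raise ValueError(
                f"{path}: expected catalog header {CATALOG_HEADER!r}, got {header!r}"
            )
        body = fh.read()
    df = pd.read_csv(
        io.StringIO(body),
        sep="\t",
        dtype={"chrom": str, "sample": str, "individual": str, "tissue": str},
        keep_default_na=False,
        float_precision="round_trip",  # vaf must survive write/read unchanged
    )
    unknown = [c for c in df.columns if c not in CATALOG_COLUMNS]
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise ValueError(
            f"{path}: unexpected catalog columns; expected {CATALOG_COLUMNS}, "
            f"unknown={unknown}, missing={missing}"
        )
    df["pos"] = df["pos"].astype(int) - 1
    df["coverage"] = df["coverage"].astype(int)
    df["alt_count"] = df["alt_count"].astype(int)
    df["vaf"] = df["vaf"].astype(float)
    df["flags"] = df["flags"].astype(str)
    return MutationCatalog(df)
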