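"""Cancer-mutation enrichment, driver-gene tests and VAF selection analysis.

Overlap between a sample's somatic calls and a catalogue of cancer point
mutations is scored by an upper-tail hypergeometric test whose population
is every possible substitution at covered positions (N covered bases times
the three possible alternate alleles). A position-permuted control that
preserves each call's reference and alternate base validates the null.
Driver-gene burdens are compared to the panel-wide rate by binomial tails,
low-diversity mutation identities are removed by the t-metric, and
selection is read from VAF contrasts across consequence classes and cancer
status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Snv = tuple[str, int, str, str]  # chrom, pos (0-based), ref, alt

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CancerMutationSet:
    """A catalogue of cancer SNVs with allele- and position-level indexes."""

    def __init__(self, snvs: Iterable[Snv]):
        self.snvs: set[Snv] = set()
        for chrom, pos, ref, alt in snvs:
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise ValueError(f"not a SNV: {chrom}:{pos} {ref}>{alt}")
            self.snvs.add((chrom, pos, ref, alt))
        self.positions: set[tuple[str, int]] = {(c, p) for c, p, _, _ in self.snvs}

    def __len__(self) -> int:
        return len(self.snvs)

    def __contains__(self, snv: Snv) -> bool:
        return snv in self.snvs

    def position_match(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.positions

    @classmethod
    def from_tsv(cls, path: str) -> "CancerMutationSet":
        """Read a chrom/pos/ref/alt TSV (1-based positions on disk)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = ["chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(
            (r.chrom, int(r.pos) - 1, r.ref, r.alt) for r in df.itertuples(index=False)
        )


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap of one sample's calls with cancer mutations."""

    sample: str
    K: int  # sample mutations
    n: int  # cancer mutations at covered positions
    N: int  # covered base pairs
    k: int  # allele-level overlap
    p: float
    adjusted_p: float | None = None

    @property
    def overlap_fraction(self) -> float:
        return self.k / self.K if self.K else 0.0


def cosmic_enrichment(
    sample: str,
    calls: Iterable[Snv],
    cancer: CancerMutationSet,
    covered_positions: Iterable[tuple[str, int]],
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of cancer mutations in one sample.

    Population = N x 3 possible substitutions at covered (>= 40 reads)
    bases, successes = cancer mutations at covered positions, draws = the
    sample's K mutations, observed = the allele-level overlap k;
    p = P(X > k).
    """
    calls = set(calls)
    covered = set(covered_positions)
    K = len(calls)
    N = len(covered)
    if K > 3 * N:
        raise ValueError(f"K={K} draws exceed the population 3N={3 * N}")
    n = sum(1 for snv in cancer.snvs if (snv[0], snv[1]) in covered)
    k = sum(1 for snv in calls if snv in cancer)
    if n == 0:
        return EnrichmentResult(sample, K, 0, N, k, 1.0)
    p = float(stats.hypergeom.sf(k, 3 * N, n, K))  # strictly greater than k
    return EnrichmentResult(sample, K, n, N, k, min(1.0, p))


def adjust_enrichment(
    results: Sequence[EnrichmentResult], method: str = "bonferroni"
) -> list[EnrichmentResult]:
    """Multiple-testing adjustment across samples (Bonferroni or BH)."""
    ps = [r.p for r in results]
    adj = multipletests(ps, method=method)[1] if results else []
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return list(results)


def permuted_mutation_control(
    calls: Sequence[Snv],
    covered_positions: Mapping[tuple[str, int], str],
    seed: int = 0,
) -> list[Snv]:
    """Permuted call set preserving the exact multiset of (ref, alt) pairs.

    Each call is re-planted at a random covered position whose reference
    base equals the call's reference, keeping the same ref-to-alt change.
    """
    rng = np.random.default_rng(seed)
    by_ref: dict[str, list[tuple[str, int]]] = {}
    for (chrom, pos), ref in covered_positions.items():
        by_ref.setdefault(ref, []).append((chrom, pos))
    for v in by_ref.values():
        v.sort()
    permuted: list[Snv] = []
    for chrom, pos, ref, alt in calls:
        pool = by_ref.get(ref)
        if not pool:
            raise ValueError(f"no covered positions with reference base {ref!r}")
        nchrom, npos = pool[rng.integers(len(pool))]
        permuted.append((nchrom, npos, ref, alt))
    return permuted


@dataclass
class DriverBurdenResult:
    tissue: str
    observed: int
    opportunity: int
    expected_rate: float
    direction: str  # 'enriched' or 'depleted'
    p: float
    bh_fdr: float | None = None


def driver_binomial_test(
    per_tissue: Mapping[str, tuple[int, int]],
) -> list[DriverBurdenResult]:
    """Tissue driver-gene burden vs the panel-wide average rate.

    ``per_tissue`` maps tissue -> (observed driver mutations, opportunity).
    The expected rate k is the pooled mutations-per-opportunity across all
    tissues; tissues above expectation get the upper binomial tail, below
    the lower tail; BH correction across tissues. Zero-opportunity tissues
    are skipped.
    """
    usable = {t: (n, o) for t, (n, o) in per_tissue.items() if o > 0}
    total_n = sum(n for n, _ in usable.values())
    total_o = sum(o for _, o in usable.values())
    if total_o == 0:
        return []
    k = total_n / total_o
    results = []
    for tissue in sorted(usable):
        n, o = usable[tissue]
        if n / o >= k:
            p = float(stats.binom.sf(n - 1, o, k))  # P(X >= n)
            direction = "enriched"
        else:
            p = float(stats.binom.cdf(n, o, k))  # P(X <= n)
            direction = "depleted"
        results.append(DriverBurdenResult(tissue, n, o, k, direction, min(1.0, p)))
    fdr = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, fdr):
        r.bh_fdr = float(q)
    return results


def diversity_filter(calls: pd.DataFrame, t_max: float = 3.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-diversity mutation identities by the t-metric.

    For each mutation identity (chrom, pos, ref, alt) within a gene,
    t = occurrences of that identity / number of unique identities in the
    gene. Identities with t strictly greater than ``t_max`` are removed.
    ``calls`` needs columns gene, chrom, pos, ref, alt (one row per
    observation). Returns (filtered calls, per-identity t table). The
    operation is idempotent and order-invariant.
    """
    if calls.empty:
        return calls.copy(), pd.DataFrame(columns=["gene", "chrom", "pos", "ref", "alt", "t"])
    key_cols = ["gene", "chrom", "pos", "ref", "alt"]
    counts = calls.groupby(key_cols, sort=True).size().rename("occurrences").reset_index()
    uniq = counts.groupby("gene").size().rename("unique_mutations")
    counts = counts.join(uniq, on="gene")
    counts["t"] = counts["occurrences"] / counts["unique_mutations"]
    bad = counts.loc[counts["t"] > t_max, key_cols]
    bad_keys = set(map(tuple, bad.to_numpy()))
    keep = ~calls[key_cols].apply(tuple, axis=1).isin(bad_keys)
    return calls[keep].reset_index(drop=True), counts[key_cols + ["t"]]


# ---------------------------------------------------------------------------
# Consequence annotation from a supplied transcript model


@dataclass
class Transcript:
    """One canonical coding transcript: ordered exons of an all-coding CDS."""

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order

    def cds_offset(self, pos: int) -> int | None:
        """Offset of a genomic position within the spliced CDS, or None."""
        blocks = self.exons if self.strand == "+" else list(reversed(self.exons))
        offset = 0
        for start, end in blocks:
            if start <= pos < end:
                within = pos - start if self.strand == "+" else end - 1 - pos
                return offset + within
            offset += end - start
        return None

    def is_last_exon(self, pos: int) -> bool:
        last = self.exons[-1] if self.strand == "+" else self.exons[0]
        return last[0] <= pos < last[1]


def annotate_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcripts: Sequence[Transcript],
    ref_getter,
) -> tuple[str | None, bool]:
    """(consequence, last-exon flag) of a coding SNV under a transcript model.

    Consequence is 'synonymous', 'missense' or 'nonsense' (premature stop
    gained); None when no supplied transcript covers the position. The
    reference codon is read from the genome via ``ref_getter(chrom, pos)``.
    """
    for tx in transcripts:
        if tx.chrom != chrom:
            continue
        offset = tx.cds_offset(pos)
        if offset is None:
            continue
        codon_start = offset - offset % 3
        codon = []
        positions = []
        for tx_off in range(codon_start, codon_start + 3):
            g = _genomic_position(tx, tx_off)
            if g is None:
                return None, tx.is_last_exon(pos)
            base = ref_getter(chrom, g)
            if tx.strand == "-":
                base = base.translate(_COMPLEMENT)
            codon.append(base)
            positions.append(g)
        codon_ref = "".join(codon)
        within = offset % 3
        alt_base = alt if tx.strand == "+" else alt.translate(_COMPLEMENT)
        codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1:]
        aa_ref = CODON_TABLE.get(codon_ref)
        aa_alt = CODON_TABLE.get(codon_alt)
        if aa_ref is None or aa_alt is None:
            return None, tx.is_last_exon(pos)
        if aa_alt == aa_ref:
            consequence = "synonymous"
        elif aa_alt == "*" and aa_ref != "*":
            consequence = "nonsense"
        else:
            consequence = "missense"
        return consequence, tx.is_last_exon(pos)
    return None, False


def _genomic_position(tx: Transcript, cds_offset: int) -> int | None:
    blocks = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    remaining = cds_offset
    for start, end in blocks:
        length = end - start
        if remaining < length:
            return start + remaining if tx.strand == "+" else end - 1 - remaining
        remaining -= length
    return None


def cancer_status(snv: Snv, cancer: CancerMutationSet) -> str:
    """'in_cancer' (position + allele), 'not_in_cancer' (position only), or 'unmatched'."""
    if snv in cancer:
        return "in_cancer"
    if cancer.position_match(snv[0], snv[1]):
        return "not_in_cancer"
    return "unmatched"


@dataclass
class VafSelectionReport:
    medians: pd.DataFrame  # per class (and class x cancer status)
    contrasts: pd.DataFrame  # pairwise Mann-Whitney p values
    fold_ratios: pd.DataFrame  # cancer/non-cancer median ratio per class
    last_exon_nonsense: pd.DataFrame


def _boot_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    meds = np.empty(n_boot)
    for b in range(n_boot):
        meds[b] = np.median(values[rng.integers(0, len(values), size=len(values))])
    lo, hi = np.quantile(meds, [0.025, 0.975])
    return float(lo), float(hi)


def vaf_selection_analysis(
    calls: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    min_class_size: int = 5,
) -> VafSelectionReport:
    """Median VAF by consequence class and cancer status, with contrasts.

    Lower VAF indicates smaller clonal expansions, the footprint of negative
    selection; cancer-status stratification separates mutations previously
    seen in cancer (position + allele match) from position-only matched
    controls. ``calls`` needs columns vaf, consequence and optionally
    cancer_status and last_exon. Bootstrap CIs use ``n_boot`` replicates;
    classes below ``min_class_size`` are flagged unstable.
    """
    rng = np.random.default_rng(seed)
    classes = ["synonymous", "missense", "nonsense"]
    df = calls[calls["consequence"].isin(classes)].copy()
    has_status = "cancer_status" in df.columns

    rows = []
    group_cols = ["consequence"] + (["cancer_status"] if has_status else [])
    for key, grp in df.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        v = grp["vaf"].to_numpy(dtype=float)
        lo, hi = _boot_ci(v, rng, n_boot) if len(v) else (np.nan, np.nan)
        rows.append(
            dict(
                zip(group_cols, key),
                n=len(v),
                median_vaf=float(np.median(v)) if len(v) else np.nan,
                ci_low=lo,
                ci_high=hi,
                unstable=len(v) < min_class_size,
            )
        )
    medians = pd.DataFrame(rows)

    contrast_rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            va = df.loc[df["consequence"] == a, "vaf"].to_numpy()
            vb = df.loc[df["consequence"] == b, "vaf"].to_numpy()
            if len(va) and len(vb):
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            else:
                p = np.nan
            contrast_rows.append({"class_a": a, "class_b": b, "p": p})
    contrasts = pd.DataFrame(contrast_rows)

    fold_rows = []
    if has_status:
        for cls in classes:
            inc = df.loc[
                (df["consequence"] == cls) & (df["cancer_status"] == "in_cancer"), "vaf"
            ]
            out = df.loc[
                (df["consequence"] == cls) & (df["cancer_status"] == "not_in_cancer"),
                "vaf",
            ]
            if len(inc) and len(out) and np.median(out) > 0:
                ratio = float(np.median(inc) / np.median(out))
                p = float(
                    stats.mannwhitneyu(inc, out, alternative="two-sided").pvalue
                )
            else:
                ratio, p = np.nan, np.nan
            fold_rows.append(
                {"consequence": cls, "fold_ratio": ratio, "p": p, "n_in": len(inc), "n_out": len(out)}
            )
    fold_ratios = pd.DataFrame(fold_rows)

    if "last_exon" in df.columns:
        le = df[(df["consequence"] == "nonsense") & df["last_exon"].astype(bool)]
        le_rows = []
        for other in ("synonymous", "missense"):
            vo = df.loc[df["consequence"] == other, "vaf"].to_numpy()
            if len(le) and len(vo):
                p = float(
                    stats.mannwhitneyu(le["vaf"].to_numpy(), vo, alternative="two-sided").pvalue
                )
            else:
                p = np.nan
            le_rows.append(
                {
                    "contrast": f"last_exon_nonsense_vs_{other}",
                    "n_nonsense": len(le),
                    "median_vaf_nonsense": float(np.median(le["vaf"])) if len(le) else np.nan,
                    "p": p,
                }
            )
        last_exon = pd.DataFrame(le_rows)
    else:
        last_exon = pd.DataFrame(columns=["contrast", "n_nonsense", "median_vaf_nonsense", "p"])
    return VafSelectionReport(medians, contrasts, fold_ratios, last_exon)
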