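"""Matched-DNA validation of RNA-derived mutation calls.

RNA-seq coverage in highly expressed genes can exceed 1000x, so calls with
very low VAF are detectable in RNA but not in typical ~80x exome DNA. The
framework therefore gates comparisons on the expected DNA-side support

    r_i = C_DNA * (A_RNA / C_RNA)

and evaluates the false-discovery rate only where r_i >= 8. Because that
gate shifts the evaluable set toward high VAFs, a VAF-binned FDR weighted by
the VAF composition of *all* calls corrects the raw estimate. A
position-permuted random-allele control (expected to be almost entirely
unsupported in DNA) validates the FDR construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MatchedPair:
    """One RNA call with DNA coverage and allele support at the same site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rna_coverage: int
    rna_alt_count: int
    dna_coverage: int
    dna_alt_count: int

    def __post_init__(self) -> None:
        for c, a, label in (
            (self.rna_coverage, self.rna_alt_count, "RNA"),
            (self.dna_coverage, self.dna_alt_count, "DNA"),
        ):
            if a < 0 or c < 0 or a > c:
                raise ValueError(f"invalid {label} counts: alt={a}, coverage={c}")

    @property
    def rna_vaf(self) -> float:
        return self.rna_alt_count / self.rna_coverage


@dataclass
class FdrReport:
    """Raw and VAF-weighted FDR estimates from matched DNA."""

    n_pairs: int
    n_evaluable: int
    n_unsupported: int
    raw_fdr: float | None
    bins: pd.DataFrame  # bin edges, per-bin FDR, fraction of ALL calls per bin
    weighted_fdr: float | None
    flags: set[str] = field(default_factory=set)


def expected_alt_reads(
    dna_coverage: int, rna_alt_count: int, rna_coverage: int
) -> float:
    """Expected DNA reads supporting the alternate allele, r_i.

    ``r_i = C_DNA * (A_RNA / C_RNA)``: the DNA-side support implied by the
    RNA VAF. With 80x DNA coverage and an RNA VAF of 0.006 only 0.48 reads
    are expected, so such sites carry no validation power.
    """
    if rna_coverage <= 0:
        raise ValueError(f"RNA coverage must be > 0, got {rna_coverage}")
    return dna_coverage * (rna_alt_count / rna_coverage)


def _vaf_bin_edges(vafs: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Decile edges of the observed VAF distribution, deduplicated."""
    qs = np.quantile(vafs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0] + 1e-9])
    edges[0], edges[-1] = 0.0, 1.0
    return edges


def matched_fdr(
    pairs: Sequence[MatchedPair],
    r_min: float = 8.0,
    vaf_bin_edges: Sequence[float] | None = None,
) -> FdrReport:
    """Empirical FDR of RNA calls against matched DNA.

    A call validates when at least one DNA read supports the same alternate
    allele; the raw FDR is the unsupported fraction of the evaluable set
    (r_i >= ``r_min``). The weighted FDR re-weights per-VAF-bin FDRs by the
    fraction of *all* calls in each bin, correcting the selection of
    high-VAF calls induced by the power gate.
    """
    n_pairs = len(pairs)
    if n_pairs == 0:
        return FdrReport(0, 0, 0, None, pd.DataFrame(), None, flags={"empty"})
    all_vafs = np.array([p.rna_vaf for p in pairs])
    evaluable = [
        p
        for p in pairs
        if expected_alt_reads(p.dna_coverage, p.rna_alt_count, p.rna_coverage) >= r_min
    ]
    if not evaluable:
        return FdrReport(
            n_pairs, 0, 0, None, pd.DataFrame(), None, flags={"no_evaluable_calls"}
        )
    unsupported = [p for p in evaluable if p.dna_alt_count == 0]
    raw_fdr = len(unsupported) / len(evaluable)

    if vaf_bin_edges is None:
        edges = _vaf_bin_edges(all_vafs)
    else:
        edges = np.asarray(vaf_bin_edges, dtype=float)
    ev_vafs = np.array([p.rna_vaf for p in evaluable])
    ev_unsup = np.array([p.dna_alt_count == 0 for p in evaluable])
    # right-closed bins over (0, 1]; lowest edge inclusive
    all_idx = np.clip(np.searchsorted(edges, all_vafs, side="left") - 1, 0, len(edges) - 2)
    ev_idx = np.clip(np.searchsorted(edges, ev_vafs, side="left") - 1, 0, len(edges) - 2)

    rows = []
    flags: set[str] = set()
    for b in range(len(edges) - 1):
        frac_all = float(np.mean(all_idx == b))
        in_bin = ev_idx == b
        n_ev = int(in_bin.sum())
        fdr_b = float(ev_unsup[in_bin].mean()) if n_ev else np.nan
        rows.append(
            {
                "vaf_low": edges[b],
                "vaf_high": edges[b + 1],
                "n_evaluable": n_ev,
                "fdr": fdr_b,
                "fraction_of_all_calls": frac_all,
            }
        )
    bins = pd.DataFrame(rows)

    weights = bins["fraction_of_all_calls"].to_numpy()
    fdrs = bins["fdr"].to_numpy()
    defined = ~np.isnan(fdrs)
    if defined.all():
        weighted = float(np.sum(weights * fdrs))
    elif defined.any():
        # renormalize over bins where an FDR could be estimated
        w = weights[defined]
        weighted = float(np.sum(w * fdrs[defined]) / w.sum())
        flags.add("bins_without_evaluable_calls")
    else:
        weighted = None
        flags.add("no_bin_fdr_defined")

    return FdrReport(
        n_pairs=n_pairs,
        n_evaluable=len(evaluable),
        n_unsupported=len(unsupported),
        raw_fdr=raw_fdr,
        bins=bins,
        weighted_fdr=weighted,
        flags=flags,
    )


def weighted_fdr_from_bins(
    bin_fractions: Sequence[float], bin_fdrs: Sequence[float]
) -> float:
    """Convex combination of per-bin FDRs weighted by call fractions.

    E.g. 20 % of calls at 25 % FDR and 80 % at 30 % FDR gives 29 %.
    """
    fr = np.asarray(bin_fractions, dtype=float)
    fd = np.asarray(bin_fdrs, dtype=float)
    if fr.shape != fd.shape:
        raise ValueError("bin fractions and FDRs must align")
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError(f"bin fractions must sum to 1, got {fr.sum()}")
    return float(np.sum(fr * fd))


def permuted_allele_control(
    calls: Sequence[tuple[str, int, str, str]],
    covered_positions: Mapping[tuple[str, int], str],
    dna_support: Mapping[tuple[str, int, str], int],
    seed: int = 0,
) -> tuple[list[tuple[str, int, str, str]], float]:
    """Position-permuted random-allele negative control.

    Each call (chrom, pos, ref, alt) is re-planted at a random RNA-covered
    position, keeping the multiset of reference bases: the new position's
    reference equals the original call's reference, and the alternate is
    drawn at random from the three non-reference bases. Returns the permuted
    call set and the fraction with zero DNA support — expected near 1 when
    DNA carries only true variants.
    """
    if len(covered_positions) < len(calls):
        raise ValueError(
            f"only {len(covered_positions)} covered positions for {len(calls)} calls"
        )
    rng = np.random.default_rng(seed)
    by_ref: dict[str, list[tuple[str, int]]] = {}
    for (chrom, pos), ref in covered_positions.items():
        by_ref.setdefault(ref, []).append((chrom, pos))
    for v in by_ref.values():
        v.sort()

    permuted: list[tuple[str, int, str, str]] = []
    for chrom, pos, ref, alt in calls:
        pool = by_ref.get(ref)
        if not pool:
            raise ValueError(f"no covered positions with reference base {ref!r}")
        nchrom, npos = pool[rng.integers(len(pool))]
        choices = [b for b in "ACGT" if b != ref]
        nalt = choices[rng.integers(3)]
        permuted.append((nchrom, npos, ref, nalt))

    unsupported = sum(
        1 for (c, p, r, a) in permuted if dna_support.get((c, p, a), 0) == 0
    )
    frac_unsupported = unsupported / len(permuted) if permuted else float("nan")
    return permuted, frac_unsupported
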