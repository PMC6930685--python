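"""Mutation spectra, profile clustering, strand asymmetry and signatures.

Substitutions are represented pyrimidine-centric: complementary changes
(C>T and G>A, say) are one event seen from the two DNA strands and are
collapsed into the six classes C>A, C>G, C>T, T>A, T>C, T>G. With k
flanking bases on each side this yields 6 * 4^(2k) context classes — 96 for
trinucleotides, 1536 for pentanucleotides.

Raw context counts are confounded by what is expressed: a sample expressing
GC-rich genes offers more C-centred contexts to mutate. Profiles are
therefore normalized by the expression-weighted context content of the
transcribed genome,

    mut_i = c_i / sum_g s_{g,i} e_g

summing over genes with TPM >= 1 in the sample, where s_{g,i} counts
occurrences of context i in gene g and e_g is the gene's TPM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGT", "TGCA")
PYRIMIDINES = frozenset("CT")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def collapse_substitution(ref: str, alt: str, context: str) -> tuple[str, str, str, bool]:
    """Collapse a substitution to its pyrimidine-centric representation.

    ``context`` is centred on ``ref`` (odd length). Purine references are
    reverse-complemented together with their context. Returns
    (class like "C>T", collapsed context, collapsed alt, flipped flag).
    Ambiguous context bases survive collapsing but mark the context unusable
    for profile counting.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid substitution {ref}>{alt}")
    context = context.upper()
    if len(context) % 2 != 1 or context[len(context) // 2] != ref:
        raise ValueError(f"context {context!r} not centred on ref {ref!r}")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", context, alt, False
    flipped_ref = ref.translate(COMPLEMENT)
    flipped_alt = alt.translate(COMPLEMENT)
    return f"{flipped_ref}>{flipped_alt}", _revcomp(context), flipped_alt, True


def class_label(context: str, alt: str) -> str:
    """Label like ``AC[C>T]TG`` for a collapsed context and alternate base."""
    mid = len(context) // 2
    return f"{context[:mid]}[{context[mid]}>{alt}]{context[mid + 1:]}"


def all_class_labels(flank: int) -> list[str]:
    """All 6 * 4^(2k) pyrimidine-centric class labels for flank width k."""
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        ref, alt = sub[0], sub[2]
        for left in itertools.product("ACGT", repeat=flank):
            for right in itertools.product("ACGT", repeat=flank):
                ctx = "".join(left) + ref + "".join(right)
                labels.append(class_label(ctx, alt))
    return labels


@dataclass
class SpectrumProfile:
    """Per-sample mutation spectrum: raw counts and normalized rates."""

    sample: str
    flank: int
    counts: pd.Series
    normalized: pd.Series  # mut_i; NaN where the context denominator is zero
    n_unusable: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.counts)


def count_contexts(sequence: str, flank: int) -> dict[str, int]:
    """Pyrimidine-centric context occurrences in one sequence.

    Each position contributes its (2*flank+1)-mer, reverse-complemented when
    the centre base is a purine. Windows containing non-ACGT bases are
    skipped.
    """
    k = 2 * flank + 1
    counts: dict[str, int] = {}
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            continue
        centre = window[flank]
        if centre not in PYRIMIDINES:
            window = _revcomp(window)
        counts[window] = counts.get(window, 0) + 1
    return counts


def context_profile(
    sample: str,
    mutations: Iterable[tuple[str, str, str]],
    gene_sequences: Mapping[str, str],
    expression: Mapping[str, float],
    flank: int = 2,
    tpm_min: float = 1.0,
) -> SpectrumProfile:
    """Expression-normalized context mutation profile for one sample.

    ``mutations`` yields (ref, alt, context) with context centred on ref and
    width 2*flank+1. The denominator of class i sums s_{g,i} * e_g over
    genes with TPM >= ``tpm_min``. Classes whose context never occurs in the
    expressed genes have undefined (NaN) normalized values.
    """
    expressed = {g: e for g, e in expression.items() if e >= tpm_min}
    if not expressed:
        raise ValueError("no genes expressed at or above tpm_min")
    labels = all_class_labels(flank)
    counts = pd.Series(0, index=labels, dtype=int)
    n_unusable = 0
    for ref, alt, context in mutations:
        cls, ctx, c_alt, _ = collapse_substitution(ref, alt, context)
        if any(b not in "ACGT" for b in ctx):
            n_unusable += 1
            continue
        counts[class_label(ctx, c_alt)] += 1

    denom_by_context: dict[str, float] = {}
    for gene, tpm in expressed.items():
        seq = gene_sequences.get(gene)
        if seq is None:
            raise KeyError(f"no sequence for expressed gene {gene!r}")
        for ctx, n in count_contexts(seq, flank).items():
            denom_by_context[ctx] = denom_by_context.get(ctx, 0.0) + n * tpm

    denom = pd.Series(
        [denom_by_context.get(lbl.split("[")[0] + lbl[lbl.index("[") + 1] + lbl.split("]")[1], 0.0) for lbl in labels],
        index=labels,
        dtype=float,
    )
    normalized = counts / denom.replace(0.0, np.nan)
    return SpectrumProfile(sample, flank, counts, normalized, n_unusable)


def penta_profile(
    sample: str,
    mutations: Iterable[tuple[str, str, str]],
    gene_sequences: Mapping[str, str],
    expression: Mapping[str, float],
    tpm_min: float = 1.0,
) -> SpectrumProfile:
    """1536-class pentanucleotide profile (two flanking bases each side)."""
    return context_profile(sample, mutations, gene_sequences, expression, 2, tpm_min)


# ---------------------------------------------------------------------------
# Embedding + silhouette clustering


def silhouette_scores(coords: np.ndarray, labels: Sequence, group) -> np.ndarray:
    """Per-sample silhouette s_i = (b_i - a_i) / max(a_i, b_i) for one group.

    a_i is the mean distance of sample i to the other members of its group;
    b_i is its mean distance to all samples outside the group (not the
    nearest other cluster).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    inside = np.flatnonzero(labels == group)
    outside = np.flatnonzero(labels != group)
    if len(inside) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    if len(outside) < 1:
        raise ValueError("no samples outside the group")
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    s = np.empty(len(inside))
    for j, i in enumerate(inside):
        a = dist[i, inside].sum() / (len(inside) - 1)
        b = dist[i, outside].mean()
        s[j] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


def default_embedding(
    dims: int = 2,
    max_iter: int = 500,
    perplexity: float = 30.0,
    pca: bool = True,
    theta: float = 0.5,
    seed: int = 0,
) -> Callable[[np.ndarray], np.ndarray]:
    """t-SNE embedding honouring the stated parameters (Barnes-Hut)."""

    def embed(X: np.ndarray) -> np.ndarray:
        from sklearn.manifold import TSNE

        perp = min(perplexity, (len(X) - 1) / 3)
        tsne = TSNE(
            n_components=dims,
            max_iter=max_iter,
            perplexity=perp,
            angle=theta,
            init="pca" if pca else "random",
            method="barnes_hut" if dims <= 3 else "exact",
            random_state=seed,
        )
        return tsne.fit_transform(np.asarray(X, dtype=float))

    return embed


@dataclass
class SilhouetteReport:
    """Per-group clustering coherence in the embedded space."""

    coords: np.ndarray
    groups: pd.DataFrame  # group, n, ss, ci_low, ci_high
    random_expectation: float
    random_sd: float
    flags: set[str] = field(default_factory=set)


def embed_and_score(
    profiles: pd.DataFrame,
    groupings: Mapping[str, str] | pd.Series,
    embedding: Callable[[np.ndarray], np.ndarray] | None = None,
    n_perm: int = 10,
    n_boot: int = 10000,
    seed: int = 0,
) -> SilhouetteReport:
    """Embed profiles in 2-D and score group coherence by silhouette.

    ``profiles`` is samples x classes (rows indexed by sample id); columns
    with all-NaN normalized values are dropped, remaining NaNs treated as 0.
    Group silhouette = mean s_i with a bootstrap 95 % CI; the random
    expectation averages the mean group score over ``n_perm`` label
    permutations. Singleton groups are flagged and skipped.
    """
    groupings = pd.Series(dict(groupings))
    samples = [s for s in profiles.index if s in groupings.index]
    if len(samples) < 4:
        raise ValueError("need at least 4 samples with group labels")
    X = profiles.loc[samples].dropna(axis=1, how="all").fillna(0.0).to_numpy(dtype=float)
    labels = groupings.loc[samples].to_numpy()
    if embedding is None:
        embedding = default_embedding(seed=seed)
    coords = np.asarray(embedding(X), dtype=float)
    if coords.shape != (len(samples), 2):
        raise ValueError(f"embedding must return (n, 2) coordinates, got {coords.shape}")

    rng = np.random.default_rng(seed)
    flags: set[str] = set()
    rows = []
    unique_groups = pd.unique(labels)
    for group in unique_groups:
        n_in = int((labels == group).sum())
        if n_in < 2 or n_in == len(samples):
            flags.add(f"singleton_or_total_group:{group}")
            rows.append({"group": group, "n": n_in, "ss": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            continue
        s = silhouette_scores(coords, labels, group)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = s[rng.integers(0, len(s), size=len(s))].mean()
        lo, hi = np.quantile(boots, [0.025, 0.975])
        rows.append(
            {"group": group, "n": n_in, "ss": float(s.mean()), "ci_low": float(lo), "ci_high": float(hi)}
        )
    groups_df = pd.DataFrame(rows)

    perm_means = []
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        vals = []
        for group in unique_groups:
            if 2 <= (perm == group).sum() < len(samples):
                vals.append(silhouette_scores(coords, perm, group).mean())
        if vals:
            perm_means.append(float(np.mean(vals)))
    rand_mean = float(np.mean(perm_means)) if perm_means else np.nan
    rand_sd = float(np.std(perm_means)) if perm_means else np.nan
    return SilhouetteReport(coords, groups_df, rand_mean, rand_sd, flags)


def person_grouping_score(
    coords: np.ndarray,
    individuals: Sequence,
    n_individuals: int = 20,
    seed: int = 0,
) -> float:
    """Mean silhouette over a random subset of individual-of-origin groups."""
    individuals = np.asarray(individuals)
    rng = np.random.default_rng(seed)
    eligible = [
        ind
        for ind in pd.unique(individuals)
        if 2 <= (individuals == ind).sum() < len(individuals)
    ]
    if not eligible:
        raise ValueError("no individual has 2+ samples")
    chosen = rng.choice(eligible, size=min(n_individuals, len(eligible)), replace=False)
    scores = [silhouette_scores(coords, individuals, ind).mean() for ind in chosen]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Transcriptional strand asymmetry


@dataclass
class StrandTally:
    """Transcribed- vs non-transcribed-strand mutation tallies."""

    per_sample: pd.DataFrame  # sample, tissue, class, transcribed, non_transcribed
    per_tissue: pd.DataFrame  # tissue, class, means/SDs per strand, ratio
    zscores: pd.DataFrame  # per-sample z vs the tissue distribution
    n_excluded_no_gene: int = 0
    n_excluded_ambiguous_strand: int = 0


def strand_asymmetry(calls: pd.DataFrame, exons, sample_tissue: Mapping[str, str]) -> StrandTally:
    """Assign collapsed calls to the transcribed or non-transcribed strand.

    A call is on the transcribed strand when its pyrimidine reference base
    lies on the template strand of the host gene. Calls outside any gene or
    in regions with genes on both strands are excluded and counted.
    ``calls`` needs columns sample, chrom, pos, ref, alt.
    """
    n_no_gene = 0
    n_ambiguous = 0
    records: dict[tuple[str, str], dict[str, int]] = {}
    for row in calls.itertuples(index=False):
        hosts = exons.genes_overlapping(row.chrom, row.pos)
        strands = {ex.strand for ex in hosts}
        if not hosts:
            n_no_gene += 1
            continue
        if len(strands) > 1:
            n_ambiguous += 1
            continue
        gene_strand = strands.pop()
        cls, _, _, flipped = collapse_substitution(row.ref, row.alt, row.ref)
        pyr_strand = "-" if flipped else "+"
        template_strand = "-" if gene_strand == "+" else "+"
        strand_key = "transcribed" if pyr_strand == template_strand else "non_transcribed"
        rec = records.setdefault((row.sample, cls), {"transcribed": 0, "non_transcribed": 0})
        rec[strand_key] += 1

    rows = [
        {
            "sample": sample,
            "tissue": sample_tissue.get(sample, ""),
            "class": cls,
            "transcribed": rec["transcribed"],
            "non_transcribed": rec["non_transcribed"],
        }
        for (sample, cls), rec in sorted(records.items())
    ]
    per_sample = pd.DataFrame(
        rows,
        columns=["sample", "tissue", "class", "transcribed", "non_transcribed"],
    )

    tissue_rows = []
    z_rows = []
    if not per_sample.empty:
        for (tissue, cls), grp in per_sample.groupby(["tissue", "class"]):
            mt, sdt = grp["transcribed"].mean(), grp["transcribed"].std(ddof=0)
            mn, sdn = grp["non_transcribed"].mean(), grp["non_transcribed"].std(ddof=0)
            ratio = mt / mn if mn > 0 else np.nan
            tissue_rows.append(
                {
                    "tissue": tissue,
                    "class": cls,
                    "mean_transcribed": mt,
                    "sd_transcribed": sdt,
                    "mean_non_transcribed": mn,
                    "sd_non_transcribed": sdn,
                    "ratio": ratio,
                }
            )
            for r in grp.itertuples(index=False):
                z_rows.append(
                    {
                        "sample": r.sample,
                        "tissue": tissue,
                        "class": cls,
                        "z_transcribed": (r.transcribed - mt) / sdt if sdt > 0 else np.nan,
                        "z_non_transcribed": (r.non_transcribed - mn) / sdn if sdn > 0 else np.nan,
                    }
                )
    per_tissue = pd.DataFrame(
        tissue_rows,
        columns=[
            "tissue",
            "class",
            "mean_transcribed",
            "sd_transcribed",
            "mean_non_transcribed",
            "sd_non_transcribed",
            "ratio",
        ],
    )
    zscores = pd.DataFrame(
        z_rows, columns=["sample", "tissue", "class", "z_transcribed", "z_non_transcribed"]
    )
    return StrandTally(per_sample, per_tissue, zscores, n_no_gene, n_ambiguous)


# ---------------------------------------------------------------------------
# Signature similarity (marker-expression stratified)


@dataclass
class SignatureSimilarity:
    cosine_all: float
    p_all: float
    cosine_restricted: float
    p_restricted: float
    restricted_to: str
    flags: set[str] = field(default_factory=set)


def _cosine(u: np.ndarray, v: np.ndarray) -> tuple[float, bool]:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0, True
    return float(u @ v / (nu * nv)), False


def signature_similarity(
    profiles: pd.DataFrame,
    marker_expression: pd.Series,
    signature: pd.Series,
    quantile: float = 0.20,
    n_perm: int = 1000,
    seed: int = 0,
    restrict_to: str = "C>T",
) -> SignatureSimilarity:
    """Cosine similarity of a low-vs-high-expression mutation log ratio to a signature.

    The statistic compares the log ratio of mean per-context mutation rates
    between the ``quantile`` of samples with lowest marker expression and the
    same-size highest-expression group against a reference signature vector,
    both over all contexts and restricted to one substitution class. The p
    value is the fraction of ``n_perm`` random same-size two-group splits
    whose statistic is at least the observed one.
    """
    samples = [s for s in profiles.index if s in marker_expression.index]
    if len(samples) < 10:
        raise ValueError("need at least 10 samples")
    n_grp = int(np.floor(quantile * len(samples)))
    if n_grp < 2:
        raise ValueError(f"quantile groups of {n_grp} samples are too small")
    contexts = [c for c in profiles.columns if c in signature.index]
    if not contexts:
        raise ValueError("no shared contexts between profiles and signature")
    P = profiles.loc[samples, contexts].fillna(0.0)
    sig = signature.loc[contexts].to_numpy(dtype=float)
    order = marker_expression.loc[samples].sort_values().index
    low, high = list(order[:n_grp]), list(order[-n_grp:])

    eps = 1e-9

    def log_ratio(lo_idx, hi_idx) -> np.ndarray:
        lo = P.loc[lo_idx].mean(axis=0).to_numpy() + eps
        hi = P.loc[hi_idx].mean(axis=0).to_numpy() + eps
        return np.log2(lo / hi)

    mask_restricted = np.array([f"[{restrict_to}]" in c for c in contexts])
    obs = log_ratio(low, high)
    flags: set[str] = set()
    cos_all, deg_all = _cosine(obs, sig)
    cos_r, deg_r = _cosine(obs[mask_restricted], sig[mask_restricted])
    if deg_all or deg_r:
        flags.add("degenerate_log_ratio")

    rng = np.random.default_rng(seed)
    ge_all = ge_r = 0
    for _ in range(n_perm):
        perm = rng.permutation(samples)
        lr = log_ratio(list(perm[:n_grp]), list(perm[n_grp : 2 * n_grp]))
        c_all, _ = _cosine(lr, sig)
        c_r, _ = _cosine(lr[mask_restricted], sig[mask_restricted])
        ge_all += c_all >= cos_all
        ge_r += c_r >= cos_r
    return SignatureSimilarity(
        cosine_all=cos_all,
        p_all=ge_all / n_perm,
        cosine_restricted=cos_r,
        p_restricted=ge_r / n_perm,
        restricted_to=restrict_to,
        flags=flags,
    )
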