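# rnamut

Somatic DNA mutation discovery from bulk RNA-seq.

Bulk RNA-seq of normal tissue is, incidentally, a deep survey of the DNA
sequence of every expressed exon. A somatic mutation present in a clone of
cells shows up as a non-reference allele at a reproducible genomic position,
with an allele fraction set by the clone's size and the allele's expression.
The hard part is that RNA-seq is also full of things that look like somatic
mutations and are not: sequencing errors, alignment artifacts, RNA editing,
and germline variants. `rnamut` implements the full discovery pipeline —
candidate calling from pileups, a thirteen-step artifact filter cascade,
validation against matched DNA, and the downstream analyses that make the
resulting mutation catalogs interpretable (mutational spectra, tissue/donor
profiles, covariate associations, cancer-mutation enrichment, selection
signals, and chromatin covariates) — together with a generative simulator
that plants known mutations and known artifact classes so every stage can be
tested against ground truth.

## Method overview

**Candidate calling** (`rnamut.caller`). Aligned reads are deduplicated
(duplicates resolved toward the highest mean base quality), piled up per
position, and filtered to base calls with Phred quality >= 30. A position
becomes a candidate when the remaining calls show exactly two distinct
alleles, total high-quality coverage `C >= 40`, and alternate support
`A >= 6`. Sites where neither allele matches the reference are flagged
(`no_ref_allele`) and excluded downstream.

**Filter cascade** (`rnamut.filters`). Candidates then pass through, in
order: chromosome blacklist (sex chromosomes, mitochondria, unplaced
scaffolds); common-SNP and RNA-editing position masks; allele-specific
germline exclusion from matched DNA genotypes; a splice-proximity filter
(< 7 bp from an exon boundary); a binomial sequencing-error test (reject
unless `P(X >= A | C, 0.001) <= 1e-4`); four two-sided Mann–Whitney U tests
comparing alternate vs reference reads on read position, mapping quality,
base quality and strand at alpha = 0.05; a simulation-based variant-distance
test; a strict VAF ceiling (> 0.7 removed); tissue recurrence (allele seen in
>= 40 % of samples of one tissue removed) and cohort recurrence (>= 4 % of
all samples, removed cohort-wide), both computed with exact rational
arithmetic; and a hypermutated-sample outlier test on residual mutation load.
Per-sample attrition is reported for every step.

**Validation** (`rnamut.validation`). For calls with matched DNA, the
expected DNA-side support is `r_i = C_DNA * (A_RNA / C_RNA)`. Calls with
`r_i >= 8` are evaluable; the false discovery rate is the fraction of
evaluable calls without DNA support, reported raw and re-weighted across VAF
bins.

**Downstream** (`rnamut.profiles`, `associations`, `enrichment`,
`chromatin`). Pyrimidine-centric 6/96/1536-class mutational spectra with
expression-weighted context normalization; per-donor clustering quality via
silhouette scores on a pluggable 2-D embedding; transcribed-strand
asymmetry; inverse-normal-transformed mutation-load regressions against
technical and biological covariates with rank-, permutation- and
Benjamini–Hochberg-based FDR; hypergeometric enrichment of calls in known
cancer mutations with permuted-catalog controls; consequence annotation and
VAF-based selection contrasts; and histone-mark regression on
depth-corrected per-exon mutation rates.

## Worked example

```python
from rnamut.simulate import SimConfig, PlantedEvent, simulate_pileups
from rnamut.caller import build_pileups, dedup_reads, scan_candidates
from rnamut.validation import expected_alt_reads

sim = simulate_pileups(SimConfig(
    n_samples=1, n_sites=500, coverage_mean=100.0, seed=11,
    events=[PlantedEvent(250, "A", 0.25, "somatic")],
))
obs = sim.observations["sample000"]
calls = scan_candidates(build_pileups(dedup_reads(obs)), sim.ref_getter, "sample000")
for c in calls:
    print(c.chrom, c.pos, c.ref, c.alt, c.coverage, c.alt_count)
print("expected DNA support at 80x:", expected_alt_reads(80, 6, 1000))
```

Output:

```
chr1 250 C A 97 24
expected DNA support at 80x: 0.48
```

The planted C>A mutation at position 250 (true VAF 0.25) is recovered at
24/97 reads. The second line is the validation arithmetic: a call at RNA VAF
0.006 expects only 0.48 supporting reads in 80x DNA, which is why validation
is restricted to calls with expected support >= 8.

The same pipeline is available from the command line:

```bash
rnamut simulate --n-sites 200 --coverage 80 --out pileup.tsv
rnamut call --pileup pileup.tsv --ref ref.fa --out candidates.tsv
rnamut validate --pairs pairs.tsv --out bins.tsv
rnamut enrich --catalog catalog.tsv --cancer cancer.tsv --covered covered.tsv --out enrichment.tsv
rnamut chromatin --exon-table exons.tsv --out marks.tsv
```

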