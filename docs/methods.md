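# Methods

## Model and procedure

The package measures pairwise genotype discordance over a fixed panel of
genomic positions. A sample's data is a byte string `s` of length `L` (the
panel size), `s[i] ∈ {A,C,G,T,R,Y,S,W,K,M,\0}`: uppercase IUPAC codes for
called diploid SNV genotypes, NUL for anything else. Three bytewise
operations per pair produce three counts (zero bytes of XOR, OR, AND), and
the four identities in the README turn them into a discordance rate. The
XOR count includes both-missing positions (NUL XOR NUL = NUL), which is why
the OR count is subtracted; the AND count identifies positions with any
missing data only because every called code has bit 6 set — this bit-6
property is asserted over the whole alphabet in the tests and validated on
every panel construction.

Comparisons are scheduled one-way (each unordered pair once, `N(N−1)/2`
total) and mirrored into a symmetric matrix. The engine is deliberately
single-threaded: the point of the design is that byte-level operations alone
make desk-scale all-vs-all cheap. The naive per-position loop
(`naive_compare_pair`) implements the identical contract and serves as the
independent oracle in the tests and as the performance baseline; it is never
used by the pipeline.

### Degenerate cases and numerical choices

* **Zero queryable positions** (disjoint missingness): the rate is an
  explicit undefined value (`None` in records, NaN in the matrix, `NA` in
  TSVs), never 0 — reporting 0 would fake a perfect match.
* **Low-confidence pairs**: pairs with fewer than `min_queryable` (default
  50) mutually called positions get a flag in the pair table. A rate over a
  handful of positions is statistically meaningless; the flag reports, it
  never drops data.
* **Diagonal**: self-discordance is analytically 0 whenever a sample has at
  least one call, and undefined for an all-missing sample.
* **Ties in the sorted pair table** break lexicographically by sample names;
  undefined-rate pairs sort last.
* **Het/hom mismatches at the same ALT** (`R` vs `G`) count as discrepancies:
  single-byte equality is the comparison semantic.
* The count identities are enforced in the `PairwiseCounts` constructor, so
  any internal inconsistency raises immediately rather than producing a
  plausible-looking rate.

## Genotype encoding rules

VCF GT fields map to bytes as follows: diploid called genotypes with both
alleles single bases encode to the base (hom) or IUPAC ambiguity code (het),
symmetric in allele order and phase-blind (`0|1` ≡ `1/0`). Everything else —
missing or half-missing GT, ploidy ≠ 2, indel/symbolic/`N` alleles, a record
whose REF is not a single base — encodes to NUL. Non-diploid calls are
counted and logged. An allele index beyond the site's allele list is a
malformed-record error naming chrom/pos/sample, not a silent NUL.
Hemizygous calls (e.g. male X) therefore encode as NUL; a single IUPAC byte
cannot distinguish haploid states, and discarding them costs only panel
positions.

"Low quality" is operationalized as opt-in thresholds — site `QUAL <
min_site_qual`, per-sample `FORMAT/DP < min_depth`, optionally non-PASS
FILTER — all disabled by default so that the defaults never silently drop
data. Panel positions with no VCF record are missing by default
(`absent_policy="missing"`); for force-called inputs,
`absent_policy="homref"` fills them with the reference-base homozygote,
taking the reference base from any record seen at that locus or from a
supplied lookup. BED and VCF contig names are matched verbatim unless
`contig_normalization` is enabled; a file sharing zero positions with the
panel triggers a loud warning, since the usual cause is a `chr`-prefix
mismatch.

## Synthetic cohorts

The generator (`simulate`) draws, per site, a minor-allele frequency `p`
from a named distribution (default Uniform[0.15, 0.30], matching a
common-variant panel with population allele frequency ≥ 15%), then per
individual a genotype under Hardy-Weinberg equilibrium (hom-ref `q²`, het
`2pq`, hom-alt `p²`). Every emitted sample copies its individual's truth
and independently applies:

* **genotype error** — with probability `e` per genotype, replacement by one
  of the other two genotype states, uniformly. This is the simplest
  symmetric error model and makes the replicate-pair expectation closed
  form: `P(differ) = 2e(1−e) + e²/2 ≈ 2e`.
* **missingness** — with probability `m` per genotype, the call becomes NUL.
  Default `m = 0.02`, a typical panel-site dropout for exome data.

A swap plan exchanges the data under two sample labels after generation,
emulating a wet-lab swap; the truth record tracks each label's true
individual. Sites sit at regular 100 bp spacing on two synthetic
chromosomes (exercising chromosome-keyed allele-fraction plotting). Output
is force-called single-sample VCF 4.2 with GT/DP/AD/QUAL (depths
Poisson(40), het ALT reads Binomial(DP, ½)), a BED3 panel, a manifest TSV
and a JSON-lines truth file; a given spec + seed reproduces every file byte
for byte.

The analytic companions used to check the simulation:

* unrelated pairs: `E_p[1 − (q⁴ + 4p²q² + p⁴)]`, the probability two
  independent HWE draws differ, integrated over the MAF distribution
  (quadrature for uniform, exact for a point mass). For Uniform[0.15, 0.30]
  this is ≈ 0.508, inside the 40–55% band expected for
  different-individual pairs at common-variant panels.
* replicate pairs: `2e(1−e) + e²/2` as above (0.0199 at `e` = 1%, under the
  3% same-individual ceiling).

### What the generator does not emulate

No linkage disequilibrium, population structure, relatedness between
individuals, realistic site-frequency spectra, strand/reference biases, or
read-level error processes. Passing tests therefore demonstrate the
correctness of the encoding/comparison machinery and the separation of the
same-individual and unrelated regimes under idealized genotypes — not
calibrated discordance values for any particular real cohort, where
same-individual discordance varies with assay and caller.

## Problem sizes in tests

The shipped checks run 20 individuals × 10,000 sites for the unrelated
regime, 10 duplicated individuals × 10,000 sites for replicates, a
12-individual duplicated cohort × 5,000 sites for swap resolution, a
200-pair random-string sweep (lengths 1–5,000, missingness 0–100%) for
oracle equivalence, and 200 samples × 20,000 positions for the
performance-direction check. These sizes keep each check in seconds while
leaving the statistical margins (e.g. ±1.5 percentage points on a mean over
190 pairs, 3 standard errors on replicate rates) far wider than the Monte
Carlo noise.

## Design choices where the design was open

* **Reporting, not deciding**: the tool ranks pairs and flags best matches;
  it does not auto-call swaps. Investigation stays with the analyst.
* **Heatmap order is manifest order** — no clustering or dendrogram. The
  reading of the heatmap (same-individual blocks hugging the diagonal)
  depends on the user grouping samples by individual in the manifest; the
  color scale maps low discordance to the dark-red end and is a
  presentation choice, documented rather than canonical.
* **Plots dump their data as TSV** next to the images; all tests assert on
  the TSVs, never on pixels.
* **CLI split into `compare` / `simulate` / `plot`** so saved matrices can
  be re-plotted without re-ingesting VCFs.

## Known limitations

Quadratic pair count (no clustering/minimizer shortcuts); no kinship or
IBD estimation — discordance separates same-individual from unrelated but
is not a calibrated relatedness degree; multiallelic records are taken
as-is (no re-normalization or left-alignment); duplicate records at one
locus resolve first-passing-wins with a counted warning; VCF is the only
entry point (no FASTQ/BAM).
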