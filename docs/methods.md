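# Methods

This note documents the models and procedures svorchard implements, the
parameter defaults and why they were chosen, the design decisions made
where a choice was genuinely open, and the limits of what the synthetic
panels can demonstrate.

## Coordinates and formats

All internal coordinates are 1-based, fully closed — the native convention
of VCF and GFF3 — so no conversion happens at any analysis boundary. The
BED writer is the single place where 0-based half-open coordinates are
produced. VCF is read and written through pysam/htslib; QUAL passes
through htslib as a 32-bit float, so the package serializes it at
2-decimal precision, which is the precision round-trip identity is
guaranteed at. A translocation is represented as a reciprocal pair of
breakend (BND) records sharing one event id and is counted as a single
event everywhere; the pair enters consensus merging once, through the mate
with the lexicographically smaller locus, and both mate loci must agree
within the merge distance for two translocation calls to be merged.

Gene models come from GFF3. When a gene has several transcripts the
representative is the one with the longest total CDS (deterministic
tie-break on the transcript id); introns are the gaps between its
consecutive CDS intervals; the promoter is the 2000 bp immediately
upstream of the strand-aware gene start, truncated at contig edges.

## Per-caller filtering

LUMPY-style call sets are filtered with strict comparators: quality > 20,
total supporting reads > 5, and deletions shorter than 340 bp are removed
when they carry no split-read support. Values exactly at a cutoff fail
these ">" rules, mirroring how the inequalities are written. Missing
evidence fields count as 0, which is conservative for this filter. The
340-bp deletion rule is applied per caller, before merging. Small
variants use GATK-style hard filters (SNPs: QUAL < 40, QD < 2, FS > 60,
MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8; indels: QD < 2,
FS > 200, ReadPosRankSum < −20); a record is dropped when any condition
of its class fires, and conditions whose annotation is absent are not
evaluated, which is conservative for retention. Both filters are
idempotent and partition their input.

## Consensus merging

Two calls are compatible when they lie on the same chromosome(s), share SV
type and strand orientation (each requirement can be relaxed), and both
breakpoint distances are at most `max_dist` (default 1000 bp). Clusters
are connected components of the compatibility graph — single-linkage
chaining, which matches the semantics of the standard merging tool for
this design and is independent of caller order. The implementation builds
components with a sliding window over start positions, which is exact
because a start distance beyond `max_dist` already breaks compatibility;
the test suite checks equivalence against a brute-force all-pairs graph
oracle. A cluster is emitted only with calls from ≥ 2 distinct callers
(`min_callers`). Representative coordinates are the lower median of member
breakpoints — the merging convention is not prescribed anywhere, and the
median is robust and deterministic. The 50 bp–10 Mb size gate runs both
per caller and after merging (idempotent for this rule). Deletions and
insertions are tallied together as "indels" only in the reporting layer;
distinct types are kept internally.

## Population matrix, MAF, rarefaction

Genotypes are alt-allele dosages 0/1/2 with missing coded separately.
MAF = min(p, 1−p) with p computed over non-missing diploid genotypes.
"Occurrence frequency" is interpreted as carrier frequency — the fraction
of non-missing accessions in a group with dosage ≥ 1 — matching the
per-accession presence/absence reading of SV occurrence; an allele-
frequency variant of the statistic would be a trivial switch. Rarefaction
draws accessions without replacement for each subsample size and counts
variants with at least one carrier in the draw; missing genotypes never
count as carriers. The curve's mean is provably non-decreasing in sample
size, and the full-panel endpoint equals the number of segregating
variants. No functional form is fitted to the curve: only the empirical
points are produced.

## Selection scan

For each SV and phase (domestication: wild vs landrace; improvement:
landrace vs improved) the 2×2 table is carriers/non-carriers × group,
tested with the two-sided Fisher exact test and adjusted with
Benjamini–Hochberg within the phase. BH was chosen as the FDR method; the
classification thresholds are q < 0.001 (strict) and fold change > 2
(strict). Fold change uses Haldane-style +0.5 smoothing on carrier counts
— (carriers + 0.5)/(n + 1) — so it stays finite when a group has no
carriers, which is the typical pattern for strongly selected SVs; the
test itself uses raw counts. Direction compares raw frequencies: positive
when the later group is higher. With 13 wild accessions, the smallest
achievable two-sided p (all-or-nothing tables) is on the order of 1e−8,
so q < 0.001 with ~1000 simultaneous tests is attainable only for
near-complete frequency shifts — a real power constraint of small wild
panels that the synthetic defaults reflect (below).

## Diversity and sweeps

Per-site π is the unbiased pairwise-difference estimator
2j(n−j)/(n(n−1)); a site needs at least two non-missing genotypes, else it
contributes 0. Windowed π sums site values inside each window (default
100 kb, step 10 kb; a site contributes to every window containing it) and
divides by the full window length — the windowed-π convention of the
standard VCF toolkit — so SNP density matters, not only per-site
diversity. ROD is the ratio π_earlier/π_later exactly as written, not
1 − ratio. Windows where the later group has zero diversity but the
earlier does rank above every finite ratio; windows with zero diversity
in both are excluded from ranking. The top ⌈5%⌉ of ranked windows are
flagged, ties at the boundary resolving in genomic order, and flagged
windows that overlap or are step-contiguous merge into one sweep region —
region counts are otherwise undefined for overlapping windows. Region
overlap between SNP-based and SV-based sweeps is the summed pairwise
intersection length.

## Association support

The single-marker test is the F test of a simple linear regression of
phenotype on dosage (df = n − 2), with missing pairs dropped. It makes no
population-structure correction: mixed-model GWAS is out of scope, and
the synthetic phenotypes are structure-free, so the test is calibrated on
them (its null type-I error is checked at α = 0.05). LD is the squared
Pearson correlation of dosage vectors (composite LD; genotypes are
unphased). The Bonferroni cutoff is −log10(α/m) reported to 2 decimals,
with m the number of markers actually tested after MAF ≥ 0.01 filtering.

## Synthetic panels: what they emulate

The generator produces a toy genome (default 2 × 2 Mb contigs), gene
models, truth SVs, per-caller call sets, population genotypes, SNPs, and
a phenotype, all from one seed fanned out into named sub-streams (a
component can change without perturbing the others; identical seeds give
byte-identical files).

- **Truth SVs** (default 300): type mix 35% DEL / 25% INS / 5% DUP / 5%
  INV / 30% BND, log-uniform sizes (100 bp–10 kb for DEL/INS/DUP, 1–100 kb
  for INV), echoing the shape of empirical SV maps where indels dominate,
  translocations are common, and inversions run large. Same-type truth
  SVs are kept ≥ 2.5 kb apart so clusters are unambiguous.
- **Callers** (lumpy, manta, gridss, delly): each misses a truth SV with
  probability 0.1 (FNR), jitters breakpoints by N(0, 50 bp), and adds 10%
  caller-private false calls. Private false calls of the same type are
  placed more than the merge distance apart across all callers, so they
  are unreplicated by construction and must be removed by the ≥ 2-caller
  rule alone. The LUMPY-like caller emits quality/support fields with 5%
  of calls engineered to fail the QC rules.
- **Population genotypes**: 13 wild / 70 landrace / 233 improved
  accessions. Neutral SVs share a Beta(0.3, 3) base carrier frequency
  (most variants rare) drifted by N(0, 0.03) per group. Selected SVs (20
  per phase by default) start at carrier frequency U(0.01, 0.05) in the
  earlier group and shift by 0.8 — the near-absent-to-near-fixed pattern
  that strongly selected SVs show empirically, and the only regime a
  13-accession wild group can detect at q < 0.001 (see above). Dosages
  are Binomial(2, p) under Hardy–Weinberg with p = 1 − √(1 − f), masked
  at 5% missingness.
- **SNPs**: exponential spacing (mean 200 bp), base frequency
  U(0.05, 0.5) with small per-group drift. Inside each planted sweep
  region the later group of the region's phase keeps a site polymorphic
  with probability 0.1, scaling expected diversity to 10%.
- **Phenotype**: one causal SV at carrier frequency 0.51 in every group
  (allele frequency 0.3), effect 1, Gaussian noise calibrated so the
  marker explains 30% of trait variance.

What the panels do **not** emulate: linkage disequilibrium between
variants (sites are independent), population structure and kinship,
reference bias, genotyping error correlated with SV type or size,
caller-specific breakpoint biases, and sequence content (no reads are
simulated). Passing tests therefore demonstrate the correctness and
calibration of the algorithms under their stated assumptions — not
robustness to structure confounding or caller idiosyncrasies in real
panels.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
instances chosen to make the statistics decisive: merge recovery uses 10
panels of 300 truth SVs; selection recovery uses 20 panels of 1020 SVs
(20 shifted); the permuted-label null uses 5000–10,000 variants; sweep
recovery uses 10 panels with ~20,000 SNPs; the clustering oracle runs 100
random instances of up to 200 records. Every random stage takes an
explicit seed, reports it in its output, and is reproducible to the byte.

## Known limitations

- The Fisher test and BH adjustment are exact but the scan loops per
  variant; panels beyond ~10⁶ variants would want a vectorized
  hypergeometric path.
- Breakend merging compares mate loci pairwise but does not model
  multi-break rearrangements.
- The ROD ranking treats truncated terminal windows like full windows
  (their π denominator is the configured window length); sweeps at contig
  ends are accordingly slightly harder to flag.
- `read_gff3` requires gene/mRNA/CDS features; models without CDS (e.g.
  non-coding genes) yield empty CDS/intron sets and participate only
  through their promoters.
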