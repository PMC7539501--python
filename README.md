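# svorchard

Population structural-variation (SV) analysis for resequenced crop panels:
build a consensus SV map from multiple callers, annotate its functional
impact on genes, scan for variants selected during domestication and
improvement, detect selective sweeps from windowed nucleotide diversity,
measure map saturation by rarefaction, and run the supporting GWAS
computations — all exercised end to end on synthetic panels with known
ground truth.

The package targets the study design used for crop SV maps built from
hundreds of short-read genomes in structured panels (wild, landrace, and
improved groups), where SVs are called per accession by several tools,
filtered, merged into population-level consensus events, genotyped, and
then mined for signals of selection and trait association.

## The methods at the core

**Consensus merging.** Calls from different callers describe the same event
when they share SV type and breakpoint strand orientation and both
breakpoints lie within 1000 bp. Consensus SVs are the connected components
of this compatibility graph (single-linkage chaining), kept only when at
least 2 distinct callers contribute, with sizes gated to 50 bp–10 Mb.
LUMPY-style call sets are first filtered by quality (> 20), read support
(> 5), and the rule that deletions < 340 bp need split-read support.

**Selection scan.** For each SV the carrier ("occurrence") frequency is
compared between the two groups of a phase — wild vs landrace
(domestication) and landrace vs improved (improvement) — with a two-sided
Fisher exact test on the 2×2 carriers/non-carriers table. P values are
Benjamini–Hochberg adjusted per phase; an SV is under positive (later
frequency higher) or negative selection when *q* < 0.001 and the smoothed
fold change max(f′A, f′B)/min(f′A, f′B) exceeds 2, with
f′ = (carriers + 0.5)/(n + 1).

**Sweep detection.** Per-site diversity π = 2j(n−j)/(n(n−1)) over n
haplotypes with j alternate alleles is summed in 100-kb windows sliding by
10 kb and divided by window length. ROD = π_earlier/π_later ranks windows;
the top 5% are flagged and merged into sweep regions.

**Impact annotation.** SVs are intersected with CDS, intron, and 2-kb
strand-aware promoter intervals; each affected gene gets one category by
the precedence CDS > intron > promoter, so category counts partition the
affected-gene count.

**GWAS support.** MAF ≥ 0.01 filtering, the Bonferroni cutoff
−log10(α/m), a single-marker regression test, and composite LD r² between
dosage vectors.

## Worked example

Run the whole pipeline on a simulated panel (200 planted SVs, 40 genes,
dense SNPs, 13 wild / 70 landrace / 233 improved accessions):

```python
from svorchard import PipelineConfig, run_pipeline
from svorchard.pipeline import format_report

report = run_pipeline(PipelineConfig(seed=1, simulate={
    "n_truth_svs": 200, "n_genes": 40, "snp_spacing": 500,
    "n_selected_svs": 10}))
print(format_report(report))
```

Key lines of the output (abridged):

```
## SV map
- indel: 120
- DUP: 10
- INV: 10
- BND: 60
- total: 200

## selection
- domestication.positive: 6
- domestication.negative: 4

## sweeps
- SNP.domestication.n_regions: 1
- SNP.domestication.total_mb: 0.29

## rarefaction
- saturation_pct: [73, 82, 89, 93, 95, 96, 98, 99, 99, 100]
```

All 200 planted SVs survive QC and consensus merging (the per-type counts
sum to the total); the domestication scan recovers the planted
frequency-shifted SVs in both directions; the planted low-diversity region
appears as one SNP-based domestication sweep of ~0.3 Mb; and the
rarefaction curve shows the map saturating as accessions are added.

The same stages are available from the shell:

```bash
svorchard simulate --seed 1 --out study/
svorchard qc --caller lumpy study/lumpy.vcf study/lumpy.qc.vcf
svorchard merge study/lumpy.qc.vcf study/manta.vcf study/gridss.vcf study/delly.vcf
svorchard rarefy study/sv_genotypes.vcf study/panel.tsv
svorchard run --config pipeline.yaml
```

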