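# Methods

## The measurement model

Every analysis rests on a per-cytosine reading model. A cytosine carries a
true state (unmodified C, 5mC, or 5gmC) and a true modified fraction
*f* ∈ [0, 1] — the fraction of molecules at that position carrying the
modification. After a conversion chemistry and PCR, each sequenced molecule
reads T or C; the probability of reading C at a site is a mixture over its
molecule populations:

```
p_C = f_gmc · P(C | 5gmC) + f_mc · P(C | 5mC) + (1 − f_gmc − f_mc) · P(C | C)
```

with chemistry-specific reading probabilities:

* **DEA** — `P(C | C) = P(C | 5mC) = 0.002` (residual non-conversion,
  uniform across CG/CHG/CHH), `P(C | 5gmC) = 1` (the glyceryl group blocks
  deamination; an optional loss parameter exists and defaults to 0, since
  mass spectrometry shows essentially no 5gmC conversion).
* **WGBS** — `P(C | 5mC) = P(C | 5gmC) = 1` by definition of bisulfite
  protection; `P(C | C) = 0.002`.
* **TET-BS** — `P(C | C) = 0.002`; the two-step oxidation + bisulfite leaves
  about 3% of 5mC unconverted on average, with context multipliers
  (CG 1.0, CHG 1.5, CHH 0.75 around the 3% mean) capturing its
  context-dependent conversion efficiency.

**Locus-level escape heterogeneity (TET-BS).** A homogeneous 3% escape can
essentially never exceed a 17% ratio filter at ~100× depth
(P(X ≥ 18; Bin(100, 0.03)) ≈ 10⁻⁹), yet TET-BS data show false 5gmC calls
concentrated at methylated CpGs. The observable therefore implies that
conversion efficiency varies between loci (secondary structure, oxidation
completeness). We model the per-site escape probability as Beta-distributed
with the context mean above and shape α = 0.25 (heavy right tail: a small
percentage of sites escape at > 20%). DEA non-conversion is kept
homogeneous, matching its observed uniformity across contexts. α is
exposed as `escape_dispersion` (None = homogeneous).

## Site calling

Confident 5gmC sites satisfy **strictly** `n_unconverted > 10` and
`ratio > 0.17` (the printed wording of the filters is strict, and the
boundary cases are tested as such). Zero-depth records are skipped and
counted, not errors. Knockout subtraction is positional exclusion: any
candidate whose (chrom, pos, strand) is also called — under identical
thresholds — in the *Dnmt1*-KO sample is flagged `removed_by_ko` and
excluded from the retained set but kept in the audit table. An alternative
reading (ratio arithmetic against the KO) was considered and rejected as the
default because the KO signal is sparse technical noise, not a smooth
background; the audit table retains what a ratio-based variant would need.

At 100× depth the joint filter requires ≥ 18 unconverted reads; under DEA
chemistry the per-site false-positive probability for an unmodified
cytosine is P(X ≥ 18; Bin(100, 0.002)) ≈ 10⁻²⁹, so the expected number of
false calls in a megabase-scale genome is far below one. This analytic bound
is verified against simulation in the tests.

**Gradient testing.** `gradient_select` evaluates a (count, ratio) grid on a
DEA/TET-BS pair of the same specimen: called counts, mass abundance in ppm,
exact-position overlap and Jaccard per grid point. The selected point
maximizes Jaccard among points whose mean abundance falls within a
multiplicative window (default 0.5–2×) of the expected ppm; an empty window
falls back to the global best-overlap point with a warning. Overlap is
site-level identity — no proximity window — because both methods report the
same coordinate system at base resolution.

**Abundance** is mass-based: `1e6 · Σ u_called / Σ d_all`, paralleling a
mass-spectrometry mole fraction of modified cytosine; a site-count variant
(`abundance_ppm_sites`) exists for sensitivity analysis.

**Deconvolution** clamps `wgbs_ratio − gmc_ratio` to [0, 1]; the clamped
negative mass is tallied (`attrs["negative_mass"]`) as an estimate of
residual noise. Confident 5mC sites apply the same strict thresholds to the
deconvolved signal, with `depth · mc_ratio` as the 5mC-attributable count.

## Coordinates and conventions

Internal arithmetic is 0-based half-open; the per-cytosine report keeps the
extractor dialect (1-based plus-strand reference coordinate for both
strands), GFF3 is converted from 1-based closed, BED/bedGraph are 0-based
half-open. Minus-strand cytosines are independent records — symmetric CpG
counts are never pooled, matching per-cytosine extractor output; strands
are pooled only in spike-in conversion-rate strata (configurable by
filtering the input). One transcript per gene (longest by exonic length) is
used for all gene-level analyses.

Context is classified from the two bases 3′ of the C on its own strand
(CG; CHG; CHH with H ∈ {A,C,T}; AMBIG when an N or the chromosome end
intervenes). The classifier is verified against an exhaustive independent
oracle over all 5-mers on both strands.

## Annotation constants

| constant | default | note |
|---|---|---|
| promoter window | 2000 bp upstream of TSS | orientation-aware, `(TSS−2000, TSS]` |
| downstream window | 300 bp past TES | |
| TSS-distance window | ±3000 bp, 100-bp bins | counts both directions |
| TE flank | 1000 bp, closed at exactly 1000 | nested TEs merged before zoning |
| feature precedence | promoter > exon > intron > downstream > distal | common annotator default |
| expression quartile | 0.25 | ties broken by stable gene id |
| metagene | 1-kb flanks in 50-bp bins, 60 body bins | minus-strand genes reversed |

A site in one gene's intron but within another gene's promoter window is a
promoter site (precedence); the precedence order is configurable. The
transcript segmentation for expression correlation is {promoter, first/
middle/last third of the gene body, downstream}, plus the whole body; the
thirds are measured in transcription orientation. Correlation is Spearman
by default (robust to FPKM skew; Pearson by flag), with region summaries as
both max and mean over covered cytosines and 0 where a region has none.
"Gene contains 5gmC" means ≥ 1 confident site between promoter start and
downstream end. k-mer enrichment uses exact one-sided binomial tests
against the genome-wide C-centred k-mer background with Benjamini–Hochberg
adjustment at 0.05.

## The synthetic study

`synthio` emulates the structure the real system presents to the pipeline:

* GC-rich genome (default 64% GC, ~1.56 Mb in 2 chromosomes ⇒ ~10⁶
  cytosines over both strands), non-overlapping genes with exons/introns,
  TE and histone-mark intervals.
* 5mC planted per context (CG 3%, CHG 0.8%, CHH 0.4% — CpG-preferential,
  sparse overall), with density boosts inside TEs (×2) and H3K9me1 (×5) and
  higher levels inside boosted regions (f → f^0.5), reflecting the
  repressive-chromatin pattern. Per-site levels are Beta-distributed
  (CG skewed high, CHH low) with a per-gene coherent level shift
  (±0.25 uniform): genes are differentially methylated, which is what
  makes gene-level 5mC–expression correlation detectable at all.
* 5gmC planted at 10 ppm of cytosines (site density), CHH-weighted (0.70)
  with a ×3 intron boost, 60% of sites exclusive of 5mC; per-site fraction
  uniform in (0.5, 0.95). Non-exclusive sites carry a secondary 5mC
  fraction `f_mc2 ≤ 1 − f_gmc` on the remaining molecules, so WGBS-minus-DEA
  deconvolution can find 5mC at shared sites while each cytosine still has
  exactly one labelled state.
* Depth ~ negative binomial, mean 100×, shape 20 (matching ~95–145×
  coverage).
* Spike-ins: the verbatim 480-bp fully-5mC amplicon template and a
  deterministic 5-kb lambda-like unmodified fragment.
* Expression: log FPKM = 3.0 + 1.5 · (mean 5gmC fraction in the first third
  of the gene body) − 1.5 · (mean 5mC fraction over the body) + N(0, 1).
* KO sample: the same genome with every state C, plus an optional
  noise-site injector to exercise KO subtraction.

All generators are deterministic given (config, seed).

**Scaling choices.** The default configuration reproduces the study's
*rates* (10 ppm, ~100×) at desk scale, which leaves only ~10 5gmC sites —
enough for calling precision/recall but not for association analyses. The
association preset (`SimConfig.for_association()`: 500 genes, 2.4 Mb,
200 ppm) instead preserves the *absolute* number of 5gmC-bearing genes
(a few hundred sites, as at genome scale) while shrinking the null mass;
recovery of the expression link is then carried by a realistic number of
genes. Tests use genomes of 0.06–2.4 Mb; the largest single run is the
default-condition recovery at ~10⁶ cytosines.

**What the simulator does not model** — and hence what passing tests do not
show about real data: sequencing error beyond conversion chemistry, PCR
duplicates and mapping bias, fragment-level bisulfite degradation,
strand-asymmetric coverage, correlated methylation beyond the per-gene
shift, isoform structure, and any real motif preference of CMD1. Recovery
numbers on synthetic data are upper bounds on real-data performance.

## Numerical choices

Clopper–Pearson (exact) 95% intervals for conversion rates; Fisher's exact
test for two-proportion comparisons (chemistry contrasts, DE proportions).
Zero-depth strata are flagged `no_data`, never reported as rate 0.
Ratios at zero depth are NaN. Metagene bins with no covered cytosine are
NaN, not 0. Degenerate correlations (constant input, < 10 genes) are
flagged `unstable` with NaN statistics rather than raised.

## Known limitations

* The measured 5gmC/5mC overlap underestimates sharing relative to truth:
  at shared sites the secondary 5mC fraction is bounded by 1 − f_gmc and
  often falls below the 17% ratio filter, so threshold censoring inflates
  the apparent exclusivity. The truth-level accounting in the tests
  quantifies this.
* KO subtraction removes a true site if the KO sample coincidentally calls
  the same position; at realistic non-conversion rates this is negligible
  but not impossible.
* The gradient search treats the two methods symmetrically; a chemistry
  with systematically inflated calls (TET-BS at methylated CpGs) shifts the
  Jaccard surface and can favour stricter cut-offs.
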