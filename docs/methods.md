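# Methods

## Data model

Four inputs drive the analysis, all tabular (tab-delimited text; the panel
is a VCF):

1. **GWAS summary statistics** — one row per biallelic SNV: identifier,
   chromosome, 1-based position, effect and other allele, per-effect-allele
   odds ratio, association p-value. Column names are mapped through a
   dialect configuration, so PGC-style ("daner") headers parse without code
   changes. Rows with indel/multi-allelic notation, non-positive or
   unparseable odds ratios, p-values outside [0, 1], or duplicated keys are
   rejected and counted (first occurrence wins on duplicates); a missing
   mandatory column aborts.
2. **Human-specific site catalog** — positions where the modern human
   lineage (MD) or the archaic lineage (AD) carries the derived allele,
   with ancestral/derived states defined against the chimpanzee outgroup.
3. **MAF table** — per-SNP minor allele frequency in [0, 0.5], from an
   external frequency resource (not from the LD panel).
4. **Reference genotype panel** — VCF used only to estimate linkage
   disequilibrium; dosages are 0/1/2 ALT-allele counts, missing allowed.

All inputs must share one genome build; no coordinate conversion is
performed. GWAS SNPs join catalog sites by rsID first, then by
(chromosome, position). A SNP whose rsID matches a site recorded at
different coordinates is excluded as a key conflict rather than joined by
either key. Unjoined SNPs stay in the analysis universe — they form the
genome-wide denominator.

## Pipeline

Stages run in a fixed order: **prune → join → MAF attach/filter →
polarize → bin → test**. One global seed fans out to per-dataset,
per-stage child seeds via a seed sequence, so stages are individually
reproducible and a full run is a pure function of (inputs, config, seed).
Every filter logs its counts (read rejects, join misses, prune removals,
MAF exclusions, unresolved polarity) into a JSON run summary — the audit
trail asserted by the tests. Batch mode applies the identical pipeline to
several GWAS datasets.

### LD pruning

Statistical tests downstream assume approximately independent SNPs. Within
each chromosome, every pair of SNPs at most `window_bp` apart (default
1,000,000) whose dosage vectors have squared Pearson correlation above
`r2_threshold` (default 0.2) is flagged. r² is the composite (genotypic)
correlation over pairwise-complete samples — the unphased statistic; pairs
with fewer than 4 complete samples or a constant vector are unflagged.
Flagged pairs are processed in ascending (chromosome, left position, right
position) order; when both members are still retained, one is removed by a
fair coin. The coin is a keyed hash of (seed, chromosome, positions), not a
draw from a shared stream: each pair's outcome is then independent of which
other pairs happened to be flagged, which makes retained sets reproducible
and threshold changes comparable. SNPs absent from the panel pass through
untested and are counted — silently dropping them would bias the
enrichment denominator. The all-pairs-within-distance rule is step-free
and at least as strict as any stepped window scheme.

The retained-count monotonicity under a rising threshold is an empirical
property of block-structured data, not a theorem: removing a "hub" SNP at
a low threshold can break many pairs at once that a higher threshold must
break one by one. The test suite checks it on the standard synthetic block
structure, where it holds.

### MAF filter and polarity

Only SNPs with MAF strictly below 0.1 enter the enrichment analysis — the
frequency ceiling at which human-specific variants occur; SNPs without a
MAF entry are excluded and counted. By default the same filter also
restricts the polarity-ratio analysis (`maf_filter_scope: both`), for
internal consistency between the two analyses; `enrichment_only` lifts it
from the ratio analysis.

Polarity: the risk allele is the effect allele if OR > 1, else the other
allele. The catalog's ancestral allele is matched against the GWAS alleles
directly first; only if that fails are both GWAS alleles complemented, and
A/T and C/G SNPs are never complement-resolved (conservative exclusion,
`strand_ambiguous`). OR exactly 1 carries no direction (`no_direction`).
A SNP is derived-risk when the non-ancestral (derived) allele is the risk
allele, derived-protective otherwise. Allele checks precede the direction
check, so an unmatchable ancestral state reports as an allele problem even
at OR = 1. Note that for a strand-unambiguous biallelic SNP the two
alleles and their complements cover all four nucleotides, so
`allele_mismatch` can only arise from non-ACGT ancestral states.

### Binning

The analyzed (post-prune, post-filter) SNPs' p-values are cut into ten
bins. Default edges are the empirical sample deciles — published decile
boundaries are themselves data-derived — and a fixed-edge mode applies a
user-supplied list verbatim for replication-style runs
(`stats.PAPER_DECILE_EDGES` carries the canonical schizophrenia-analysis
list [1, 0.886, 0.781, 0.671, 0.559, 0.443, 0.336, 0.233, 0.140, 0.054,
0]). Bins are indexed from the highest-p interval (0) to the lowest (9).
Intervals are closed on the high-p side and half-open below, the lowest
closed at 0; a p equal to an interior edge falls in the bin having that
edge as its upper bound.

### Per-bin and overall statistics

Fold-change scores are computed in both orientations (printed convention
(b·c)/(a·d), default; observed/expected (a·d)/(b·c)); the run summary
always names the convention used. The denominators a and b are computed on
the identical filtered universe used for binning, which makes bin counts
conserve exactly (Σd = b, Σc = a per lineage). Undefined statistics (zero
denominators, empty bins) are NaN in memory and `NA` on disk, with counts
still reported.

Two-sided Fisher exact p-values follow the point-probability rule: the sum
of hypergeometric probabilities, over all tables with the observed
margins, whose point probability does not exceed the observed table's.
Because conventions for two-sided exactness differ, the implementation
uses exact big-integer numerators (a multiplicative hypergeometric
recurrence over the support with a common denominator), so ties are
resolved by integer comparison with no floating-point gate; a zero margin
returns p = 1 and is flagged. No multiple-testing correction is applied
across bins; raw per-bin p-values are reported.

Per bin, MD and AD are contrasted on membership ([[d_MD, c−d_MD],
[d_AD, c−d_AD]]) and on polarity ([[risk_MD, prot_MD], [risk_AD,
prot_AD]]); each lineage is additionally contrasted against the genome
background. The membership contrast compares the two lineages' site rates
directly, so it is null-calibrated only when the two catalogs contribute
equal polymorphic-site rates; with unequal catalogs it (correctly) detects
the base-rate difference.

"Overall" aggregates are genuinely ambiguous, so three are reported and
the default is named in the run summary: (i) the bin-pooled MD-vs-AD
Fisher test (default); (ii) Fisher-combined per-bin p-values; (iii) a
per-lineage chi-square goodness-of-fit of the per-bin site counts d_i
against the expectation c_i·b/a. The pooled per-lineage 2×2 is degenerate
(pooling returns the margins, p = 1 identically), which is why the
goodness-of-fit statistic carries the per-lineage overall signal.

## Synthetic-data generator

The generator produces summary statistics directly rather than simulating
individual-level case/control genotypes: the analysis consumes only
summary statistics, and direct generation makes ground truth exact.

* **Panel.** SNPs are laid out in LD blocks along one chromosome. Within a
  block each site copies a latent dosage vector and redraws per-sample
  with probability 1 − r^{1/4} (r the target within-block r²), giving
  pairwise dosage correlations ≈ r inside a block and independence across
  blocks. Defaults: 20,000 SNPs in 5,000 blocks of ~4 SNPs spaced 50 kb,
  200 samples, within-block r² 0.8 — small tight LD clusters, so pruning
  keeps roughly one SNP per cluster and a large analyzed universe
  remains, as in real post-pruning GWAS sets.
* **Catalog and overlap.** 4,000 MD and 3,000 AD sites by default, of
  which `overlap_fraction` (default 0.3, matching the ~28–31% of catalog
  sites observed polymorphic in large GWAS) coincide with GWAS SNPs; the
  remainder are monomorphic and never join. Overlapped sites carry the
  GWAS rsID with probability 0.7, exercising both join keys.
* **Polarity and odds ratios.** An overlapped site is derived-protective
  with probability θ/(1+θ) (θ = `protective_excess_md` or `_ad`; θ = 1 is
  the symmetric null). The odds-ratio magnitude is log-normal
  (|N(0, 0.15)| on the log scale) and oriented so the derived allele's
  direction matches the drawn polarity; the listed effect allele is
  ancestral or derived at random. Site SNPs use strand-unambiguous allele
  pairs, so every simulated polarity is resolvable and calls can be scored
  against truth exactly.
* **P-values.** A fraction `assoc_effect_fraction` (default 0.05) of SNPs
  receives p-values from a shifted-|z| alternative (z ~ N(2.5, 1));
  the rest are uniform. Polarity is drawn independently of the p-value by
  default, so any detected polarity signal is attributable to the injected
  θ alone; `coupling_gamma > 0` makes θ_eff = θ^((1−p)^γ), concentrating
  the excess in low-p bins for demonstrations, and is recorded in the
  output metadata.
* **MAF.** Beta(0.5, 3) truncated to (0, 0.5]; site-overlapping SNPs are
  resampled below 0.1 to mirror the frequency ceiling of human-specific
  variants. `cap_site_maf: false` disables the cap to test the filter
  itself. Panel allele frequencies are drawn independently of the MAF
  table, as in the real pipeline where frequencies come from a separate
  resource.

What the generator does **not** emulate: coalescent/demographic realism,
archaic introgression tracts, strand errors, genotyping artifacts,
population stratification, or any dependence between association strength
and site membership. Passing tests therefore demonstrate the pipeline's
internal correctness and calibration, not robustness to those real-data
complications.

`simulate_resolved_polarities` is a summary-level shortcut that draws only
(lineage, polarity, p) triples — exactly the sampling model the full
generator induces for resolved site SNPs under uncoupled settings — and is
used for the calibration and power studies below.

## Verification study sizes

Chosen to give tight Monte-Carlo error at desk scale: the exact-Fisher
check enumerates every 2×2 table with all margins ≤ 30 (~162,000 tables);
the pruning contract runs 1,000 SNPs in 20 blocks with an exhaustive
all-pairs check; null calibration uses 2,000 replicates of 2,000 resolved
SNPs (per-bin ratio-test size at α = 0.05 must lie in [0.03, 0.07]);
parameter recovery uses 200 replicates of 5,000 resolved SNPs per lineage
at θ_MD = 2 (pooled ratio within [1/2.3, 1/1.7] in ≥ 95%, pooled contrast
p < 0.001 in ≥ 99%); determinism reruns a full 1,000-SNP pipeline and
compares bytes.

## Known limitations

* The greedy random-removal pruning keeps an arbitrary member of each
  correlated pair; some published practice preferentially keeps the more
  significant SNP, which would bias p-value-stratified counts and is
  deliberately not done here.
* Strand-ambiguous (A/T, C/G) SNPs that fail a direct ancestral match are
  excluded rather than frequency-resolved.
* The membership contrast's base-rate sensitivity (above) means its pooled
  p-value reflects catalog composition, not selection, when catalogs
  differ in size.
* Fisher exact tests are conservative at small per-bin counts; reported
  type-I error runs slightly below nominal in sparse bins.
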