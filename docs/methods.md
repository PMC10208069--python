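# Methods note

This note records the statistical model behind `bulkmap`, the generator
that stands in for real sequencing data, the default parameter choices
and why they were made, and the known limits of both.

## 1. Genetic model

One autosomal locus with two alleles, A (dominant, "green" phenotype) and
B (recessive parent's allele; BB gives "yellow"). Two fully inbred,
fully homozygous parents (AA × BB) produce an F1, whose selfed progeny
form the F2 mapping population. Expected F2 genotype ratio 1:2:1, hence
the 3:1 phenotype ratio that `chisq_segregation` tests (Pearson
goodness-of-fit, df = 1, no continuity correction).

Meiosis follows the Haldane model: per gamete the number of crossovers on
a chromosome of genetic length L cM is Poisson(L/100), breakpoint
positions are uniform on the cM scale, and there is no interference or
chromatid choice bias. Recombination fraction and map distance are linked
by r = (1 − e^(−2d/100))/2 and its inverse d = −50·ln(1 − 2r); the
Kosambi inverse is available by flag.

## 2. Pool statistics

For each biallelic site, with AD_ref/AD_alt the pool's read depths on the
two parental alleles (ALT = the recessive parent's allele):

- SNP-index = AD_alt / (AD_ref + AD_alt)
- Δ(SNP-index) = SNP-index(yellow pool) − SNP-index(green pool)
- ED² = Σ over the four bases of (p_yellow − p_green)²; for a biallelic
  site this equals 2·(alt-proportion difference)². InDel alleles map onto
  two pseudo-bases, which leaves ED² well defined.

At a fully linked site with selection-perfect bulks the yellow pool is
fixed ALT (index 1) and the green pool has ALT frequency 1/3 (AA:Aa among
dominants is 1:2), so Δ → 2/3 and ED² → (2/3)² + (2/3)² = 8/9. These two
constants anchor most oracle tests.

Site filters, applied in a fixed first-fail order so each removal is
attributed to exactly one rule: `low_gq` (any of the four samples below
GQ 50), `parent_het` (a parent heterozygous or missing),
`parent_monomorphic` (parents share a genotype), `pool_missing` (a pool
with zero reads).

## 3. Windows, thresholds, peaks

Per-site Δ and ED² are averaged in 200 kb windows sliding by 100 kb —
windows are [k·step+1, k·step+window], 1-based inclusive, truncated at
the chromosome end; windows with fewer than `min_sites` sites get null
means and can never be significant.

Two threshold modes are implemented:

- **quantile (default):** the 95%/99% global empirical quantiles of the
  observed |window-mean Δ| — the "top 5% / top 1%" reading of the usual
  plotted significance lines. With ~3,300 windows genome-wide and a
  single causal region, the upper 1% tail is occupied by the true peak
  and its shoulders, so unlinked chromosomes are almost never flagged.
- **simulate:** a per-window Monte-Carlo null. For each simulated site,
  each bulk's B-allele count is Binomial(2·pool_size, ½) (no phenotype
  selection), reads are Binomial at the window's observed per-site
  depths, and the thresholds are quantiles of the |window-mean Δ| null
  (linear-interpolation quantiles for cross-platform determinism;
  n_sims ≥ 1000 enforced).

The simulate mode is the QTL-seq-style construction, but it is
*per-window*: a 99% threshold yields ~1% false positives per window by
design, i.e. ~33 false windows genome-wide, which defeats genome-wide
peak calling (and its independent-sites null also understates the
window-mean variance, since real bulk allele frequencies are almost
perfectly correlated within 200 kb). The global-quantile mode is
therefore the default for calling; the simulate mode remains available
for per-window inference.

Peak calling takes the windows above the chosen threshold (99% level by
default; the ED² co-requirement is optional), merges
overlapping/adjacent significant runs, and additionally fuses runs
separated by at most `merge_gap_bp` = 2 Mb. That distance is the
linkage-decay scale of the design (~3.3 cM/Mb here): within it the
window statistic is still dominated by the same locus and merely wiggles
around the threshold on the peak shoulders, so two flagged runs that
close together are one association signal.

## 4. The generator and its defaults

Defaults (`SimConfig()`), chosen once as the study conditions:

| parameter | default | why |
|---|---|---|
| genome | 11 chromosomes × 30 Mb | small-cucurbit scale |
| map length | 100 cM/chromosome (≈3.3 cM/Mb) | makes 115 kb ≈ 0.4 cM, so a 847-plant F3 yields single-digit recombinants between flanks ~115 kb apart |
| variants | 4,000/chromosome + causal (~27 per 200 kb window) | same order as a real resequencing study after filtering (hundreds per window would be typical at full scale; 400/chromosome proved noise-dominated) |
| F2 size | 241; bulks 30 + 30 | typical BSA design |
| depth | Poisson, mean 53.83× per pool | typical pool depth |
| sequencing error | 0.01/read, symmetric | observed ALT-read probability f(1−e) + (1−f)e |
| GQ | mixture: 99 or 20 with failure prob. 0.02 | produces a realistic `low_gq` filter bite (~8% of sites lose ≥1 of 4 samples) |
| causal locus | chr6:23,800,000 | planted ground truth |

Parents are emitted as fixed 0/0 and 1/1 calls; pool GT fields are naive
frequency cuts (≤0.15 / ≥0.85) and are *not* used by the analysis, which
works from AD. Bulk membership is drawn without replacement within
phenotype class; the yellow bulk is genotype-perfect (all BB at the
causal locus), matching visual selection of a recessive phenotype.

Realism limits: uniform variant spacing (no SNP deserts/clusters), no
mapping bias or duplicated-region artifacts, GQ independent of depth,
error rate constant across sites, no phenotyping error, and one
environment-free fully penetrant locus. These make the planted truth
exactly recoverable — appropriate for testing the estimator, generous
relative to real data.

The F3 fine-mapping stage simulates selfed progeny of an F2 plant
heterozygous across the 770 kb marker region (21 evenly spaced markers,
ST1–ST21 at ~38.5 kb spacing; flanks ST9/ST12 bracket the causal locus
at ~115.5 kb). The inbred panel is generated directly under the
insertion ⇔ yellow rule with an optional count of planted discordant
lines.

## 5. Linkage, fine mapping, panel

**Two-point linkage.** Marker order is taken from physical position; only
adjacent pairs are estimated. Each two-locus genotype class contributes
its definite recombinant-gamete count; the double heterozygote is
ambiguous (0 or 2 recombinant gametes) and is resolved by EM with E-step
weight 2r²/((1−r)² + r²). Pairs estimated at r ≥ 0.5 get infinite cM, a
warning, and are excluded from the summed map length.

**Fine mapping.** For K ordered markers, candidate causal positions live
in 2K−1 slots (marker/gap alternating). A position inherits the nearest
flanking non-missing genotype codes; where those flanks disagree (a
crossover interval) the genotype is ambiguous and cannot exclude the
position. Dominant-model consistency: yellow requires code B; green is
consistent with A or H; missing codes impose no constraint. The
consistent slot sets are intersected over *all* phenotyped individuals
(non-recombinants also constrain), and the result is reported bounded by
the nearest flanking markers. An empty intersection raises a conflict
error naming the offending individuals rather than voting — scored
recombinants are assumed error-free. Resolution is therefore
marker-limited: with 38.5 kb spacing the interval cannot shrink below
one marker gap regardless of recombinant count.

**Panel concordance.** 2×2 phenotype × insertion table; two-sided Fisher
exact p; degenerate margins report p = 1 with a warning.

**Sequence utilities.** Translation uses the standard code and stops at
the first stop codon; `premature_stop` is true iff that stop precedes
the final codon. Insertions are placed after a 1-based offset; a
frame-preserving 15 bp insertion carrying an in-frame stop truncates the
protein, a clean 39 bp insertion adds 13 residues. 2^−ΔΔCt computes
per-replicate ΔCt (target − reference, paired by plate order) and tests
sample vs calibrator ΔCt with Welch's t by default (pooled by flag) —
with n = 3 replicates, assuming equal variances is the riskier choice.

## 6. Numerical and design decisions

- Internal coordinates are 1-based inclusive everywhere (VCF
  convention); BED output converts (start−1, end) at the writer only.
  Interval width = end − start + 1.
- All randomness flows from `numpy.random.SeedSequence(seed).spawn()`
  per stage, so adding replicates or stages never perturbs earlier
  streams; identical config + seed gives byte-identical TSV/BED output
  (floats written with `%.6g`).
- Quantiles use linear interpolation (deterministic across platforms).
- The VCF reader is a deliberate minimal-subset parser (biallelic,
  `GT:AD:GQ`), cross-checked against cyvcf2 in the test suite; FASTA and
  translation go through Biopython, all test statistics through SciPy.
- The core analysis is a model/results pair (`BulkedSegregantScan` /
  `BsaScanResults`); mapping and sequence operations are plain functions
  — a χ² test or an interval intersection has no state worth a model
  object.

## 7. Limitations

- The generator's idealizations (above) mean measured power/false-peak
  rates are upper bounds on real-data performance.
- The simulate threshold mode is per-window and anti-conservative
  genome-wide; it is not used for peak calling by default.
- Fine-mapping resolution is bounded by marker spacing, and phenotypes
  are scored on individuals (no family-level progeny testing).
- Two-point EM assumes coupling-phase F2 codominant data; no dominant
  markers, no ordering search, no interference-aware mapping.
- Single-locus, fully penetrant trait only; no multi-pool or multi-QTL
  designs.
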