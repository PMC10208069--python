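# bulkmap

Bulked-segregant mapping of a single dominant/recessive locus, end to end:
a built-in F2/F3 population and pool-sequencing simulator, the BSA-seq
genome scan (SNP-index and ED² statistics with sliding-window significance
calling), Mendelian segregation testing, regional two-point linkage,
recombinant-based fine mapping, diagnostic-marker concordance, and
CDS-consequence / qPCR (2^−ΔΔCt) utilities — with a CLI that runs the
whole pipeline reproducibly from one seed.

## The scientific problem

A qualitative trait (e.g., stigma color in a cucurbit crop) segregates
3:1 in an F2 population from two inbred parents, so a single locus with a
dominant allele controls it. To locate that locus without genotyping every
plant, **bulked-segregant analysis by sequencing (BSA-seq)** pools DNA
from the two phenotypic extremes (here 30 + 30 F2 plants) and sequences
each pool. At sites linked to the causal locus, the pools' allele
frequencies diverge:

- **SNP-index** of a pool at a site = fraction of reads carrying the
  recessive parent's (ALT) allele, `AD_alt / (AD_ref + AD_alt)`.
- **Δ(SNP-index)** = SNP-index(recessive pool) − SNP-index(dominant pool).
  At a fully linked site it tends to `1 − 1/3 = 2/3` (the dominant-pool
  bulk is 1/3 ALT because AA:Aa segregate 1:2 among the dominant class).
- **ED²** = squared Euclidean distance between the pools' four-base read
  proportion vectors; `8/9 ≈ 0.889` at a fully linked site.

Per-site statistics are averaged in 200 kb windows sliding by 100 kb,
windows beyond the 95%/99% reference band of |window-mean Δ| are flagged,
and runs of significant windows are merged into candidate peak intervals.
The locus is then narrowed by genotyping a large F3 family with regional
markers, intersecting the genomic regions consistent with each
recombinant's phenotype, and validated with a diagnostic insertion marker
on an inbred panel.

Because raw sequencing data for such a study is huge, `bulkmap` ships a
**generator**: a Haldane-model meiosis simulator that produces the F2
population, the bulks, pooled read depths with sequencing error and
genotype-quality noise, the F3 fine-mapping family, and the inbred panel,
so every stage runs (and is tested) against a planted ground truth.

## Worked example

The core analysis is a statsmodels-style model/results pair: build a
`BulkedSegregantScan` from variant records (VCF with two parents + two
pools), call `.fit()`, get a `BsaScanResults`.

```python
import bulkmap as bm

# simulate one study-scale replicate (11 chromosomes x 30 Mb, 4000
# variants/chromosome, n_f2=241, bulks 30+30, ~54x depth; causal locus
# planted at chr6:23,800,000) and scan it:
rep = bm.run_replicate(seed=7)
results = rep["results"]          # a BsaScanResults
print(results.summary())
```

Output (this exact text, deterministic under the seed):

```text
Bulked-segregant scan
======================================================
sites in / passing filters : 44001 / 40602
  removed (low_gq            ): 3399
  removed (parent_het        ): 0
  removed (parent_monomorphic): 0
  removed (pool_missing      ): 0
windows (200 kb, step 100 kb)  : 3300
|delta| thresholds (95/99%): 0.3257 / 0.5848 [quantile]
called peak intervals (99% level): 1
  chr6:20200001-25200000  width 5.00 Mb  max delta 0.660  max ED2 0.876
```

The single called interval contains the planted locus, and the peak
window statistics sit at the fully-linked expectations (Δ ≈ 2/3,
ED² ≈ 8/9). `results.sites`, `results.windows`, `results.peaks` hold the
per-site frame, the window frame and the called intervals;
`results.save(prefix)` writes TSV/BED/JSON and `results.plot(path)` a
two-track Manhattan figure.

The full pipeline (simulate → segregation χ² → scan → F3 fine mapping →
panel concordance) runs from one config + seed:

```bash
bulkmap run --seed 7 --out-dir demo_run    # bundled demo config
```

Key fields of the resulting `demo_run/summary.json` at seed 7:

```text
segregation : 169 green : 72 yellow, chi2 = 3.06, p = 0.080 (3:1 kept)
bsa         : 1 peak, chr6:20,200,001-25,200,000
finemap     : 847 F3, flanks ST9/ST12, 5 recombinants,
              interval chr6:23,758,000-23,873,500 (115.5 kb)
panel       : 45/45 concordant, Fisher p = 4.1e-13
```

Standalone subcommands: `bulkmap simulate`, `bsa`, `segregation`,
`finemap`, `panel`, `cds-effect`, `ddct` (see `--help` on each). Exit
codes: 0 success, 2 config error, 3 stage failure.

## Reproduction

Everything is deterministic given a seed; identical config + seed gives
byte-identical TSV/BED outputs.

```bash
# full test suite (unit + property + 7 acceptance criteria; ~5 min)
python -m pytest -q tests/

# headline quantities as JSON ({"name": {"value": ..., "n": ...}}; ~2 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

At seed 1 the acceptance run reports, among others: segregation p 0.127
(191:50 vs 3:1), peak-interval width 4.94 Mb from its printed bounds,
519-aa protein from a 1560 bp ORF, causal-window Δ 0.657 / ED² 0.876,
100% peak detection and 100% false-peak-free replicates (n = 50), 9 F3
recombinants among 847, and 45/45 panel concordance.

## Layout

```
src/bulkmap/
  simulate.py    F2/F3/bulk/pool-depth/panel generator (SimConfig)
  variant_io.py  minimal VCF 4.2 subset, BED3, TSV tables
  bsa.py         filters, SNP-index/ED², windows, thresholds, peaks,
                 BulkedSegregantScan -> BsaScanResults
  mapping.py     chi-square segregation, EM two-point linkage,
                 recombinants, delimit_interval, panel concordance
  sequtil.py     CDS translation/insertion effects, 2^-ddCt
  pipeline.py    RunConfig + run_all (stage orchestration)
  cli.py         click CLI (`bulkmap`)
  study.py       replicate-level power/calibration helpers
docs/methods.md  model, assumptions, parameter choices, limitations
```

See `docs/methods.md` for the statistical model, the generator's realism
envelope, and the rationale behind the default analysis choices.
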