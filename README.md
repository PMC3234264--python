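# irilmap

Linkage-map construction and genome-colinearity analysis for intermated
recombinant inbred line (IRIL) populations genotyped on SNP arrays.

The package covers an array-genotyping analysis pipeline end to end:

- **`irilmap.simpop`** — synthetic data with known truth: forward
  simulation of IRIL populations (F2 → *t* generations of random
  intermating → single-seed-descent selfing, Haldane crossovers),
  genotyping noise with per-call quality (GC) scores, two-channel
  intensity clusters of the four recurring marker pattern types, and
  "wrong assemblies" with planted inversions, translocations and
  deletions.
- **`irilmap.genio`** — strict readers/writers for the three tabular
  dialects (genotype tables with IUPAC calls and the literal `Failed`
  token; map tables with per-population `frame`/`placed`/`-` status, cM
  and pseudo-cM columns; physical placement tables), plus config
  loading and the CLI shell.
- **`irilmap.clusterqc`** — intensity-pattern classification (1-D theta
  mixtures, BIC model selection), genotype calling with an intensity
  floor, failure rates, per-group call rates, parent/F1 triplet
  consistency, duplicate concordance, exact-binomial segregation
  distortion scan, DICE similarity + UPGMA dendrogram.
- **`irilmap.panelsel`** — prioritized four-step SNP panel selection
  with prefilters and greedy even-spacing fill.
- **`irilmap.linkmap`** — de-novo map construction: stage-specific
  filtering (GC 0.8/0.6, missing 35%/50%, MAF > 0.10), two-point
  estimation and linkage grouping, scaffold (≥ 10 cM spacing, replicate
  seeds, reconciliation) → framework (robustness-controlled insertion)
  → bin placement (maximum-likelihood interval assignment), and
  intermating-corrected genetic distances: the line-level recombinant
  fraction `R(r, t) = ½[1 − (1−r)^t (1−2r)/(1+2r)]` with Haldane cM and
  a pseudo-cM scale (t forced to 0).
- **`irilmap.syncomp`** — map-vs-assembly comparison: chromosome
  concordance, non-syntenic clusters, named non-colinear regions
  (`<chrom>.<n><pop>`), monotone-smoothed recombination landscapes
  (cM/Mbp), homothetic physical-position prediction, polymorphism
  deserts.

## CLI

```sh
irilmap --seed 7 simulate --n-chromosomes 10 --markers-per-chrom 200 \
    --n-lines 239 --t-intermating 4 \
    --out-genotypes geno.csv --out-gc gc.csv \
    --out-placement placement.csv --out-truth truth.json
irilmap qc  --genotypes geno.csv --out-report qc.csv --out-summary qc.json
irilmap map --genotypes geno.csv --gc-scores gc.csv --t-intermating 4 \
    --population sim --out-map map.csv
irilmap compare   --map-table map.csv --population sim \
    --placement placement.csv --out-synteny synteny.csv --out-regions regions.csv
irilmap landscape --map-table map.csv --population sim \
    --placement placement.csv --out landscape.csv
```

Global flags: `--seed`, `--config` (YAML or JSON key-value file),
`--log-level`.

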