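# hic3dqc

Quality control and reproducibility scoring for binned intrachromosomal
Hi-C contact matrices, exercised end-to-end on synthetic data.

The package implements:

* **Four replicate-similarity scores**
  * `hicrep` — stratum-adjusted correlation coefficient (SCC): 2D mean-filter
    smoothing, per-genomic-distance Pearson correlations, variance-weighted
    aggregation. Range [-1, 1].
  * `genomedisco` — random-walk concordance: sqrt-normalization,
    row-stochastic transition matrix raised to power *t* (default 3),
    normalized L1 distance, score = 1 − distance. Range [-1, 1]. Coverage
    is matched by downsampling the deeper sample first.
  * `hicspector` — spectral score: normalized graph Laplacian, sum of
    Euclidean distances between the *r* (default 20) leading sign-aligned
    eigenvectors, linearly rescaled to [0, 1].
  * `quasar-rep` — correlation of enrichment-weighted interaction
    correlation matrices computed within a 100-bin band of the diagonal.
* **A single-sample quality score** (`quasar-qc`): weighted minus unweighted
  correlation mean, pooled across chromosomes.
* **Noise simulation**: genomic-distance noise (within-offset shuffling,
  stratified by marginal products in groups of 100), random-ligation noise
  (marginal-biased pair draws), and exact-count mixtures at chosen noise
  fractions (default ladder 5–50%).
* **Resampling**: uniform (hypergeometric) downsampling, coverage ladders
  and pseudo-replicates (two independent downsamples of the pooled pair,
  each at the average coverage).
* **Synthetic data**: product-model contact intensities (distance decay ×
  TAD blocks × compartments × bin bias) and labeled benchmark sets with
  biological / pseudo / non-replicate pairs.
* **Benchmarking**: per-chromosome score aggregation, empirical
  midpoint thresholds between non-replicate and biological score
  distributions, replicate-type ranking evaluation and noise-response
  curves.

## CLI

All I/O uses TAB-separated triplet text (`chrom  start1  start2  count`,
0-based bin starts, upper triangle) or dense TSV.

```sh
# synthetic benchmark (triplet files + JSON manifest of labeled pairs)
hic3dqc synth --n-cell-types 2 --n-bins 200 --n-interactions 1000000 --seed 1 --out synth/

# score a pair with one method
hic3dqc score --method hicrep     --a a.tsv --b b.tsv --resolution 40000
hic3dqc score --method genomedisco --a a.tsv --b b.tsv --t 3 --seed 1
hic3dqc score --method hicspector  --a a.tsv --b b.tsv --r 20
hic3dqc score --method quasar-rep  --a a.tsv --b b.tsv --window 100

# single-sample quality (one file per chromosome)
hic3dqc qc chr1.tsv chr2.tsv

# noise injection and resampling
hic3dqc simulate-noise --matrix a.tsv --levels 5,10,15,20,30,40,50 --g-share 0.333 --seed 1 --out noisy/
hic3dqc downsample --matrix a.tsv --n 1000000 --seed 1 --out down.tsv
hic3dqc pseudoreps --a a.tsv --b b.tsv --seed 1

# ranking experiment over a labeled manifest
hic3dqc benchmark --config cfg.json --out report.json
```

`cfg.json` keys: `manifest` (path to a `synth`-style manifest), `resolution`,
`methods`, `seed`, optional per-method `params`.

## Conventions

* Contact matrices are symmetric, non-negative, dense per-chromosome
  arrays; raw matrices hold integer counts.
* Marginal of bin *i* = full row sum; total interactions = sum over the
  upper triangle including the diagonal.
* Every stochastic operation takes an explicit seed; fixed seeds give
  bit-identical results.
* Undefined scores raise `UndefinedScoreError` instead of returning a
  silent number; genome-level means skip undefined chromosomes with a
  warning.
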