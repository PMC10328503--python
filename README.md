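# tardis-barseq

Simulation and quantification of random-barcode lineage experiments built
on *C. elegans* extrachromosomal arrays (TARDIS barcoding). A degenerate
15-mer barcode (`NNNCNNTNTNANNNN`: 11 random positions, 4^11 ≈ 4.2
million sequences) is amplified by complexing PCR, assembled into a
heritable array, and integrated one-per-animal into a genomic landing
pad; each stage is read out by UMI-tagged 87 bp amplicon sequencing.

The package provides, as one library plus a CLI:

* **Generative simulator** — library synthesis, per-template
  Beta-efficiency PCR (the "jackpotting" mechanism), array formation as
  founder sampling with zero-truncated Poisson(λ) copy numbers,
  frequency-proportional integration, and FASTQ read simulation with
  UMIs, PCR duplicates, substitution errors and a truth sidecar.
* **Read processing** — Q30 running-sum 3′ trimming (NextSeq poly-G mode
  available), N and max-expected-error ≤ 1 filters, crop to 87 bp,
  `CAC`+10+`GAC` UMI extraction, duplicate collapse on (UMI, sequence),
  trim to the 15 bp barcode; every stage keeps a conservation ledger.
* **Error correction** — abundance-greedy Levenshtein clustering
  (radius 2, merge ratio 5), with exact mass conservation.
* **Statistics** — plateau read-count threshold, diversity and jackpot
  summaries, sequence-logo probability matrices, multi-sample
  membership/containment overlap, zero-truncated Poisson fits with
  chi-square GOF, and array-vs-F1 Pearson correlation (log-space
  p-values) with replicated-outlier detection.

## Worked example

The numbered drivers under `analysis/` walk the whole chain; each prints
what it found and writes tables under `results/analysis/`.

```sh
python analysis/01_simulate_dataset.py 0
python analysis/02_process_reads.py
python analysis/03_cluster_barcodes.py
python analysis/04_diversity_stats.py
python analysis/05_array_f1_correlation.py 0
```

Output of the final two steps at seed 0:

```
plateau threshold (from raw counts): 5 reads (fallback default, no plateau found)
diversity: 1288 unique barcodes over 32574 reads; frequency CV 0.995
jackpots (count > 50): 62 barcodes = 4.70% of unique, 15.2% of reads
fixed-position probabilities: {4: 1.0, 7: 1.0, 9: 1.0, 11: 1.0}
zero-truncated Poisson fit to the array copy numbers: lambda = 3.192, GOF p = 0.000 (jackpot amplification thickens the tail)
promoter panel worked example: 13 injected, 12 present in the array line, 9 confirmed integrated

unbiased integration: pooled r = 0.9992 (log10 p = -124.6, n = 91)
per-replicate r: [0.9966, 0.9967, 0.9972, 0.9963]; outliers flagged: 0
planted bias (x4 / x0.25): pooled r = 0.9802; flagged [('ACTCGATGTTAGAAC', 'over'), ('GATCAATTTAACTGC', 'under')]
outlier recovery over 100 seeds: 100 exact (100%)
```

Reading this: a simulated 1319-founder array sequenced at ~45k reads
yields 1288 barcodes above the 5-read threshold; the four fixed template
positions are perfectly conserved; the array's copy numbers fit a
zero-truncated Poisson with λ̂ ≈ 3.2 (the GOF rejects the pure Poisson
because 5% of founders carry log-normal jackpot amplification — exactly
the planted deviation). In the integration experiment, array frequencies
predict F1 integrant frequencies at r ≈ 0.999, and when two barcodes are
planted with 4× and 0.25× integration bias the replicated-outlier rule
(|standardized residual| > 3 in ≥ 3 of 4 replicates) recovers exactly
that pair, with directions, in 100/100 simulations.

The same pipeline runs as a single command on simulated or real FASTQ:

```sh
tardis-barseq run --seed 0 --out-dir results/demo
tardis-barseq process --fastq sample.fastq.gz --out-dir results/sample
```

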