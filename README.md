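# hoxtempo

Tools for asking whether Hox cluster genes are *activated* in the order
they sit on the chromosome — the temporal collinearity hypothesis — in
early *Xenopus tropicalis* embryos, using the two kinds of evidence that
bear on it:

* **nascent-transcript RT-qPCR**: absolute quantitation of pre-spliced
  (intron-containing) transcripts, the direct readout of active
  transcription, against no-reverse-transcriptase (RT−) controls; and
* **RNA-seq-style trajectories**: smoothed transcripts-per-embryo curves,
  ordered by when each gene's curve first reaches fixed per-embryo counts.

It is written for developmental biologists and computational people who
want the full statistical chain — calibration, detection, onset
estimation, rank analysis — as tested, reusable code, together with a
synthetic-data generator that stands in for embryo time courses so every
stage can be exercised without any wet-lab data.

## The analysis

**Absolute quantitation.** A dilution series of known template fits
`Cq = b + m·log10(copies)` by OLS; amplification efficiency is
`10^(−1/m) − 1` (1.0 = perfect doubling, `m = −3.32`). Copies are
back-calculated only inside the calibrated range; reactions with no
amplification by the cycle limit count as zero copies.

**Detection of de novo transcription.** Per gene and time point, RT+
replicate copy numbers are compared with RT− (an F-test chooses the pooled
or Welch t-test; the t-test is one-sided, RT+ > RT−, α = 0.05).

**Three onset estimators** for each gene over the 14-point sampling series
(3 hpf / stage 7 to 19.5 hpf / stage 24, 23 °C):

1. *qPCR detection* — earliest time with a significant RT+/RT− difference;
2. *extrapolated onset* — background-subtracted (RT+ − mean RT−) de novo
   copies are compared across time points by Tukey–Kramer; the earliest
   significant rise between two sampling points defines a line whose
   x-intercept is the onset. A gradual riser whose adjacent steps are each
   non-significant but whose two-step rise is significant gets a
   *bridged* interval, fitted by OLS over the span;
3. *midpoint* — the center of that rise interval.

**Trajectory ordering.** Genes are ranked by the first time their mean
trajectory reaches 200,000 / 100,000 / 50,000 / 10,000 transcripts per
embryo (linear interpolation); crossings within a 30-min window group as
simultaneous, and 95%-band overlap annotates order confidence.

**Collinearity.** Kendall's τ-b between a gene's 3′→5′ position in its
cluster and its onset time, with onset differences inside the window
treated as ties, an explicit inversion list, and permutation p-values
(onsets shuffled across the cluster's genes).

## Worked example

The numbered scripts under `analysis/` run the whole chain on a simulated
collinear HoxA panel plus one gradual-riser gene:

```sh
python analysis/01_simulate_dataset.py --seed 0
python analysis/02_quantify_qpcr.py
python analysis/03_estimate_onsets.py
python analysis/04_order_trajectories.py
python analysis/05_assess_collinearity.py
```

`02` calibrates and quantifies:

```
standard curve: slope -3.3217, efficiency 1.000, R^2 1.0000, valid 10-1e+06 copies
de novo transcripts detected for 12/12 genes
```

`03` prints the three estimates per gene (hpf) — note the gradual riser,
whose rise interval bridges 10.5–12.5 hpf, so its midpoint onset is 11.5:

```
method         extrapolated  midpoint  qpcr_detection
gradual_riser         10.51      11.5            11.5
hoxa1                  4.50       5.5             6.5
hoxa2                  6.50       7.0             7.5
...
hoxa13                16.50      17.5            18.5
bridged rise intervals (gradual risers): gradual_riser
```

`04` confirms the crossing order is identical at all four thresholds, and
`05` reports, per onset method:

```
HoxA [extrapolated]: tau-b +1.000, 0 inversion(s), P(tau_perm >= tau) = 0.001 -> consistent with collinearity
```

A τ-b of 1 with zero inversions means the recovered activation order
matches genomic order exactly; on an anti-collinear panel the same
pipeline returns τ-b = −1 with every comparable pair inverted.

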