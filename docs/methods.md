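# Methods

## Transcription model

Each gene in each tissue follows a deliberately minimal kinetic model:
maternal mature mRNA `M0` decays as `M0·exp(−d·t)`; zygotic synthesis of
pre-mRNA starts at the effective onset `T = max(onset, t_MBT)` (bulk
zygotic transcription does not begin before the midblastula transition,
~4 hpf at 23 °C) at a constant per-embryo rate `r`; pre-mRNA converts to
mature mRNA by first-order splicing at rate `s`. Closed form:

    pre(t)    = (r/s)·(1 − exp(−s·(t − T)))        for t ≥ T, else 0
    mature(t) = M0·exp(−d·t) + r·(t − T) − pre(t)   for t ≥ T

so with `d = 0` the synthesized mass balance `pre + mature = M0 + r·(t−T)`
holds exactly (tested). An optional "leaky" term adds the same kinetics at
a low rate from 0 hpf, off by default. Nothing finer (bursting, cell-number
growth, delays) is modeled: the downstream statistics consume only the
qualitative shape — nascent signal appearing at onset and a nascent pool
orders of magnitude below the mature pool.

Defaults (per embryo): `r = 2000 copies/h`, `s = 0.2 /h`,
`M0 = 5·10^5`, `d = 0.05 /h`, `t_MBT = 4 hpf`. These describe a
housekeeping-like gene: a mature pool that stays within a factor of ~2
over the sampled window while the nascent pool rises yet stays ≤ 5% of it
at 18.5 hpf (tested); hox-like fixtures set `M0 = 0`. Rates are
calibration choices — the assay constrains only ratios and shapes, and all
detection statistics are scale-free under the multiplicative noise below.

## Measurement model

One qPCR reaction contains 1/40 embryo (ten embryos pooled, 5 ng of the
2 µg reverse-transcribed). Replicate Cq values are generated through the
standard curve with Gaussian noise (default sd 0.2 cycles, i.e. ~14%
copy-level CV), Poisson-distributed genomic-DNA contamination copies
(mean 0.05; the same draw feeds RT+ and RT− reactions, keeping the RT−
background "virtually no amplification"), and censoring at 40 cycles.
Copy values outside the calibrated dilution range are marked and excluded
from statistics, never extrapolated; censored reactions count as zero
copies. All simulators take explicit seeds; there is no global random
state.

## Statistical procedures

**RT+ vs RT−.** A two-sided F-test of variance equality at the same α as
the main test (the conventional reading of "F-test, then t-test") chooses
between the pooled and Welch t-tests. The t-test is one-sided (RT+ > RT−)
by default because contamination cannot depress RT+ in expectation; the
two-sided variant is a parameter. Degenerate cells (all-censored RT+,
fewer than two usable replicates, zero variance on both sides) are
resolved by rule and flagged rather than by the t machinery.

**Tukey–Kramer.** Implemented directly on the studentized-range
distribution with the Kramer unequal-n standard error
`sqrt(MSE/2·(1/n_i + 1/n_j))`, pooled within-group MSE and `N − k` error
degrees of freedom; cross-checked in the tests against an independent
reference implementation, and against the pooled t-test for `k = 2`
(where `q = t·√2`). It runs on replicate-level background-subtracted
values (each RT+ replicate minus the RT− mean — the RT− is a plate-level
background estimate, so subtracting its mean preserves RT+ dispersion;
negative differences clamp to zero with a flag). P-values are optional so
that large simulation loops only pay for the (cached) critical quantile.

**Rise interval.** Among significant *increasing* pairs `(i, j)`, the
earliest rise is the one ending soonest (smallest `j`): the first time the
transcript number is demonstrably above an earlier level. If the adjacent
pair `(j−1, j)` is itself significant, that consecutive pair is the
interval. Otherwise the interval bridges from the latest earlier point
still significantly below `j` — the last time at the pre-rise level —
flagged `bridged`. Ranking candidate intervals by their endpoint (rather
than "consecutive pairs first, anywhere") matters in practice: a gradual
riser usually has clearly significant consecutive pairs *later* in the
course, which would otherwise mask the earlier two-step rise that defines
its onset.

**Extrapolated onset.** For a consecutive interval, the x-intercept of
the line through the two points, `t_i − y_i·(t_j − t_i)/(y_j − y_i)`; for
a bridged interval, the x-intercept of the OLS line through all points of
the span. Intercepts below 0 hpf clamp to 0 (flagged); intercepts before
the sampling point preceding the interval are reported raw with a warning
— the estimator is allowed to place onsets between sampling points, and
clamping them to the grid would reintroduce the granularity the method
exists to avoid. Extrapolation uses background-subtracted means (the same
series the significance test ran on).

**Trajectory ordering.** Crossing is computed on the mean curve, linearly
interpolated between grid points; the 95% bands only annotate confidence
(overlap at both genes' crossing times), because no probabilistic
definition of "reached" is available from band summaries alone.
Simultaneity grouping is single-linkage within the 30-min window —
transitive, so a chain can span more than the window end to end; a
complete-linkage variant is selectable. Ties break by gene id, making the
output independent of input order. Genes never reaching a threshold rank
last as their own group.

**Collinearity.** Kendall τ-b between within-cluster position rank
(a dense 1..n rank, since X. tropicalis clusters are gappy in paralogous
groups) and onset time, computed by explicit O(n²) pair enumeration so the
inversion list falls out of the same pass; onset differences within the
simultaneity window count as ties. Inference is by permutation of onset
values across the cluster's genes (n ≤ 13 rules out asymptotics), with
add-one p-values for both tails: `P(τ_perm ≥ τ_obs)` (evidence of
concordance) and `P(τ_perm ≤ τ_obs)`. The numeric criterion — τ-b,
inversion count, permutation p — is this package's operationalization of
"temporal collinearity holds"; the biology fixes no threshold, so reports
carry the window and permutation settings alongside every verdict.

## The gradual-riser fixture

The bridged-interval behavior is exercised by a designed plate: de novo
copies 0 through 10.5 hpf, 175 at 11.5, 360 at 12.5, then a plateau
(800–1180), with three replicates per point at ±0.2 Cq around the design
value (~14% CV). Under Tukey–Kramer across the 14 groups this spread puts
the critical difference between the one-step (175) and two-step (360)
rises by a wide margin, so neither (10.5, 11.5) nor (11.5, 12.5) is
significant while (10.5, 12.5) is — deterministically, which is the point:
the significance pattern is a property of the design, not of a noise
draw. The pipeline then brackets the rise at (10.5, 12.5) and the midpoint
estimator returns 11.5 hpf. A stochastic variant of the same pattern
(seeded Cq noise) is covered in the unit tests.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — maternal
decay, post-MBT onset, nascent ≪ mature, triplicate multiplicative Cq
noise, near-censoring RT− background, range censoring, tissue-mixture
averaging of nascent signal. It does not emulate Gaussian-process
trajectory fitting (lognormal replicate draws with percentile bands stand
in; only band-overlap semantics are consumed), sequencing reads, spatial
expression, cell-number growth, or per-gene efficiency differences.
Passing tests therefore demonstrate that the estimators recover what this
model generates at realistic noise; they do not validate the kinetic model
against real embryos.

## Problem sizes and tolerances in the test suite

Parameter recovery uses 11 true onsets on 5–12 hpf, default kinetics,
Cq sd 0.3 and 20 seeds (220 estimates), requiring the extrapolated onset
within half the local sampling interval in ≥ 80% of cases — the estimator
is intrinsically biased early by up to a gap width when an onset falls
late in a sampling gap, which is why the bound is a quantile, not a mean.
Type-I control uses 100 silent-gene plates (≤ 10% false onsets);
order-preservation uses 500 random two-tissue mixtures; the statistical
cores are compared against reference implementations on 200 (Tukey, k = 2)
and 100 (τ-b, n ≤ 13) random instances. The collinear demonstration panel
uses onsets staggered one per sampling interval, clean technical noise
(Cq sd 0.05) and a contamination-free RT−, so that any ordering failure
would be attributable to the estimators rather than to the plate.

## Known limitations

Constant-rate synthesis understates late-course growth of nascent signal
in a growing embryo; the Tukey–Kramer step assumes homoscedastic groups
while multiplicative noise is heteroscedastic (the pooled MSE is then
dominated by high-copy groups, making early small rises conservative to
detect — visible in the detection lag of the demonstration panel); the
bridged-interval rule generalizes a procedure specified only for a single
two-step case; and stage labels are reporting metadata only. The 38-gene
annotation roster encodes the amphibian cluster complement; only the
within-cluster position ranks matter to any computation.
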