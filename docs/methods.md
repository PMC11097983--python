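# Methods

This note documents the models and procedures `cspot` implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical and design choices that were genuinely open.

## Stimulation protocol model

Stimulation trains are renewal processes with inter-stimulus intervals
drawn uniformly on `[T(1−j), T(1+j)]`, `T = 1/rate`, `j` the jitter
fraction. At the standard 0.5 Hz with 30% jitter every interval lies in
[1.4 s, 2.6 s]; the uniform family is an assumption — only the nominal
rate, the "30% jittered" description and the printed range constrain it,
and uniform bounds reproduce that range exactly. Blocks are fixed groups
of 120 consecutive stimulations. Condition structure is a per-block label
(`pre`, `drug`, `drug_light`, `pairing`, `post`, …); flashes are emitted
at `stim + flash_delay` (default +250 ms, 10 ms duration) in light-paired
epochs.

Default epoch counts: the third-series protocol uses 4 pre-drug + 4
post-drug + 4 post-drug-with-flash blocks (the latter 8 are the
average-baseline-response reference), then 3 gated pairing blocks
(collicular disinhibition lasts 10–20 min ≈ 3 blocks at 0.33 Hz) and 9
post-pairing blocks, ≈ 2.4 h of recording. These counts are the package's
choice within the protocol's stated structure; the classifier's scan
length (number of post-bicuculline blocks) matters for its false-positive
rate, see below.

## Generative channel model

A channel is multi-unit activity: a homogeneous Poisson background
(default 30 Hz, the spontaneous rate of the lidocaine-control recordings)
superposed independently with stimulus-locked components. Refractoriness
is deliberately ignored — multi-unit counts pool many units.

Each component emits `Poisson(probability × gain)` spikes per stimulation
at latency `L + N(0, σ) + Exp(τ)`, truncated at 0. The ex-Gaussian shape
(sharp rise, exponential decay) is the empirically right profile for
cortically-evoked multi-unit volleys: onset is set by the tight
monosynaptic volley, the falling phase by progressively recruited
polysynaptic activity. It is also load-bearing: with a symmetric latency
distribution, scaling a response up lengthens the supra-threshold run at
*both* ends, so response duration cannot grow while onset latency stays
put — the dissociation the analysis is expected to reproduce. Defaults:
a monosynaptic component at 7.5 ms (σ 0.6 ms, τ 2.5 ms, 0.4
spikes/stimulus) and a multisynaptic one at 18.5 ms (σ 1.5 ms, τ 4 ms,
0.25 spikes/stimulus), straddling the 12 ms mono/multi boundary.

Potentiation multiplies potentiable components by a gain (≥1) from a
per-channel onset block, ramping linearly over 4 blocks (timecourses of
the phenomenon grow gradually, and onsets vary by channel — the default
array model jitters onset by 0–2 blocks past the pairing start). A
potentiating channel may instead (or additionally) recruit a brand-new
component at a previously silent latency. A systemic drug scales every
component from the drug epoch onward. Per-channel ground truth
(potentiated flag, latencies, onset block) is recorded for recovery
testing.

What the simulator does **not** emulate: flash-evoked striatal spiking
(rarely observed in the preparation), local field potentials, waveform
realism beyond a single biphasic template (raw traces exist only to
exercise the threshold-extraction module), spike-sorting structure,
correlated noise across channels, and slow nonstationarity of the
background rate. Passing recovery tests therefore show the *analysis
logic* behaves as intended under the stated statistical structure — not
that real recordings are this well behaved; in particular real
across-block drift would inflate the reference SDs and make the 2 SD
peak rule more conservative than it is here.

## Analysis parameters

| parameter | default | meaning |
|---|---|---|
| bin width | 1 ms | PSTH resolution |
| window | −500…+100 ms | 500 ms spontaneous baseline + response headroom |
| response window | 0…50 ms | where evoked peaks are searched |
| evoked threshold | mean + 3 SD | over the block's 500 baseline bins |
| peak rule | mean + 2 SD | per-bin, across the 8 reference blocks |
| latency tolerance | ±2 ms | "similar latency" matching for peaks |
| run length | 5 (label `run7` at ≥7) | consecutive supporting blocks |
| veto scope | pre-drug blocks (1–4) | strict mode: all 12 pre-bicuculline |
| veto_min_run | 1 | pre-drug blocks that must carry a similar-latency peak to veto |

The SD in the evoked threshold is the population SD of the per-bin
baseline counts of that block's PSTH: the threshold is compared against
per-bin counts, so its dispersion must be per-bin dispersion (the
alternative — SD across stimulations of the mean — would be an SEM and
far too tight). Ties at the peak break to the earliest bin; onset/offset
are read as boundaries of the contiguous strictly-supra-threshold run
around the peak. Blocks without a detectable response contribute
magnitude 0 to the normalized series; normalization reports percent of
the pre-bicuculline mean (100 = no change), with percent-change available.

For potentiation calls, the candidate latency ranges over observed
post-bicuculline peak latencies; among qualifying candidates the longest
supporting run wins, earliest latency on ties. Duration pools distinct
peak bins across the supporting blocks (a per-block alternative was
considered; pooling matches the "number of bins over which a potentiated
response was observed" reading and is what `duration_bins` reports).
The two printed channel criteria differ only in run length as stated, so
they are implemented as one run-length rule whose label records whether
the run reached 7.

## Statistics

The drug-effect test compares pre-drug (blocks 1–4) with post-drug
baseline (blocks 5–12) per-channel per-block response values (adjusted
counts summed over the response window) in an additive two-way layout,
channels as blocks. F = MS(period)/MS(residual); its null distribution
comes from shuffling period labels among blocks independently within each
channel (the layout stays proportional, so period and channel effects
remain orthogonal and only the period sum of squares moves). The p-value
uses the add-one rule and so is never 0; a zero residual is reported as
degenerate with p = 1/(1+N). The external method the study cites for this
test is not reproduced in print; the scheme here is the closest standard
construction and is declared as such, not asserted to match it.

Proportions of potentiated channels use Pearson's chi-square on the 2×2
table, df = 1, no continuity correction by default (configurable).
Ordinary tests around these (Mann-Whitney, Wilcoxon, Kruskal-Wallis,
regression CIs) are delegated to scipy.

## Known limitation: calibration of the peak rule

The per-bin 2 SD rule is anti-conservative by construction. For a fresh
block drawn from the same distribution as the 8 reference blocks,
`P(x > mean + 2·popSD of 8)` is ≈ 6–7% *per bin* for essentially any
count distribution (a small-sample t₇-tail effect), not the ≈ 2.3% a
known-variance Gaussian would give. Worse, the SD estimate is fixed per
bin across all scanned blocks, so a bin with an unluckily small estimate
fires in many consecutive blocks: without the pre-drug veto, ≥5-block
spurious runs flag roughly a third of null channels. The veto suppresses
exactly this failure mode (the same bin also fires pre-drug), bringing
the null flag rate to ≈ 10% of channels under the default 24-block
protocol — but it equally vetoes genuine potentiation at latencies where
a single pre-drug bin happened to cross, capping sensitivity near 0.65
at gain 2 in the recovery experiments. These two numbers move together:
relaxing the veto (`veto_min_run=2`, requiring recurring pre-drug peaks)
raises sensitivity to ≈ 0.99 but the null flag rate to ≈ 36%. No setting
of the rule's stated parameters achieves both a ≤5% null flag rate and
≥0.9 sensitivity; a better-calibrated rule would need a t-corrected
threshold or more reference blocks, which would change the method. The
package implements the rule as defined and reports both operating points;
the acceptance suite records the resulting sensitivity and false-positive
rates without adjustment.

A smaller cousin of the same effect: with 1 ms bins at a 30 Hz background
(≈3.6 counts/bin over 120 stimulations), the evoked mean + 3 SD rule
crosses somewhere in the 50-bin response window in ≈ 15–20% of null
blocks. Spurious "responses" are single-bin and tiny, so the normalized
block series stays flat under the null (its regression slope CI covers
zero), but per-block detection flags should not be read as calibrated
5%-level decisions.

## Numerical choices

Bins are half-open `[lo, hi)`, 0-based, latencies are bin-start times
from stimulation onset. Latency binning adds a 10⁻⁶ ms nudge before
flooring so spikes generated exactly on a bin boundary are not pushed
into the lower bin by the float subtraction `spike − stim`. On-disk
times are seconds with six decimals; latencies in tables are ms. The
extraction module defaults to negative polarity, 4 SD, 0.5 ms dead time
(conventional multi-unit practice; the source recordings define the
threshold only as "determined over the baseline recordings"). Problem
sizes in the test and acceptance runs (20 seeds per recovery condition,
200 null replicates × 1000 permutations for the F-test calibration,
8-channel arrays for the period comparison) are chosen so the whole
verification cycle completes in minutes on one core while keeping
Monte-Carlo error well inside the asserted tolerances.
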