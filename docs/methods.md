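# Methods

This note documents the model behind each pipeline stage, the parameters
that matter, the synthetic data the test suite runs on, and the design
choices made where more than one reasonable option existed.

## Signal model and preprocessing

The input is a channels × samples voltage matrix from a probe whose
electrode coordinates are known in micrometres.  The pipeline assumes
additive, roughly stationary background noise per channel, spikes whose
per-channel amplitude decays with distance from the source, and an
absolute refractory period per neuron of at least ~1.5 ms.  Voltages are
used as stored: every threshold is data-derived, so the pipeline is
invariant to overall gain.

Preprocessing is a 3rd-order Butterworth bandpass, 300–3000 Hz, applied
forward-backward (`sosfiltfilt`).  Zero phase matters because peak
alignment downstream is phase sensitive; the filter order is a
compromise between rolloff and transient length and is configurable.
Recordings are resampled to a 14 kHz working rate (polyphase, 30 kHz
inputs become up = 7 / down = 15) — high enough to preserve waveform
shape for alignment, low enough to keep threshold scanning cheap.

## Detection

Noise scale: σ̂ₙ = median(|X|)/0.6745 per channel.  The denominator is
the standard-normal inverse CDF at 0.75, making σ̂ₙ equal to the true
standard deviation for Gaussian noise while the median keeps sparse
large spikes from inflating it (the plain standard deviation shifts >20 %
under 2 % contamination; σ̂ₙ shifts <5 %).  Threshold = *k*·σ̂ₙ, default
*k* = 4; values outside 3–5 trigger a warning.  A snippet of `wnd` = 3 ms
is cut wherever |x[i]| exceeds the threshold and is the maximum of a
window positioned so the peak sits at fraction *p* = 0.5; exact ties keep
the earliest index; windows overhanging the trace are dropped (documented
edge loss).  Detection is polarity-free (absolute value), per channel,
with each channel's own threshold.

## Grouping (divide-and-conquer)

Same-event membership is not observable directly, so it is defined
operationally: coincident (|Δt| ≤ 0.5 ms) snippets on neighboring
electrodes (distance < `thres_nb` = 40 µm) are candidates for being
copies of one spike.  Events are grown by *watershed claiming*: snippets
are visited strongest first, and an event claims candidates of
non-increasing amplitude, transitively.  Two amplitude local maxima —
two units firing together on nearby channels — therefore produce two
events rather than one, which a plain transitive closure would not.
Two refinements, both motivated by failure modes observed on synthetic
data:

- *Shape gate.*  A claim between comparable-amplitude snippets (weaker
  above 0.8× the stronger) additionally requires their peak-aligned,
  peak-normalized waveforms to correlate ≥ 0.8.  Spatial decay scales a
  spike but preserves its shape, so a comparable-amplitude coincident
  pair with clearly different shapes is two units, and suppressing one
  would silently delete a spike.  Clearly decayed copies skip the gate:
  near-threshold copies are too noisy for a reliable shape test, and a
  failed test would leave a duplicate event behind.
- *Wide window for weak copies.*  Copies at ≤ 0.5× the claimer may have
  their apparent peak displaced by noise well beyond 0.5 ms, so they are
  claimed over twice the coincidence window.

Only the largest-amplitude member of each event is retained (ties to the
lowest channel id); retained snippets are grouped by electrode.

## Clustering

Each group is clustered independently.  Features are the first two
principal components — the components that carry waveform variance above
the noise floor — computed on a 1.5 ms centre sub-window of each snippet
(the 3 ms snippet exists so pursuit has context; its flanks can carry
tails of *neighboring* spikes, which do not belong in the feature space).
Before PCA every waveform is re-anchored on its sinc-interpolated peak:
when a spike's true extremum falls between samples, discrete alignment
splits a unit into phase cohorts one sample apart, and a
sample-by-sample feature space would resolve the cohorts into two
clusters.

Clustering is HDBSCAN (scikit-learn implementation) on the
mutual-reachability transform, `min_cluster_size` = 10 and
`min_samples` = 5 by default.  The pipeline additionally floors the
cluster size at 2.5 % of the group, because in a busy group a few dozen
mutually similar collision-distorted waveforms can otherwise pass for a
unit.  Density-based clustering is used precisely because spike clouds
are not Gaussian and because collisions land in low-density regions:
those points are labeled −1 and recovered later, instead of corrupting
the clusters.  Groups smaller than the cluster-size floor are labeled
all-outlier rather than producing an unreliable template.

A cluster whose mean waveform does not clear 1.2× the channel threshold
is demoted to outliers: threshold-grazing noise snippets are mutually
similar (they are all aligned noise bumps) and cluster readily, but no
real unit's template sits that close to the detection threshold.  This
demotion is what makes lenient thresholds cheap — the extra detections
either match a template in pursuit or are discarded.

## Templates and merging

A cluster's template is the pointwise mean of its member waveforms, each
member re-anchored on its interpolated peak first (averaging straddled
anchors smears the spike).  The mean, not the median, keeps estimation
consistent with merging, which also averages.

Merging compares templates in one shared space: waveforms are
peak-normalized, aligned to a common reference template by full-waveform
cross-correlation (anchoring each template on its own peak fails when
two features compete for the peak), scaled by 1/√L so distances read as
per-sample RMS deviation relative to a unit-peak waveform, and projected
onto 3 principal components.  On this scale the default merge threshold
σ = 0.05 means "5 % average per-sample disagreement", independent of
window length and sampling rate; measured same-unit template pairs sit
at 0.01–0.03 and distinct units at 0.06–0.6, so the threshold falls in
the gap.  The low-dimensional projection suppresses estimation noise in
the comparison without touching genuine shape differences.

Two templates merge when they are closer than σ *and* their home
electrodes are identical or neighbors.  Because two different neurons
can genuinely have near-identical waveforms on neighboring electrodes,
two vetoes protect the merge:

- *Refractory consistency.*  Duplicates of one unit cannot fire within
  a refractory period of each other, so cross pairs at 0.3–1 ms (pairs
  below 0.3 ms are double detections, which merging is meant to fix)
  above 0.4 % of the smaller train indicate two independent units.  The
  threshold sits well below the naive 2·r·w expectation because
  duplicate suppression eats many of the coincidences.
- *Cross-channel amplitude consistency.*  Trigger-averaging one
  cluster's spike times on the other cluster's home channel recovers
  that unit's true mean amplitude there; one unit flapping between two
  electrodes shows near-full amplitude both ways, while two distinct
  units each see only the other's spatially decayed copy (≥ 50 % of the
  local template amplitude is required both ways).  Unlike the
  refractory test, this evidence survives duplicate suppression.

Candidate pairs are processed closest-first with the vetoes evaluated on
the growing components, so a small ambiguous cluster cannot bridge two
units the vetoes keep apart; merged waveforms are averaged after
cross-correlation re-registration, weighted by member-spike counts (a
5-spike spur must not drag a 500-spike template; the unweighted mean is
available).  Passes repeat until no pair merges, making the result a
fixed point — averaging denoises templates, so duplicates that start
just outside σ can become mergeable.

## Overlap resolution (pursuit)

Every outlier snippet is pursued on a segment of the filtered trace
around its peak (one extra window of context each side, so every lag in
the snippet window is admissible).  The match score is the normalized
cross-correlation — scale-free, maximal at a shape match — and a
candidate is accepted while the best score exceeds 0.8; a normalized
squared-difference metric is available behind a switch, with acceptance
1 − R > 0.8.  The accepted template is subtracted at its least-squares
amplitude β (unscaled subtraction leaves systematic residuals that
re-trigger matching; an unscaled mode exists) and the loop repeats until
the residual peak falls below `dtcTh` — set to the channel's detection
threshold, below which nothing resembles a spike — or the candidate is
rejected, or an iteration cap of 5 is hit (collisions of more than five
spikes in one window are out of scope; the result is flagged truncated,
not raised).

Two gates keep pursuit honest.  Matching is *spatially local*: an
outlier on channel c is matched only against templates homed on c or a
neighboring electrode — a spike cannot appear where its unit is not —
which also prevents two units with coincidentally similar waveforms at
opposite probe ends from stealing each other's spikes.  And a match is
*reported* only when β ∈ [0.6, 1.6]: templates carry absolute amplitude,
so a genuine occurrence fits near 1, while a shape-perfect fit at β ≈
0.4 is the decayed echo of a spike already claimed on a neighboring
channel (it is still subtracted so the pursuit can continue past it).

Recovered spikes join the clustered ones; pursuit spikes duplicating a
same-unit spike within half a window are dropped.

## Unit curation

A final check removes *shadow units*: walking units largest first, a
unit whose spikes coincide (±1 ms) with retained larger units' spikes
for more than 50 % of its train is a collision echo, not a neuron —
independent neurons at tens of hertz coincide for at most roughly 40 %
of their spikes even on a busy probe.  The check runs once on cluster
spike trains before pursuit and once on the final table (an echo whose
partners were themselves recovered by pursuit is invisible to the first
pass).

## The simulator

`htsort.simulate` generates the statistical structure the pipeline
assumes, with ground truth:

- *Probe*: deterministic linear or staggered two-column layouts,
  default pitch 25 µm.
- *Waveforms*: per unit, a randomized sum of alpha functions — optional
  positive pre-lobe (many real extracellular waveforms are triphasic),
  fast negative trough (τ 0.15–0.45 ms), slower positive lobe (τ
  0.4–0.7 ms) — tapered to zero at the window end.  Two constraints keep
  the shapes realistic *after* filtering: the randomized widths put the
  shape diversity inside the 300–3000 Hz analysis band, and the positive
  excursion is capped at 60 % of the trough as measured through the
  band (somatic extracellular spikes are trough-dominant; an
  early draft violated both properties and produced units no method
  could separate, or whose detection anchor flipped between lobes).
- *Spatial decay*: exponential with constant 30 µm, so a 25–40 µm pitch
  sees each spike on 2–4 channels; the best channel's peak is SNR·σ
  (SNR 10 by default).
- *Firing*: per-unit Poisson at 25 Hz (the spike density of typical
  dense-probe ground-truth benchmarks — about 750 spikes per unit in
  30 s) with a 2 ms absolute refractory period.
- *Collisions*: a configurable fraction of spikes is re-timed to land
  within half a spike width of another unit's spike; both partners are
  flagged in the ground truth.
- *Placement*: uniform over the probe footprint with a minimum
  separation, 25 µm by default.  End-to-end benchmark fixtures use
  40 µm (= `thres_nb`): a best-channel method cannot individually
  resolve units closer than the neighbor radius, so tighter placements
  measure the geometry, not the sorter.

Everything derives from one seed.  What the simulator deliberately does
not model: electrode drift, bursting amplitude attenuation, spatially
correlated noise, probe-specific filtering artifacts.  Passing tests on
this data therefore show the pipeline implements its model correctly
and resolves what its assumptions allow — not that real tissue, where
those effects exist, will sort equally well.

## Numerical choices and degenerate inputs

Peak localisation uses ×16 polyphase upsampling (the filtered signal is
band-limited well below Nyquist, so sinc interpolation is exact up to
noise).  All tie-breaks are deterministic: earliest index within a
detection window, lowest channel id for equal amplitudes, lowest
template id and earliest lag in matching.  Zero waveforms score 0 in
matching ("no evidence").  Empty traces, empty clusters and empty
libraries raise precondition errors; an empty detection result, a pure
noise recording, or zero outliers are valid and flow through.  Serial
evaluation everywhere: parallelism would be an execution hint only, and
identical output is the contract.

## Problem sizes in the test suite

The default suite simulates seconds-to-half-minute recordings on 4–32
channels with 2–10 units (the dense-probe benchmark is 32 channels ×
30 s × 10 units, run at two detection thresholds), which exercises every
stage at a few thousand to ~45 000 detected snippets per run and keeps
the whole suite around a minute.

## Known limitations

- Units closer than the neighbor radius with similar filtered waveforms
  are fundamentally entangled for a best-channel representation; the
  vetoes reduce, but cannot eliminate, confusions there.
- The merge threshold σ = 0.05 lives in this package's normalized
  per-sample space; other spaces would need retuning.
- Collisions of near-equal amplitude at near-zero lag on the same
  channel can fail the 0.8 acceptance score for either constituent and
  stay unresolved.
- No drift compensation: slow electrode movement will smear clusters
  and defeat the location prior.
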