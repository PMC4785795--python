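# Methods

## The analysis in brief

During quiet rest, hippocampal sharp-wave ripples (SWRs, 120–250 Hz LFP
transients) accompany reactivation of place-cell firing sequences.  The
pipeline implemented here links that reactivation to synaptic plasticity
at the Schaffer-collateral CA3→CA1 synapse in five stages:

1. **Ripple detection** — band-pass the LFP, extract the smoothed
   analytic-signal envelope, and threshold it in SD units.
2. **Place-field mapping** — occupancy-normalized rate maps and
   per-traversal rasters on a 200 × 10 cm linear track.
3. **SWR-locked spike statistics** — spikes per SWR, peri-SWR time
   histograms, population co-activity, SWR-restricted CA3×CA1
   cross-correlograms.
4. **Causal-pair classification** — the plasticity-potent event rule: a
   CA3 spike followed strictly < 30 ms later by a CA1 spike or burst,
   with the CA3 anchor between 0.3 × duration before and 0.6 × duration
   after an SWR onset; plus the spike-train edits (member removal,
   event isolation) used to test necessity and sufficiency.
5. **Plasticity quantification** — EPSC minute averaging, baseline
   normalization, paired test-vs-control comparison, and OLS r² of
   relative synaptic change against spike-train predictor counts.

A synthetic-session generator with stored ground truth stands in for
tetrode, trajectory and patch-clamp recordings, making every stage
testable end to end.

## Ripple detection

The raw LFP is filtered with a 4th-order Butterworth band-pass
(120–250 Hz) applied forward-backward (zero phase), so event boundaries
are not delayed by filter group delay.  The envelope is the magnitude
of the analytic signal (Hilbert transform), smoothed with a Gaussian
kernel of sigma `smooth_ms` (default 8 ms); without smoothing,
intra-ripple envelope troughs split single events.  Events are
excursions of the z-scored envelope above `detect_sd` (default 5);
boundaries extend outward to the nearest `bound_sd` (default 2)
crossings, linearly interpolated between samples.  Events closer than
`merge_ms` (20 ms) merge; events shorter than `min_dur_ms` (20 ms) are
dropped.  Both housekeeping defaults are configurable and echoed into
output file headers.

**Baseline statistics.** The envelope mean and SD that define the
z-score are estimated by default from the median and IQR
(sigma = IQR/1.349) of the whole-trace envelope.  Quantile estimation
matters: ripples occupy a few percent of samples at many SDs and
inflate moment-based estimates severalfold, which drags the 2-SD
boundary crossing well inside the true ripple onset.  Median/IQR is
insensitive to that contamination while avoiding the tail-truncation
bias of iterative exclusion.  Moment-based whole-trace estimation
remains available (`sd_estimation="whole"`).

Whether the 5-SD rule applies to the envelope or to squared power is a
genuine ambiguity; the envelope is the default here and the choice is
an explicit config decision.  The band default follows the 120–250 Hz
convention.

## Causal-pair classification

Burst detection groups maximal runs of ≥ 2 spikes with inter-spike
intervals ≤ `burst_isi_ms` (default 10 ms, the complex-spike-burst
range).  CA1 pairing candidates are burst onsets (carrying all member
spikes) plus lone spikes.  Classification is greedy left-to-right: CA3
anchors are visited in time order; each anchor inside some event's
fractional window takes the earliest unconsumed candidate strictly
within (0, 30) ms.  Greedy single-pairing prevents one CA1 spike from
being counted in two events and one CA3 spike from anchoring two
events; a burst straddling the lag boundary qualifies if its onset is
inside the window.  The window anchor is the presynaptic (CA3) spike —
it initiates the pairing — with a CA1-anchored variant available since
the verbal rule does not name the anchor.  An exhaustive O(n²)
nested-loop oracle implementing the same tie-break policy backs the
classifier in the test suite; the two agree exactly on hundreds of
random sessions.

Predictor counts: `n_pairs` is the number of classified events;
`n_ca3_burst_pairs` counts CA3 spikes followed < 30 ms by a CA1 burst
over the whole train (whether this count should be SWR-restricted is
ambiguous, so both variants are computed — `restrict_bursts_to_swr`);
`n_ca1_spikes` is the whole-train CA1 count.

## Synthetic sessions

The generator's defaults are the study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| LFP rate | 2 kHz | typical acquisition rate for ripple-band LFP |
| ripple rate | 0.19 /s | ≈ 57 events per 300 s rest epoch |
| ripple carrier | 150 Hz | center of the ripple band |
| ripple duration | 50–100 ms | typical SWR durations |
| ripple SNR | 8 peak-envelope SDs | clearly supra-threshold for a 5-SD rule |
| background | pink (1/f) noise | SD-threshold behavior depends on the background spectrum; 1/f is closer to hippocampal LFP than white (switchable) |
| units | 1 CA3 + 4 CA1 | the exemplar ensemble size |
| baseline spiking | 0.5 Hz Poisson | sparse pyramidal-cell rest firing |
| planted pairs | (8, 4, 2, 0) | spans the observed range; 8 is the strongest exemplar |
| pair lag | 5–25 ms | strictly inside the < 30 ms rule |
| pair phase | 0–0.5 of duration | inside the [−0.3, 0.6] window |

The ripple waveform is a Gaussian-windowed sinusoid with
sigma = duration/4, so its 2-sigma envelope point sits at the nominal
onset/offset stored as ground truth; amplitude is scaled so the peak
envelope is `ripple_snr` SDs of the band-passed background.  Ripples
keep a 0.3 s guard interval from each other and the session edges so
classification windows of distinct ripples never interact.

Each planted causal pair occupies its own ripple (a config requesting
more pairs than ripples is rejected as over-constrained): the CA3
partner spike is drawn in the fractional window, the CA1 spike at a lag
inside (0, 30) ms, and both ride on independent Poisson background.
With background rate zero, classification provably returns exactly the
planted pairs — the plant-and-recover oracle the tests rely on.
Randomness comes from one master seed via spawned substreams, so
identical seeds give bit-identical sessions.

Track sessions use a constant-speed triangular sweep (20 cm/s, 50 Hz
sampling, optional position jitter) and inhomogeneous-Poisson place
cells (Gaussian tuning, default sigma 10 cm, peak 10 Hz) sampled by
thinning.  EPSC series place sweeps every 10 s (six per minute), with
post-induction amplitude rising along a logistic curve (half-rise 7 min,
tau 2 min — "slow LTP", saturated well before the 25–30 min comparison
window) toward `true_factor` × baseline, with multiplicative Gaussian
noise of the stated CV.

**What the generator does not emulate:** replay sequence content beyond
pair timing, biophysical membrane dynamics, theta-band structure,
electrode drift, spike-sorting contamination.  Passing tests therefore
demonstrate correctness of the analysis logic under the stated
statistical structure, not robustness to every pathology of real
recordings.

## Place maps and trial segmentation

Rates are occupancy-normalized (spikes per second in each 10 cm bin);
bins never visited carry NaN rather than zero.  Spike positions are
linearly interpolated at spike times; trajectory gaps > 0.5 s are
excluded from occupancy.  Trials are maximal monotone traversals
covering ≥ 80 % of the track, delimited by position extrema with
prominence of half the track length (robust to sampling jitter).  The
80 % threshold is a configurable housekeeping choice.  Maps are
unsmoothed by default with an optional Gaussian smoothing flag.

## Spike statistics conventions

All histograms use half-open bins [lo, hi); a spike exactly on an edge
belongs to the later bin.  Cross-correlogram lag sign: positive = CA1
after CA3.  The correlogram normalizer is the number of CA1 spikes
inside SWR event intervals; the restriction window (−50 ms to +150 ms
around onset) applies to both trains by default, with a flag to
restrict CA1 only — the original description is ambiguous on both
points.

## Plasticity quantification

Minute averages take consecutive non-overlapping groups of six sweeps
(a partial trailing group is dropped).  Normalization divides by the
mean of the 5 min pre-induction baseline; the induction time is
explicit metadata, never inferred.  The pathway comparison takes
per-experiment means over a 25–30 min post-induction window, applies a
paired two-tailed t-test across experiments (biological replicates, not
sweeps), and reports relative change = mean(test) − mean(control).  The
"final 5 min" window and the 25–30 min comparison window are treated as
the same (configurable) window.  Identical pathways yield p = 1 by
convention (the paired difference has zero variance).  Series-resistance
QC fails a recording if any sweep deviates > 20 % from its initial
value.  r² comes from ordinary least squares of change on predictor
count; the fit uses whatever (change, count) points it is given and
reports n alongside.

## Stimulation protocols

Replay protocols copy CA3 spike times to the EPSP channel and CA1 spike
times to the somatic AP channel (2 ms / 2 nA pulses) within a 300 s
induction epoch, preserving absolute in vivo times; the ripple pathway
receives a five-pulse 100 Hz train per SWR onset — omitted in `without`
mode, shifted −100 ms in `offset_100ms_early` mode.  Artificial pairing
protocols repeat 300 times at 5 Hz (60 s): EPSP then AP 10 ms later,
optionally delayed 13 or 53 ms after a ripple-pathway train, or EPSP
alone.  The sine-wave command traces one full cycle per SWR spanning
[onset, offset] at ±100 pA — "peak and valley" implies both extremes
occur, hence one complete cycle, phase starting at zero (rising);
cycle count is configurable.  Schedules are event lists; only the sine
command is a sampled waveform (default 10 kHz).  The constant −60 mV
holding variant is a protocol metadata flag.

## Verification problem sizes

The test suite and the acceptance script size their simulations as
follows, as the package's own verification design: detector quality on
a 200 s, 2 kHz session at 0.4 events/s and SNR 8; classifier-vs-oracle
agreement on 500 random sessions of ≤ ~200 spikes; offset sensitivity
on 100 s sessions with 20 planted early-phase pairs; end-to-end
recovery over 100 repeats of 8 sessions (60 s, 1 kHz) with planted pair
counts 0–8 and outcome change = 0.25 × count + N(0, 0.1²), whose
population r² = a²·Var(k)/(a²·Var(k) + σ²) ≈ 0.979 is the analytic
reference for the fitted value.

## Known limitations

- Detection quality figures hold at the generator's SNR regime; real
  recordings with EMG artifacts or state transitions need the
  configurable thresholds revisited and manual verification.
- The classifier assumes non-overlapping ripples (enforced upstream by
  merging) and rejects overlap rather than resolving phase ambiguity.
- Spike-train editing matches member times exactly; edits must be
  derived from the same train object or identically written files.
- No LTD scoring, replay-order decoding, sleep staging, or multi-channel
  consensus detection.
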