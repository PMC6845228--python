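# Methods

This note documents the models and procedures implemented in `cspk`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Task and data model

One session is a sequence of trials on a shared clock: a 100 ms visual cue,
reward delivery 600 ms after cue onset, and inter-trial intervals drawn
uniformly from 24–30 s. A configurable fraction (default 20%) of trials are
special: on *omission* trials the cue appears but no reward is delivered;
on *unexpected-reward* trials the reward arrives without a cue. Special
trials keep their nominal slot in the timeline so reward-aligned analyses
remain well defined. The number of special trials is `round(fraction · n)`,
positions drawn without replacement, so counts are reproducible.

All analysis windows use one global bound convention: lower bound
exclusive, upper bound inclusive. Frame *k* of a recording corresponds to
time *k/frame_rate*.

## Synthetic sessions

The generator plants every quantity the downstream analysis estimates.

**Licking.** On non-miss cue trials a lick bout begins at cue onset plus a
truncated-normal reaction-time draw; bouts contain 3 + Poisson(3) licks at
80–140 ms intervals, so the first three licks always fall within 300 ms
(the bout definition used by the analysis). Stage presets: naive, mean RT
0.74 s (SD 0.12), miss probability 0.39; trained, 0.54 s (SD 0.08), miss
probability 0.03 — chosen to match the behavioral change this task
produces across learning. Isolated licks are also emitted during the ITI
at a configurable Poisson rate (default 0.1 Hz), which feeds the
lick-triggered-average analysis.

**Cspk event trains.** Per-dendrite events are an inhomogeneous Poisson
process, sampled by thinning: a baseline rate (default 0.6 Hz, the typical
climbing-fiber order of magnitude; the true value is not known a priori
and is configurable) plus trial-locked rate bumps. A bump has an
alignment (cue, reward, or each lick), a centre, a duration (Gaussian
shape with sigma = duration/4, or boxcar), and an amplitude in Hz.
Regime presets encode the area-specific response structure:

| regime | bumps (align, peak, amp) |
| --- | --- |
| `LS_naive` | reward +200 ms, 3 Hz, rewarded & unexpected-reward trials |
| `LS_trained` | cue +380 ms, 3 Hz, rewarded & omission; reward +200 ms, 3 Hz, unexpected only |
| `CrusI_naive` | cue +230 ms, 1.5 Hz |
| `CrusI_trained` | cue +230 ms, 3 Hz; reward +200 ms, 2.5 Hz, unexpected only |
| `CrusII_naive` | reward +200 ms, 2.5 Hz; lick-locked 1 Hz |
| `CrusII_trained` | cue +300 ms, 3 Hz; reward +150 ms, 2 Hz (persistent) |

Peak times follow the response latencies characteristic of each area
(~800 ms post-cue reward responses in naive lobule simplex, ~380 ms
cue-locked responses after training, ~230/300 ms in Crus I/II). A
configurable fraction of dendrites (default 25%) is non-responsive
(baseline only).

**Fluorescence.** A Cspk transient is a difference of exponentials (rise
0.05 s, decay 0.18 s, unit peak), GCaMP6f-like; amplitudes are lognormal
with sigma 0.35 in log units — transients of variable amplitude, as
climbing-fiber-driven dendritic signals are. Traces are baseline +
superposition of transients + white Gaussian noise and are exactly linear
in the events.

**SNR convention.** `SessionConfig.snr` is the transient amplitude divided
by the **per-pixel** imaging-noise SD; it parameterises movie rendering.
A dendrite trace averaged over a K-pixel mask therefore carries an
effective trace-level SNR of about snr·√K (≈ 12× for the default ~140-px
masks). Trace-only workflows use `synth.trace_noise_sd(snr, mask_area)`
to reproduce that noise level without rendering a movie. This matters for
event detection (below): a 1.7 SD threshold on white noise at trace-level
SNR 5 would be swamped by false positives; at realistic mask-averaged
SNRs it is not.

**Field of view and movies.** Dendrites are elongated rotated ellipses
(default 40 × 4.5 px, aspect ≈ 9, ±10° orientation jitter), placed without
overlap, mirroring the parasagittally elongated appearance of Purkinje
dendrites in these recordings. Movies are the mask-weighted sum of traces
plus background, optionally translated per frame (sub-pixel, linear
interpolation) and overlaid with white pixel noise. The generator does
**not** model the optics (PSF, photon shot noise), z-motion, somata,
neuropil contamination, or slow drift — so passing tests demonstrate the
correctness of the analysis logic on data obeying its assumptions, not
robustness to every artifact of real recordings.

**Piezo.** A breathing sinusoid (3 Hz) plus randomly timed enveloped-noise
movement bursts; bursts can be planted in specific trials' pre-reward
windows to give movement-segregation analyses a ground truth.

## Analysis procedures

**Registration.** Phase correlation with upsampled refinement (default
1/20 px) between each frame and a reference; frames are moved by the
negated estimated shift with linear interpolation, edges filled with the
frame median. Equal correlation peaks resolve to the smallest shift.
Planted shifts up to ±10 px are recovered to well under 0.25 px on
textured images; accuracy degrades only with featureless frames, which
raise a degenerate-input error instead.

**ΔF/F.** Per trial, F₀ is the mean fluorescence in a pre-cue window:
(−0.9, −0.2] s at 10 Hz (mesoscale), (−0.5, −0.1] s at 30 Hz. "Trial
initiation" is taken to be cue onset. Mesoscale latency is the time of the
maximum one-frame forward difference within 500 ms before the post-cue
ΔF/F peak, with the difference between frames k and k+1 assigned to frame
k+1 so a step lands on the step time. The measure is invariant to offset
and positive scaling.

**Segmentation.** The movie (frames × pixels) is reduced by randomized,
seeded PCA; the retained orthonormal eigenimages are unmixed into
*spatially* independent components by maximizing the quartic (kurtosis)
ICA contrast over pixels under an orthogonal unmixing matrix, solved with
the classical SVD fixed-point rotation. This deterministic solver was
chosen after the stochastic parallel FastICA iteration proved unreliable
here: with surplus components the Gaussian noise subspace prevents
convergence and frequently leaves dendrites mixed, whereas the rotation
solver separates disjoint sparse sources essentially always. Surplus
components simply absorb noise and die during mask building. Each filter
is smoothed (Gaussian, 1 px), thresholded at mean + 2 SD, restricted to
pixels whose time-courses correlate > 0.8 with the candidate region's
mean time-course, and stripped of pixels claimed by more than one filter;
masks under 5 px are dropped. An optional compactness filter
(area/perimeter² threshold) can reject soma-like round regions; it is off
by default.

**Event detection.** d[t] = F[t+1] − F[t]; threshold = mean +
1.7 SD of d over the baseline frames, where the baseline is all ITI
frames (outside cue → reward + 1 s windows). One event is recorded at the
first frame of each maximal suprathreshold run; events separated by at
least one sub-threshold frame count separately, so consecutive event
frames always differ by ≥ 2. Detection runs on raw fluorescence — the rule
is invariant to offset and positive scaling, so ΔF/F adds nothing. The
baseline SD deliberately includes ITI event transients: with clearly
resolved transients this lifts the threshold far above the noise floor,
which is what makes the permissive 1.7 SD multiplier workable. On pure
noise the rule fires at P(Z > 1.7) ≈ 4.5% of frames (slightly corrected
by run-merging with the −0.5 lag-one correlation of differenced noise);
this is a property of the rule itself and is verified against an
independent Monte-Carlo implementation. A fully constant trace has zero
baseline variance and raises a degenerate-baseline error rather than
returning "no events".

**PSTHs and window statistics.** Events are binned at the frame rate into
binary trial × relative-frame rasters (an event at time t maps to relative
frame ⌊(t − t_align)·rate⌋). Per-dendrite rate = trial-mean indicator ÷ bin
width; the population PSTH is the mean ± SEM **across dendrites**. The
pre-reward window is the 600 ms between cue and reward; the post-reward
window the 600 ms after (expected) reward. Window rates are means over the
100 ms window centred on the population-PSTH peak bin (ties to the earliest
bin; the window is clipped at the analysis-window edge, not shifted). The
population test is a paired one-tailed t-test of those rates against rates
at a peak found the same way in a 1200 ms pre-cue baseline window.
All-zero differences are flagged degenerate rather than assigned a
p-value. No multiple-comparison correction is applied anywhere.

Because events are quantized to frame starts before binning, a planted
continuous-time bump peak is read out with an average half-frame (~17 ms
at 30 Hz) lag; latency recovery is therefore accurate to one bin, not
better, by construction.

**Calibration caveat (measured, not assumed).** Under a pure null
(homogeneous 0.6 Hz trains, 50 dendrites × 100 trials), the
peak-vs-baseline population test rejects at α = 0.05 in only ~1–2% of
seeded runs, not 5%: the baseline peak is a maximum over a window twice as
wide as the response window, and both peaks are selected on the shared
population mean, which couples dendrites. A continuous-Gaussian analogue
reproduces the effect, so it is selection-induced, not a discreteness
artifact. The procedure is implemented exactly as defined; users should
read its p-values as conservative under the null. The acceptance script
reports the measured null rate (`population_test_type_i_rate`).

**Classifiers.** Responsive: ≥ 2 consecutive bins in the pre- or
post-reward window above the dendrite's pre-cue mean + 1 SD (both over its
pre-cue bins). Suppressed: ≥ 2 consecutive post-reward bins below both the
pre-cue and the pre-reward mean − 1 SD. Classification uses unsmoothed
frame-rate bins. The responsive rule is monotone: adding uniform rate in
the window can never un-flag a dendrite.

**Lick-triggered averages.** Only single ITI licks ≥ 250 ms from their
neighbours qualify; sessions with fewer than four such licks are excluded
(a distinct signal, not a p-value). The peak is sought within the five
frames centred on the lick and compared, paired across dendrites and
one-tailed, with the mean of the two frames 250 ms before and the two
frames 250 ms after.

**Trial segregation.** Lick-latency quartiles use the first lick-bout
onset (≥ 3 licks within 300 ms of the first); lick-rate quartiles use
licks in the 1 s following reward delivery (the comparison window is not
pinned down by the task definition; 1 s is configurable); movement uses
piezo RMS in the pre-reward window, top/bottom deciles. Ties resolve by
trial index; the subsets partition the trials with a defined metric.

**Tracking.** The post-session mean image is registered to the
pre-session one; the integer-rounded shift is applied to the post-session
masks (binary masks cannot be sub-pixel shifted without resampling);
pixels leaving the image are dropped. Overlap = |a ∩ b| / min(|a|, |b|) —
the most permissive symmetric reading of "percent overlap"; Jaccard and
pre-mask-fraction denominators are available in the code. Pairs above 50%
are resolved greedily by descending overlap, ties by id, which makes the
matching independent of input order. Note that a criterion on
min-denominator overlap tolerates shifts along a dendrite's long axis far
better than across it: a 2 px cross-axis displacement of a 4.5 px-wide
mask legitimately fails the 50% criterion.

## Problem sizes used in validation

The test suite and acceptance script run on one CPU in minutes; sizes were
chosen to give each property adequate statistical resolution at desk
scale: detection fidelity on 60–100 dendrites × 300 s; registration on 50
planted shifts; segmentation on a 132 × 398 px field with 16 dendrites and
1500 frames (the same dendrite density and pixel SNR as a full-size
264 × 796/30-dendrite field); null calibration on 200–400 seeded runs of
50 dendrites × 100 trials; latency recovery on 100 dendrites × 150 trials;
the end-to-end movie demo on two 40-trial sessions with a shortened 4–6 s
ITI (full 24–30 s ITIs at 30 Hz produce ~80k-frame movies; ITI length
enters no trial-relative statistic, only the amount of baseline footage).

## Known limitations

- The generator's baseline Cspk rate, transient kinetics, and bump
  amplitudes are field-plausible defaults, not fitted values; regime
  presets encode qualitative response structure, not empirical magnitudes.
- Registration is rigid-translation only; no non-rigid warping or z-motion
  handling.
- Segmentation assumes spatially disjoint, temporally active sources;
  heavily overlapping dendrites would require constrained factorization
  approaches that are out of scope.
- The suppression classifier is implemented and tested on planted pauses,
  but the generator's regimes plant no suppression, mirroring the absence
  of negative-going responses in this preparation.
- Tracking handles exactly two sessions and one global rigid shift.
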