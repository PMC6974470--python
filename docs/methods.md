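# Methods

## Signal model and scope

The package targets chronic intramuscular EMG from the tibialis anterior
(TA, ankle flexor) and soleus (Sol, ankle extensor) of both hind limbs in
spinal rats moving freely in a cage, sampled at 10 kHz, optionally under
continuous sub-threshold 40 Hz epidural stimulation (0.2 ms pulses).
Analysis is strictly offline: every filter is applied forward-backward
(zero phase), because step timing — peak times, zero crossings, cycle
boundaries — feeds directly into downstream epoching and any phase lag
would bias it. Recordings are processed in 10-minute segments; a trailing
partial segment is kept rather than dropped.

## Conditioning

Band-pass: 3rd-order Butterworth, 30–1000 Hz. The Teager–Kaiser energy
operator ψ[n] = x[n]² − x[n−1]·x[n+1] converts the band-passed trace to an
instantaneous-energy estimate (for a sinusoid, A²·sin²Ω), which sharpens
burst onsets relative to plain rectification. Endpoints of ψ replicate the
nearest interior value so length is preserved (configurable policy).
The rectified energy is smoothed with a zero-phase 50 Hz Butterworth
low-pass; the low-pass order is not dictated by the operator and is set to
3 to match the band-pass. Small negative filter ripple is clipped to zero.
Because the TKEO is quadratic, the envelope scales as k² under a channel
gain k; every downstream threshold is built from statistics of the same
envelope, so detection is gain-invariant by construction (verified to the
sample in the test suite).

Smoothing acts on the TKEO output itself, not its square root; the
envelope is therefore on an energy (mV²) scale. Only ratios of envelope
values matter downstream, so the scale convention is free.

## Rest discovery and double thresholding

Each channel envelope is cut into 10 s bins. Within a bin:

1. Non-overlapping 10 ms block means are computed.
2. The minimum-mean block seeds the rest window (earliest block on ties,
   for determinism).
3. The window grows outward (alternating right/left attempts), admitting a
   neighbouring block while two criteria hold:
   * **Differential:** |Δ block mean| per second, measured relative to the
     seed block mean (the bin's rest floor), stays ≤ `dmax` = 1000/s —
     i.e. an edge block jumping by more than ten rest floors within one
     10 ms block step is treated as activity. Expressing the criterion
     relative to the rest floor rather than as an absolute mV/s rate makes
     rest discovery independent of amplifier gain; an absolute rate is
     inherently tied to one recording setup's gain. On band-limited-noise
     envelopes the rest-bin differentials stay below ~500/s while activity
     edges exceed ~2000/s, so the default sits between the two regimes.
   * **Log ramp:** the running sum of ln(1 + max(0, m_block − m_seed)/m_seed)
     over admitted blocks stays below `log_thresh` = 300. The differential
     criterion is blind to slow monotone ramps whose per-block change is
     small; the log sum accumulates along such ramps and stops growth.
     A flat bin accumulates zero, so a quiet bin is all rest. The exact
     functional form of a log-ramp stop rule is an open design point; this
     one is deliberately simple, dimensionless (gain-free), and can be
     disabled (`log_thresh: null`).
4. μ_rest and σ_rest are computed from the raw envelope samples inside the
   grown window (not from block means).

The magnitude threshold is μ_rest + J·σ_rest with J = 7. A burst is a
maximal supra-threshold run lasting at least 0.1 s (TA) or 0.3 s (Sol) —
the double (magnitude + time) criterion. Runs crossing a 10 s bin boundary
are judged against each bin's own magnitude threshold sample-wise and
against the duration criterion as one union run, so a single physiological
burst is never split into two sub-criterion fragments. A trailing partial
bin shorter than 2 s inherits the previous bin's threshold instead of
estimating statistics from too little data.

## Step registration

TA and Sol envelopes are normalized each by its own maximum over the
10-minute segment (an all-zero channel maps to zero). The normalization
scope is a deliberate choice: per-segment keeps memory bounded and matches
the processing unit; per-bin and global are possible alternatives but were
not adopted. The relative difference (normalized TA − normalized Sol) is
bounded in [−1, 1]; positive values are read as net flexion, negative as
net extension. "Negative" is strict (diff < 0); zero is neither phase.

A candidate peak must be a positive local maximum, above the 0.01
difference threshold, inside an active TA burst, and at least 0.2 s after
the previously accepted candidate (the separation rule is applied at the
candidate level, then the last surviving candidate per TA burst is kept,
so each flexor burst yields at most one step). The candidate becomes a
step iff the difference turns negative within 0.5 s and that negative
phase overlaps — by at least one sample — a Sol burst lasting ≥ 0.25 s.
The cycle window runs from the last non-positive sample at or before the
peak (clamped to the segment start, with a warning, if the signal is
positive from the outset) to whichever comes first of the difference
returning to ≥ 0 or the end of the overlapping extensor burst. Limbs are
processed independently; no interlimb coupling is imposed.

Aggregates: steps per 1-minute bin, per-event stance period (stance end −
zero crossing), cumulative trapezoidal IEMG per channel normalized to
[0, 1] over the recording, and percent change in step count against a
reference (pre-intervention) count, reported as missing when the reference
is zero.

## Evoked-potential (MEP) analysis

Epochs of 25 ms (250 samples at 10 kHz) are cut from the band-passed
signal — never the energy envelope — starting at the end of each
stimulation pulse, and kept only when the whole epoch lies inside a
detected step cycle (all epochs, flagged, when no steps are supplied).
Early/middle/late response windows are 1–4, 4–7 and 7–25 ms; deflections
before 1 ms are treated as stimulation artifact and never counted.

Extrema detection: the epoch is resampled to twice the number of points
(piecewise cubic; linear available), local maxima/minima are found with a
minimum separation of 0.6 ms and minimum prominence of 0.2 mV, and only
extrema whose central second difference on the interpolated grid reaches
1.5×10⁶ mV/s² in magnitude are retained — the curvature floor rejects slow
baseline undulations that survive the prominence test. The curvature
constant is sampling-dependent, so the configuration stores the rate it
assumes (10 kHz) and rescales it by (rate/assumed)² with a warning when
the data rate differs.

Per-epoch features: IEMG over the middle and late windows as the
rectified-area rectangle sum |x|·Δt on half-open sample windows (mV·ms) —
with this convention middle + late IEMG equals the IEMG of their 4–25 ms
union exactly — plus whole-epoch peak-to-peak, and per-window counts of
retained peaks (troughs are tallied separately, not folded into the peak
counts). Treatment summaries report total middle/late peak counts as a
ratio to a reference condition; zero-reference ratios are reported as
missing rather than 0 or infinity.

## Validation

Matching is greedy and chronological: each detection pairs with the
earliest unmatched annotated step whose interval overlaps the detection's
cycle window or whose onset lies within 0.5 s (the detector's follow
window; configurable) of the detection's zero crossing. Each annotation is
consumed at most once. True negatives are annotated non-functional events
containing no detection. Accuracy is (tp + tn) over the sampled events,
precision tp/(tp+fp), recall tp/(tp+fn); undefined 0/0 ratios are returned
as missing, never silently as 0 or 1.

## Synthetic data

The generator emulates the structure the detector relies on, not muscle
physiology: EMG bursts are amplitude-modulated band-limited (30–400 Hz)
Gaussian noise with raised-cosine edges — a standard interference-pattern
surrogate — on a Gaussian rest baseline. TA channels burst during swing
(0.4 s default), Sol during stance (2.0 s default, the typical stance of
slow spontaneous stepping in this preparation); both sides share the step
schedule with independent noise. Default burst amplitude is 1.0 mV against
0.1 mV rest noise (SNR 10). Bout onsets are drawn from a truncated
exponentially decaying intensity (half-life default 7200 s), mirroring the
decline of drug-enabled activity over a session, and pushed apart by a
minimum 4 s gap; a schedule that outruns the recording is truncated with a
warning. Stimulation adds a rectangular pulse artifact plus a scaled
evoked-response template of well-separated Gaussian lobes whose extremum
times, amplitudes, and curvature (|amp|/width²) are known analytically, so
the expected outcome of every extrema filter can be predicted
generator-side. A fixed seed reproduces the sample path bit-for-bit.

What the generator does not model — motor-unit structure, electrode drift,
movement artifact, crosstalk between muscles, co-contraction, amplitude
non-stationarity within a burst — bounds what passing tests show: they
demonstrate correctness of the detection logic under the stated noise
model, not field performance on animal recordings.

## Problem sizes and numerical choices

The end-to-end checks run a 10-minute synthetic recording (600 s, 4
channels at 10 kHz, 22 bouts × 5 steps = 220 scheduled step events per
side pair) — large enough for stable event-level rates while keeping the
full suite fast. Event-level recall and precision on this recording are
≥ 0.85 by test contract (measured ≈ 0.93–0.99 across seeds), and a ×3.7
gain applied to all raw channels moves no detected event time by even one
sample. Ties in rest-seed selection go to the earliest block; burst
intervals are half-open [start, end) in seconds from recording start;
pulse end times are the end of the last supra-threshold sample period,
with runs separated by a single sub-threshold sample merged.

## Known limitations

* The log-ramp stopping rule is one reasonable formalisation of an
  under-specified criterion; its constant (300) is exposed and the rule
  can be disabled.
* Accuracy depends on the true-negative convention; with annotation logs
  that do not enumerate non-functional events, precision and recall are
  the meaningful scores.
* Standing and other non-step activity is not classified; bursts that
  register no step are simply absent from the event log.
* No notch filtering or stimulation-artifact blanking is applied inside
  the envelope path; very large stimulation artifacts would inflate rest
  statistics.
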