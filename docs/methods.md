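# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hfokit`. It is written for users who need to judge what the
package's validated behavior does and does not imply about real recordings.

## Signal model and containers

All analysis operates on a `Recording`: a channels × samples matrix of
local field potentials in microvolts at a single sampling rate (the study
protocol records 16 SEEG channels at 4 000 Hz). Sample indexing is 0-based
and intervals are half-open `[start, end)`; channel display names keep the
clinical 1-based convention ("ch01"…"ch16"). The bilateral montage places
channels 1–3 / 9–11 in the hippocampus and 4–6 / 12–14 in sensorimotor
cortex; the two rearmost contacts of each electrode usually remain outside
the brain and are flagged as bad channels. Bad channels are retained in
files but excluded from every statistic, never interpolated — removal, not
repair, is the contract. Artifact masks are per-channel interval unions;
masked samples never enter threshold statistics, detector outputs, or rate
denominators.

EDF output is 16-bit with a symmetric physical range of ±3276.7 µV by
default, i.e. a quantization step of 0.1 µV; amplitudes outside the range
raise rather than clip. Artifact masks serialize as EDF+ annotations with
an `ARTIFACT ch=<n>` label and as a sidecar CSV. Plain EDF is read without
masks. Multi-rate EDF dialects are rejected: one rate per recording keeps
every downstream index exact.

## Multitaper spectral analysis

The spectrogram uses discrete prolate spheroidal (Slepian) tapers with
time–bandwidth product NW = 4 and m = 7 tapers (the 2NW−1 rule), 30 s
windows and 1 s steps. Each window's power column is computed literally as

    P_i = (1/m) Σ_j  z ∘ z̄ ,   z = 2 · fft(d_i · T_j) / n ,

keeping only frequencies in [0, fs/2]. The factor 2 is applied to every
bin, including DC and Nyquist; this one-sided convention is reproduced
as written rather than made Parseval-exact, and all internal consumers are
consistent with it. Tapers are unit-norm and mutually orthogonal (symmetric
DPSS; the Gram matrix is identity to machine precision). The effective
spectral resolution is the taper half-bandwidth NW/T ≈ 0.13 Hz at T = 30 s;
a pure tone concentrates > 99% of its power within that bandwidth.

PSDs are multitaper estimates averaged over non-overlapping windows
(Welch-style); windows overlapping an artifact mask are dropped entirely
rather than partially weighted — the simplest contract consistent with
artifact *removal*.

Recording quality is screened by ordinary least squares of log10(power) on
log10(frequency) over 0.5–100 Hz, excluding 48–52 Hz around the mains
notch and any non-positive bins. A channel passes when slope < 0 and
R² ≥ 0.8. The threshold is configurable; 0.8 operationalizes "near-linear"
and accepts the generator's physiological spectra (slope ≈ −1.5 with
narrow-band peaks superimposed) while rejecting white noise. The screen is
a spot check on a selected epoch (default 60 s), matching how quality is
reviewed in practice, not a whole-session statistic.

## Detectors

All three detectors use zero-phase (forward–backward) order-4 Butterworth
band-passes, preserving event timing. Internally the IED and seizure paths
decimate to ~400 Hz and ~125 Hz respectively (polyphase resampling): their
bands end at 80 Hz and 25 Hz, so the decimation is lossless for the
decision variable and keeps long sessions cheap.

**IED.** Band-pass 25–80 Hz; detection statistic is the magnitude of the
analytic (Hilbert) envelope. The threshold is "two times the baseline",
where *baseline* is defined as the ongoing background amplitude: the median
over 1 s windows of the per-window envelope maximum, computed on
artifact-free data. This robust peak-level statistic (≈ 2.8 Gaussian SD for
the band) makes the 2× rule selective; a threshold placed at twice the
envelope's *scale* parameter instead would sit near 2 SD, where the Rice
crossing rate of a 25–80 Hz envelope is several excursions per second and
any spike detector would drown in false positives. Events within 1 s of an
accepted event are discarded (greedy, earliest-first), so runs of spikes
count once; the minimum inter-onset interval of the output is therefore
≥ 1 s by construction.

**Seizure.** The signal is denoised by a Morlet continuous wavelet
transform over 32 log-spaced scales covering 1–25 Hz with per-scale soft
thresholds at 2 × the scale-wise MAD, reconstructed by the log-scale Morlet
summation (amplitude is recovered up to a constant, which cancels in the
relative threshold). Seizure energy is the sliding 1 s sum of squares of
the 1–25 Hz signal; the dynamic threshold is a rolling (5 min) mean + 2 SD.
Energy samples above the channel's global median + 5 MAD-SD are capped
before the rolling statistics so an event does not raise its own threshold
— without this, a 30 s discharge inflates the local SD and the crossing
points migrate into the event, costing seconds of onset accuracy. Events
must last ≥ 10 s (the generator draws seizure durations from 12–45 s, the
observed range; the margin keeps IED runs from being called seizures). Each
event carries a histogram of instantaneous peak frequencies (1–25 Hz, 24
bins) of the discharge. Recordings shorter than the rolling context fall
back to global statistics with a warning.

**HFO.** Band-pass 100–500 Hz at the native rate; root-mean-square in a
centered 3 ms window; candidates are runs of successive RMS values above
the channel mean + 5 SD. Candidates closer than 10 ms merge (the
convention of the original RMS ripple detector); merged candidates must
still contain a contiguous supra-threshold run of ≥ 6 ms. Surviving events
need ≥ 6 rectified-signal peaks above mean + 3 SD, counted with strict
local maxima (plateaus count once) over the event padded by 15 ms on each
side — the oscillation extends beyond the supra-RMS core, and counting
only inside the run would reject genuine ripples whose run spans ~2–3
cycles. RMS and rectified statistics are computed per channel per session
over unmasked samples, excluding detected seizure intervals, so reported
HFOs and their thresholds are interictal. Each event is annotated with its
peak frequency (zero-padded FFT of the band-passed segment, ≤ 2 Hz bins).
Sampling rates below 1 kHz are rejected; the band is clipped to 0.9 × fs/2
with a warning when 500 Hz is unreachable.

Event rates are counts divided by analyzable minutes (masked time
excluded).

## Rates, group statistics, reliability

Weekly rates pool sessions within an animal-week: Σ events / Σ analyzable
minutes. Group comparisons use one-way ANOVA plus two-sample *t*-tests —
pooled-variance by default (consistent with the ANOVA; Welch optional) —
with Bonferroni correction over each reported family and group means ± SEM.

Test–retest reliability treats each post-insult week as one test, giving an
n × 4 matrix of weekly hippocampal HFO rates (channels averaged within the
region; subjects are animals). ICC(1,k) comes from the one-way ANOVA mean
squares, `(MSB − MSW)/MSB`, with F = MSB/MSW on (n−1, n(k−1)) df and the
standard F-interval for the 95% bounds (LB = 1 − 1/(F/F₀.₉₇₅;df1,df2),
UB = 1 − 1/(F·F₀.₉₇₅;df2,df1)). Subjects with any missing week are dropped
listwise — the one-way model is defined on a complete matrix. Negative
estimates are reported as computed (labelled "poor"), not truncated:
truncation is a display choice and hides null behavior. Under the null the
estimator's expectation is 1 − (n−1)/(n−3), i.e. ≈ −0.12 at n = 20; tests
check calibration against that exact value rather than against zero.
Interpretation bands are poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤
excellent; boundary values go to the higher band since strict inequalities
would leave them unassigned.

## Synthetic data generator

The generator is the package's study stand-in, not a biophysical
simulation: events are phenomenological waveforms with exact ground truth,
sufficient to exercise every detector decision path.

*Background*: per-channel Gaussian noise spectrally shaped to 1/f^α with
α = 1.5 (flattened below 0.5 Hz), total 50 µV RMS — a typical LFP-like
spectrum; the quality screen asserts linearity, not a particular slope.
Channels within a hemisphere share a common component (mixing 0.3). A 50 Hz
line component (4 µV RMS) is added. Baseline state adds narrow-band (1 Hz
FWHM) components at 4 Hz (35 µV) and 10 Hz (25 µV), the NREM-like delta and
alpha peaks seen under mild anesthesia; the post-insult state suppresses
delta (15 µV), removes alpha, and adds burst-gated 18–20 Hz activity
(22 µV, on 0.5–2 s / off 1–4 s) on hippocampal channels. Narrow-band
components are synthesized at a reduced internal rate and upsampled — 
numerically equivalent for bands a few Hz wide.

*Events*: IEDs are biphasic Gaussian-derivative transients (20–50 ms wide,
5–8 × background RMS — amplitude placeholders, since no porcine SEEG
amplitude scale is published; they are documented as such). Ripples are
Gaussian-windowed tones, frequency drawn from N(147.3, 20.45²) Hz truncated
to [100, 200], 8 cycles by default; SNR is the ratio of event RMS to the
analytic 100–500 Hz background RMS — the detector's own decision variable —
with default 3. Seizures are amplitude-modulated rhythmic discharges
(7 → 3 Hz chirp with a second harmonic, 1 s ramps) lasting 12–45 s,
injected on one hemisphere's hippocampal channels. Motion artifacts are
large common-mode low-frequency lurches, masked on all channels. Injected
events avoid artifacts and each other; IED placements keep ≥ 2 s separation
so ground truth is compatible with the detector's refractory rule. All
counts are Poisson at the configured per-minute rates; everything derives
from one seed and regenerates bit-identically.

*Study designs*: the default manifest mirrors the study groups — 8 E+
animals whose hippocampal rates rise from ~2/min at baseline to weekly
means around 8/14/10/12 per min (each with a stable per-animal offset,
SD 2.5/min — the subject effect that the ICC measures — plus week-to-week
noise), four of which carry 1–2 electrographic seizures in weeks 2–4; and
4 E− animals that keep baseline-like spectra and flat-to-decreasing rates.
Sessions default to 10 min standing in for the protocol's 2 h recordings
(rates in events/min are duration-invariant; the scale factor is recorded
in the manifest, and `--full-scale` generates true 2 h files).

What passing closed-loop tests does **not** show about real data: the
generator's events are stereotyped and its background is stationary, so
detector sensitivity/precision here are upper bounds; real recordings add
state changes, non-stationary artifacts, and events co-occurring with
spikes (sharp transients leak power above 100 Hz and can produce "false
ripples", which the generator only reproduces if spikes and ripples are
co-injected).

## Pipeline

The study pipeline (QC → detection → rates → statistics → ICC) analyzes
hippocampal channels by default — the study's reliability endpoint is the
hippocampal HFO rate; `channel_scope` widens to all in-brain channels.
Seizure detection runs on one reference channel per hemisphere (the
discharge is network-wide and the per-animal count is the endpoint);
detected seizure intervals are excluded from that hemisphere's HFO
statistics. Channels failing the 1/f screen are excluded from detection
with a logged reason. Every number in the statistics reports is
recomputable from the emitted CSVs; outputs are byte-identical across
reruns with a fixed seed, and an existing output directory is never
overwritten without `force`.

## Numerical notes and limitations

- Filters: SOS form, `sosfiltfilt`; edge transients are ignored (events
  are injected ≥ 0.5 s from the edges; real data should be masked at file
  boundaries if needed).
- The detectors' threshold statistics include any undetected events on the
  channel; at the study's rates this biases thresholds upward by a few
  percent, which the closed-loop sensitivity targets absorb.
- Reference scheme (referential vs. bipolar) is taken as given; no
  re-referencing is computed.
- No fast-ripple (250–500 Hz) subclass is reported separately: the band is
  detected, but events in this model concentrate at 100–200 Hz.
- The seizure detector's two layers (CWT denoise + energy threshold) are
  one reading of "multi-layer thresholding"; layer count and wavelet
  parameters are configurable defaults, not fitted values.
- Desk-scale problem sizes (10-min sessions, 60-session default study) are
  the package's own defaults for iteration speed; all rate-based statistics
  are duration-invariant and `--full-scale` reproduces protocol-length
  files.
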