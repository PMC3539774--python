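# Methods

## The simulated rig

`dafsim` reproduces, in software and offline, the signal path of a
real-time acoustic feedback system for songbird experiments.  The
simulation is *causal*: the engine consumes one sample at a time, all
decisions at sample index `t` depend only on samples `<= t`, and the
event log is bit-identical regardless of how the stream is chunked.
No real-time scheduling guarantees are made or measured — hardware
latency is out of scope; what is preserved is the algorithm.

Time is carried everywhere as an integer sample index (sample 0 is the
first sample of the stream).  Every millisecond-valued configuration
entry is converted once to an integer sample or hop count by rounding;
"every 1 ms" logic counts hops, not wall time.  This avoids float-time
drift over long streams and makes all runs exactly reproducible.

## Detection

**Gating.**  In idle mode, every `gate_check_every_ms` (default 1 ms)
the rms of the last `gate_window_ms` (10 ms) of input is compared to
`gate_rms_threshold`; a crossing switches the engine to triggered mode.
While triggered, every `idle_return_check_every_s` (1 s) the rms of the
last `idle_return_window_ms` (200 ms) is compared to
`idle_return_rms_threshold`; falling below it returns the engine to
idle and closes the recorded trigger segment.  No canonical values
exist for the two thresholds, so the defaults are calibrated from a
noise-floor segment: trigger at 3x its rms, idle-return at 1.5x.  The
hysteresis (trigger > idle-return) prevents mode oscillation.  The gate
controls mode transitions only; detection itself is purely
correlational.

**Spectral analysis.**  While triggered, a 256-point FFT (Hann taper by
default) of the most recent samples is computed every hop
(`round(1 ms x 30 300 Hz) = 30` samples ~ 0.990 ms) and pushed into a
fixed-capacity spectrogram ring (512 columns; the sample ring holds 2 s
of audio — both far above the longest supported template, 100 ms, so
capacity never truncates a match window).  Magnitudes are linear by
default: Pearson correlation of linear-magnitude patches is exactly
invariant to audio amplitude, so detections depend on spectral shape,
not loudness.  A log scale (`log1p`) is available.  Columns are
computed only in triggered mode, and the column grid is global
(column ends at `t` when `(t+1) % hop == 0`), so streaming columns
coincide bit-for-bit with a one-pass offline spectrogram of the same
audio — the basis of the engine-vs-oracle equivalence tests.

**Templates.**  A template is the spectrogram patch covering
`pre_roll_ms` (10 ms) of pre-onset audio plus the first `duration_ms`
(20 ms) of a target syllable, built from an annotated recording; its
final column ends at onset + duration, so the detection time lands
inside the syllable (mid-syllable for a 40 ms syllable).  The detection
condition is `r >= threshold` (0.8) at the current hop — first
crossing wins, with no local-maximum search; ties across templates at
one hop are all emitted, ordered by template id.  Because consecutive
hops of a quasi-stationary syllable stay highly correlated, each
template carries a refractory equal to its full time span (30 ms at
defaults) so one rendition yields one detection.  A zero-variance patch
(true silence) raises an explicit degenerate-input error rather than
correlating to 0; whether silence is "song" is the gate's decision.

One documented ambiguity: descriptions of the original rig give the
correlated window variously as 20 ms and 40 ms of recent signal.  Here
the correlated window always has the template's own length
(configurable), which is the only self-consistent choice; nothing else
in the pipeline depends on it.  Whether the original normalized
spectrograms before correlating is also unknown; linear magnitudes with
plain Pearson correlation are the default for the amplitude-invariance
reason above.

## Feedback

After a detection, playback is decided by the policy: `always`;
`probabilistic` (an independent Bernoulli draw per detection,
p = 0.05 default — sparse enough that a song rarely contains two
playbacks); or `pitch_conditional` (strict inequality against a
threshold, 3530 Hz default; equality triggers in neither direction).
Playback starts at syllable onset + `delay_ms` (40 ms), where onset is
recovered as detection time minus the template's post-onset extent.
White-noise feedback is uniform noise by default (rms = amplitude/√3),
Gaussian optional; a stored waveform can be played instead.

**Pitch.**  The pitch at a hop is the frequency of the largest peak of
the 256-point FFT magnitude, refined by parabolic interpolation over
the log-magnitudes of the peak bin and its two neighbours.  The raw bin
spacing (30 300/256 ~ 118 Hz) is far coarser than the 20 Hz separating
the experimental thresholds (3530 vs 3510 Hz), so sub-bin refinement is
required; parabolic interpolation is the minimal mechanism and achieves
~2 Hz accuracy on the synthetic stacks (verified against programmed
f0).  All-zero windows yield an undefined-pitch marker (NaN), not an
exception.  The syllable's pitch is the minimum defined contour value
3–12 ms after the detection time.

**Closed loop.**  `simulate_closed_loop` feeds the engine the *mixed*
signal (input plus playback scaled by a pickup gain, emulating
microphone pickup of the speaker).  Pitch-conditional decisions are
deferred until the pitch window has elapsed (12 ms after detection,
still 20 ms before the default playback start), then playback is mixed
into the future of the stream and the engine's lockout is set to the
playback end, so the detector cannot trigger on its own output.  If a
configuration makes the nominal playback start precede the earliest
causal decision time, playback is clamped to that time with a warning.

## Synthetic song

The generator emulates Bengalese-finch-like song: a five-type syllable
inventory (harmonic stacks with 1/k harmonic amplitudes, linear
frequency sweeps), 25–50 ms syllables with raised-cosine 4 ms
attack/decay, ~60 ms gaps, a first-order Markov sequence model in which
the target stack ("b", f0 = 3500 Hz) is always followed by a frequency
sweep overlapping its frequencies (so discrimination must use the
spectro-temporal pattern), and songs that open with an introductory
sweep, never the target.  Default rendition-to-rendition variability:
f0 jitter 30 Hz s.d., gap jitter 8 ms plus 2 ms timing jitter,
amplitude jitter 5 %, and a uniform background noise floor at −40 dB
relative to unit syllable amplitude.  Sample rate 30 300 Hz throughout.
Annotations (label, onset, offset, rendition f0) are exact by
construction.

What the generator does *not* emulate: syringeal acoustics, amplitude
and frequency modulation within syllables, song-system motor
variability structure, reverberation, or any *immediate* behavioral
response of the bird to feedback — a synthetic song is fully rendered
before the loop runs, so feedback cannot stretch the following
inter-syllable interval.  Consequently the feedback-vs-control interval
comparison in the acceptance script measures a true null (its KS
p-value is large): it validates the estimator and test machinery, not a
behavioral effect, and passing tests here say nothing about how a live
bird would respond.

**The virtual bird.**  `BirdAgent` is a deliberately minimal escape
learner: each rendition that receives feedback moves its mean target
f0 by `learning_rate` (2 Hz default) away from the feedback region (up
when feedback targets pitches below threshold, down when above).  The
phenomenon it produces — gradual mean-pitch drift away from the
feedback region, reversing when the contingency flips — is the point;
the update rule is not a model of vocal learning.  Default problem
sizes keep a 6 + 6-day experiment (15 songs/day) under a minute while
leaving the drift (tens of Hz per phase) far above the day-mean
sampling error of a few Hz.

## Evaluation statistics

*Matching* is greedy-chronological one-to-one: each detection pairs
with the nearest unmatched expected detection point (truth onset +
template post-onset extent) within a tolerance, 10 ms by default — a
numeric stand-in for by-eye verification; greedy matching is validated
against exhaustive optimal assignment on small instances.  *Intervals*
use the half-difference estimator, (t_second-following − t_target)/2,
which equals the inter-onset spacing exactly for equal spacing and
avoids the playback-contaminated intervening syllable.  The *KS test*
computes D as the ECDF supremum over pooled points and the p-value from
the asymptotic Kolmogorov distribution at effective size nm/(n+m)
(appropriate for hundreds of intervals; an exact test is unnecessary at
these sizes).  *Daily pitch summaries* report mean, s.e.m. (s.d./√n)
and n per day; n = 1 days report s.e.m. 0 and are flagged.

## Numerical and degenerate-input choices

- All stochastic components draw from explicit `numpy` Generators; a
  corpus spawns one child seed per song from a single root seed.
- Pearson r is clipped to [−1, 1] after computation; zero variance
  raises, never returns 0.
- Empty rings, out-of-range windows, aliasing harmonics, stereo audio,
  unknown config keys: explicit typed exceptions, no silent coercion.
- PCM-16 WAV uses symmetric scaling by 32768 with clipping at 32767,
  bounding round-trip error by 1/32768; float WAV round trips
  bit-exactly.

## Known limitations

- Detection times are first-threshold-crossing times and precede the
  correlation peak by a few hops; the matching tolerance absorbs this.
- The engine clears its spectrogram ring on each idle→triggered
  transition, so the first template-length of columns after a trigger
  cannot detect; grammars whose songs open with a non-target syllable
  (as the default does) are unaffected.
- A mid-song return to idle (a pause aligned with the 1 s rms check)
  would likewise clear the ring; the default grammar's gaps are far too
  short for this.
- Template correlation degrades as a bird's pitch drifts far
  (> ~150 Hz) from the template's f0; long agent runs at high learning
  rates lose renditions per day, as real experiments would without
  re-templating.
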