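"""Synthetic Bengalese-finch-like song with ground-truth annotations.

Real song consists of 20-100 ms syllables — harmonic stacks and
frequency sweeps — separated by inter-syllable gaps, with the sequence
of syllables as the main source of song-to-song variability plus
rendition-to-rendition jitter in timing, amplitude and fundamental
frequency.  The generator emulates exactly that structure: a small
syllable inventory, a first-order Markov sequence model, Gaussian jitter
on gaps and f0, and a uniform background noise floor.  Every waveform
comes with exact annotations (label, onset, offset, rendition f0), which
serve as ground truth for detector evaluation.

The :class:`BirdAgent` is a deliberately minimal "virtual bird" for
closed-loop escape-conditioning runs: each rendition that earns feedback
nudges the agent's mean fundamental a fixed step away from the feedback
region.  It exists to exercise the detect -> pitch -> feedback loop, not
to model vocal learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .feedback import FeedbackPolicy, simulate_closed_loop
from .spectral import SpectralParams

__all__ = [
    "SyllableSpec",
    "SongGrammar",
    "Annotation",
    "BirdAgent",
    "DaySummary",
    "synth_syllable",
    "synth_song",
    "synth_corpus",
    "agent_day",
    "default_grammar",
]


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable type: a harmonic stack or a frequency sweep."""
    label: str
    kind: str                     # "harmonic_stack" or "sweep"
    f0_hz: float
    f0_end_hz: float | None = None   # sweeps only
    n_harmonics: int = 3
    duration_ms: float = 40.0
    attack_ms: float = 4.0
    decay_ms: float = 4.0

    def __post_init__(self):
        if self.kind not in ("harmonic_stack", "sweep"):
            raise ConfigurationError(f"unknown syllable kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ConfigurationError("duration_ms must be positive")


@dataclass
class SongGrammar:
    """A song specification: inventory, sequence model, jitter, noise."""
    syllables: dict[str, SyllableSpec]
    transitions: dict[str, dict[str, float]]  # rows over labels + "end", sum to 1
    start_label: str
    gap_ms: float = 60.0
    gap_jitter_ms: float = 8.0
    f0_jitter_hz: float = 30.0
    timing_jitter_ms: float = 2.0
    amplitude_jitter: float = 0.05
    noise_floor: float = 0.01      # -40 dB relative to unit syllable amplitude
    max_syllables: int = 12
    lead_in_ms: float = 100.0
    lead_out_ms: float = 400.0

    def __post_init__(self):
        for lab, row in self.transitions.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(f"transition row {lab!r} sums to {s}, not 1")
        for sd in (self.gap_jitter_ms, self.f0_jitter_hz, self.timing_jitter_ms,
                   self.amplitude_jitter):
            if sd < 0:
                raise ConfigurationError("jitter s.d. must be >= 0")


@dataclass(frozen=True)
class Annotation:
    """Ground truth for one emitted syllable rendition."""
    label: str
    onset_s: float
    offset_s: float
    f0_hz: float


def default_grammar(target_f0_hz: float = 3500.0) -> SongGrammar:
    """The study grammar: five syllable types, one harmonic-stack target.

    The target ("b") is a harmonic stack with a distinctive fundamental;
    the syllables that follow it are frequency sweeps overlapping the
    target's frequencies, so discrimination must rest on the spectrogram
    pattern, not on the instantaneous frequency alone.  Songs open with
    an introductory sweep, never with the target.
    """
    syl = {
        "a": SyllableSpec("a", "sweep", f0_hz=7000.0, f0_end_hz=5000.0,
                          n_harmonics=2, duration_ms=30.0),
        "b": SyllableSpec("b", "harmonic_stack", f0_hz=target_f0_hz,
                          n_harmonics=3, duration_ms=40.0),
        "c": SyllableSpec("c", "sweep", f0_hz=6000.0, f0_end_hz=3500.0,
                          n_harmonics=2, duration_ms=35.0),
        "d": SyllableSpec("d", "harmonic_stack", f0_hz=2500.0,
                          n_harmonics=4, duration_ms=50.0),
        "e": SyllableSpec("e", "sweep", f0_hz=4000.0, f0_end_hz=6000.0,
                          n_harmonics=2, duration_ms=25.0),
    }
    transitions = {
        "a": {"b": 0.85, "d": 0.15},
        "b": {"c": 1.0},
        "c": {"d": 0.55, "e": 0.45},
        "d": {"e": 0.5, "b": 0.3, "end": 0.2},
        "e": {"b": 0.35, "d": 0.25, "end": 0.4},
    }
    return SongGrammar(syllables=syl, transitions=transitions, start_label="a")


def synth_syllable(spec: SyllableSpec, params: SpectralParams,
                   f0_override: float | None = None,
                   amplitude: float = 1.0) -> np.ndarray:
    """Render one syllable: a harmonic stack (1/k harmonic amplitudes) or a
    linear frequency sweep, with raised-cosine attack/decay ramps.

    Harmonics at or above Nyquist raise :class:`ConfigurationError`.
    """
    sr = params.sample_rate_hz
    f0 = float(f0_override if f0_override is not None else spec.f0_hz)
    n = params.ms_to_samples(spec.duration_ms)
    t = np.arange(n) / sr
    nyq = sr / 2.0
    if spec.kind == "harmonic_stack":
        top = f0 * spec.n_harmonics
        if top >= nyq:
            raise ConfigurationError(
                f"harmonic {spec.n_harmonics} of {f0:.0f} Hz at/above Nyquist")
        wave = np.zeros(n)
        for k in range(1, spec.n_harmonics + 1):
            wave += np.sin(2 * np.pi * k * f0 * t) / k
    else:
        f1 = float(spec.f0_end_hz if f0_override is None
                   else spec.f0_end_hz + (f0 - spec.f0_hz))
        if max(f0, f1) * spec.n_harmonics >= nyq:
            raise ConfigurationError("sweep harmonics reach Nyquist")
        # linear chirp: phase integral of f(t) = f0 + (f1 - f0) t / T
        T = n / sr
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t * t / T)
        wave = np.zeros(n)
        for k in range(1, spec.n_harmonics + 1):
            wave += np.sin(k * phase) / k
    env = np.ones(n)
    na = min(params.ms_to_samples(spec.attack_ms), n // 2)
    nd = min(params.ms_to_samples(spec.decay_ms), n // 2)
    if na > 0:
        env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    if nd > 0:
        env[n - nd:] = 0.5 * (1 - np.cos(np.pi * np.arange(nd, 0, -1) / nd))
    wave *= env
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= amplitude / peak
    return wave


def _sample_sequence(grammar: SongGrammar, rng: np.random.Generator) -> list[str]:
    seq = [grammar.start_label]
    while len(seq) < grammar.max_syllables:
        row = grammar.transitions[seq[-1]]
        labels = sorted(row)
        probs = np.array([row[l] for l in labels])
        nxt = labels[rng.choice(len(labels), p=probs / probs.sum())]
        if nxt == "end":
            break
        seq.append(nxt)
    return seq


def synth_song(grammar: SongGrammar, params: SpectralParams,
               rng: np.random.Generator,
               f0_overrides: dict[str, float] | None = None,
               ) -> tuple[np.ndarray, list[Annotation]]:
    """Render one song and its exact annotations.

    ``f0_overrides`` shifts the mean fundamental of the named syllable
    types (used by the bird agent); rendition jitter is applied on top.
    Background noise at the grammar's noise floor fills the gaps and the
    lead-in/lead-out.
    """
    sr = params.sample_rate_hz
    seq = _sample_sequence(grammar, rng)
    annotations: list[Annotation] = []
    pos = params.ms_to_samples(grammar.lead_in_ms)
    chunks: list[tuple[int, np.ndarray]] = []
    for i, lab in enumerate(seq):
        spec = grammar.syllables[lab]
        mean_f0 = (f0_overrides or {}).get(lab, spec.f0_hz)
        f0 = mean_f0 + rng.normal(0.0, grammar.f0_jitter_hz)
        amp = max(0.1, 1.0 + rng.normal(0.0, grammar.amplitude_jitter))
        wave = synth_syllable(spec, params, f0_override=f0, amplitude=amp)
        chunks.append((pos, wave))
        annotations.append(Annotation(
            label=lab, onset_s=pos / sr, offset_s=(pos + wave.size) / sr,
            f0_hz=f0))
        if i < len(seq) - 1:
            gap = max(10.0, grammar.gap_ms + rng.normal(0.0, grammar.gap_jitter_ms)
                      + rng.normal(0.0, grammar.timing_jitter_ms))
            pos += wave.size + params.ms_to_samples(gap)
        else:
            pos += wave.size
    total = pos + params.ms_to_samples(grammar.lead_out_ms)
    song = rng.uniform(-1.0, 1.0, total) * grammar.noise_floor
    for start, wave in chunks:
        song[start:start + wave.size] += wave
    return song, annotations


def synth_corpus(grammar: SongGrammar, params: SpectralParams, n_songs: int,
                 seed: int) -> list[tuple[np.ndarray, list[Annotation]]]:
    """Generate a seeded corpus; song i uses child seed i of ``seed``."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_songs):
        rng = np.random.default_rng(child)
        out.append(synth_song(grammar, params, rng))
    return out


# ---------------------------------------------------------------------------
# Virtual bird for long-term escape-conditioning runs
# ---------------------------------------------------------------------------

@dataclass
class BirdAgent:
    """A bird that shifts its target syllable's pitch to escape feedback.

    After each rendition that received feedback, ``mean_f0`` moves
    ``learning_rate`` Hz away from the feedback region: up when feedback
    targets pitches below the threshold, down when above.
    """
    grammar: SongGrammar
    target_label: str = "b"
    mean_f0: float = 3450.0
    learning_rate: float = 2.0     # Hz per fed-back rendition
    day_length: int = 20           # songs per day

    def __post_init__(self):
        if self.mean_f0 <= 0:
            raise ConfigurationError("mean_f0 must be positive")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")


@dataclass
class DaySummary:
    """One day of a closed-loop experiment."""
    day: int
    n_renditions: int
    mean_pitch_hz: float
    sem_pitch_hz: float
    n_feedback: int
    mean_f0_end: float             # agent state after the day
    pitches_hz: list[float] = field(default_factory=list)


def agent_day(agent: BirdAgent, policy: FeedbackPolicy, config, rng,
              day: int = 0, pickup_gain: float = 0.0) -> DaySummary:
    """Sing one day's songs through the full detect->pitch->feedback loop.

    Each song runs through :func:`simulate_closed_loop`; measured
    syllable pitches come from the engine's own pitch estimator, and the
    agent's mean fundamental is updated after every fed-back rendition.
    Returns the day summary; the agent is updated in place.
    """
    if policy.mode != "pitch_conditional":
        raise ConfigurationError("agent_day requires a pitch_conditional policy")
    step = agent.learning_rate if policy.direction == "below" else -agent.learning_rate
    pitches: list[float] = []
    n_feedback = 0
    for _ in range(agent.day_length):
        song, _ann = synth_song(agent.grammar, config.spectral, rng,
                                f0_overrides={agent.target_label: agent.mean_f0})
        res = simulate_closed_loop(song, config, policy, rng,
                                   pickup_gain=pickup_gain)
        pitches.extend(p for _, p in res.pitches)
        n_feedback += len(res.playbacks)
        agent.mean_f0 += step * len(res.playbacks)
    arr = np.array(pitches)
    mean = float(arr.mean()) if arr.size else float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return DaySummary(day=day, n_renditions=arr.size, mean_pitch_hz=mean,
                      sem_pitch_hz=sem, n_feedback=n_feedback,
                      mean_f0_end=agent.mean_f0, pitches_hz=list(map(float, pitches)))
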