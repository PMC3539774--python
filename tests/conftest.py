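"""Shared fixtures: spectral parameters, a clean template source song,
templates, a calibrated engine config, and a seeded 50-song corpus.

Everything is generated programmatically; the heavier corpus fixtures
are session-scoped so the streaming runs happen once.
"""

import numpy as np
import pytest

from dafsim import (
    DetectionEvent,
    EngineConfig,
    SpectralParams,
    build_template,
    default_grammar,
    run_stream,
    synth_corpus,
    synth_song,
)

CORPUS_SEED = 123
CORPUS_SIZE = 50
TARGET = "b"
TEMPLATE_MS = 20.0


@pytest.fixture(scope="session")
def params():
    return SpectralParams()


@pytest.fixture(scope="session")
def clean_song(params):
    """Zero-jitter song used as the template source."""
    g = default_grammar()
    g.f0_jitter_hz = 0.0
    g.timing_jitter_ms = 0.0
    g.gap_jitter_ms = 0.0
    g.amplitude_jitter = 0.0
    song, anns = synth_song(g, params, np.random.default_rng(7))
    return song, anns


@pytest.fixture(scope="session")
def template_b(params, clean_song):
    song, anns = clean_song
    tgt = next(a for a in anns if a.label == TARGET)
    return build_template(song, tgt.onset_s, TEMPLATE_MS, params,
                          threshold=0.8, id=TARGET)


@pytest.fixture(scope="session")
def template_d(params, clean_song):
    song, anns = clean_song
    tgt = next(a for a in anns if a.label == "d")
    return build_template(song, tgt.onset_s, TEMPLATE_MS, params,
                          threshold=0.8, id="d")


@pytest.fixture(scope="session")
def noise_floor():
    return np.random.default_rng(1).uniform(-1, 1, 30_300) * 0.01


@pytest.fixture(scope="session")
def engine_config(params, template_b, noise_floor):
    return EngineConfig.calibrated(noise_floor, params, [template_b])


@pytest.fixture(scope="session")
def corpus(params):
    """Seeded 50-song corpus at the generator's default jitter."""
    return synth_corpus(default_grammar(), params, CORPUS_SIZE, CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus_runs(corpus, engine_config):
    """Streaming-engine event logs for every corpus song (computed once)."""
    runs = []
    for song, anns in corpus:
        events, _ = run_stream(song, engine_config)
        dets = [e for e in events if isinstance(e, DetectionEvent)]
        runs.append((song, anns, events, dets))
    return runs
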