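"""Shared fixtures: a fixed tutor motif and a calibrated reference.

The heavy pieces (feature extraction of a 10-song reference corpus and
the pooled null distributions) are built once per session and shared by
the unit and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from songsim.calibration import build_reference
from songsim.config import RunConfig
from songsim.features import (compute_features, fit_normalization,
                              normalize_features)
from songsim.selection import load_tutor_motif
from songsim.synth import (MotifSpec, SyllableSpec, random_motif_spec,
                           render_motif)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


#: 4-syllable tonal tutor motif used by the end-to-end property tests.
TUTOR_SPEC = MotifSpec((
    SyllableSpec("harmonic_stack", 90, f0=700),
    SyllableSpec("pure_tone", 70, f0=2200),
    SyllableSpec("sweep", 80, f0=1200, f1=2000),
    SyllableSpec("harmonic_stack", 100, f0=950),
), (40.0, 50.0, 45.0), "tutor")


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def pipeline(config):
    """Tutor motif + normalization + reference built from 10 unrelated songs."""
    rng = np.random.default_rng(7)
    ref_specs = [random_motif_spec(rng, name=f"ref{i}") for i in range(10)]
    ref_waves = [render_motif(s, seed=100 + i)[0]
                 for i, s in enumerate(ref_specs)]
    tutor_wave, tutor_ann = render_motif(TUTOR_SPEC, seed=5)

    raw = [compute_features(w, config) for w in ref_waves + [tutor_wave]]
    stats = fit_normalization(raw, config.normalization)
    corpus = [normalize_features(f, stats).subset(config.features)
              for f in raw[:10]]
    ref = build_reference(corpus, config, stats)
    tutor_feats = normalize_features(raw[-1], stats)
    motif = load_tutor_motif(tutor_feats, tutor_ann)
    return {
        "config": config,
        "stats": stats,
        "corpus": corpus,
        "ref": ref,
        "tutor_spec": TUTOR_SPEC,
        "tutor_wave": tutor_wave,
        "tutor_feats": tutor_feats,
        "motif": motif,
    }
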