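"""Deterministic random-stream splitting.

All generators in the package derive their randomness from a single
session seed via ``numpy.random.SeedSequence`` spawn keys.  Each modality
(or sub-stage) owns a fixed integer key so that adding a new consumer
never perturbs the streams of existing ones.
"""
from __future__ import annotations

import numpy as np

# Fixed registry: never reorder or renumber, only append.
STREAM_KEYS = {
    "design": 0,
    "stimulus": 1,
    "behavior": 2,
    "eeg": 3,
    "pupil": 4,
    "bold": 5,
    "decoding": 6,
    "pls": 7,
    "stats": 8,
    "ddm": 9,
}


def child_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Return the child generator for ``stream`` (and optional sub-keys).

    Parameters
    ----------
    seed
        Session-level seed.
    stream
        Registered stream name (see ``STREAM_KEYS``).
    extra
        Optional further integer keys (e.g. subject index, trial index).
    """
    key = (STREAM_KEYS[stream],) + tuple(int(k) for k in extra)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
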