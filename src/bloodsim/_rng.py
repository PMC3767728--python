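"""Deterministic random-stream derivation.

Every stochastic draw in the simulator comes from a `numpy` Generator whose
SeedSequence is keyed by (run seed, patient id, arm, event).  Patient
characteristics use one stream per patient; each arm's event draws use their
own sub-streams.  This gives common random numbers for characteristics across
arms and scenarios (variance reduction for paired comparisons) while keeping
event noise independent between arms.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

ARM_CODES = {"ABT": 1, "PAD": 2, "EPO": 3}
EVENT_CODES = {"characteristics": 0, "strategy": 1, "infection": 2, "pneumonia": 3}


def stream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the sub-stream identified by ``(seed, *key)``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def characteristics_stream(seed: int, patient_id: int) -> np.random.Generator:
    return stream(seed, patient_id, 0, EVENT_CODES["characteristics"])


def make_rng_factory(seed: int, patient_id: int) -> Callable[[str, str], np.random.Generator]:
    """Factory ``(arm, event) -> Generator`` for one patient's event draws."""

    def factory(arm: str, event: str) -> np.random.Generator:
        return stream(seed, patient_id, ARM_CODES[arm], EVENT_CODES[event])

    return factory
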