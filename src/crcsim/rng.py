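"""Counter-based random-number streams.

Every stochastic draw in the simulator comes from a Philox stream keyed by
``(master_seed, person_id, purpose)``.  Keying streams by purpose keeps a
person's natural history identical across screening scenarios (common random
numbers), so scenario contrasts such as life-years gained are paired
differences rather than differences of independent runs.
"""

from __future__ import annotations

import numpy as np

# Purpose codes.  PROFILE covers sex and individual risk, LESIONS covers the
# adenoma/carcinoma history, OC_DEATH the other-cause death age.  ATTEND,
# TEST and COLO are consumed only by the screening layer; keeping attendance
# separate from test results makes "always attends" and "attends with
# probability 1" produce byte-identical downstream draws.
PROFILE = 0
LESIONS = 1
OC_DEATH = 2
ATTEND = 3
TEST = 4
COLO = 5

_N_PURPOSES = 8


def person_stream(master_seed: int, person_id: int, purpose: int) -> np.random.Generator:
    """Return the dedicated generator for one (person, purpose) pair."""
    if not 0 <= purpose < _N_PURPOSES:
        raise ValueError(f"unknown stream purpose {purpose}")
    key = (int(master_seed) << 64) | (int(person_id) * _N_PURPOSES + purpose)
    return np.random.Generator(np.random.Philox(key=key))
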