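import numpy as np
import pytest

from pvasim import HYPOTHETICAL, T_LAMPROIDES

#: all (life history, growth rate) study parameterizations
STUDY_COMBOS = [
    (spec, lam)
    for spec in (HYPOTHETICAL, T_LAMPROIDES)
    for lam in (0.9, 0.95, 1.0, 1.025)
]

#: printed fecundities for each combination, 4 d.p.
PRINTED_FECUNDITIES = {
    ("hypothetical", 0.9): 0.4,
    ("hypothetical", 0.95): 0.45,
    ("hypothetical", 1.0): 0.5,
    ("hypothetical", 1.025): 0.5250,
    ("t_lamproides", 0.9): 0.3292,
    ("t_lamproides", 0.95): 0.3976,
    ("t_lamproides", 1.0): 0.4630,
    ("t_lamproides", 1.025): 0.4947,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
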