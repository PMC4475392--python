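"""Deterministic per-stage child seeds derived from a single master seed."""

import numpy as np

# Stable stage ordering: changing this table changes every derived stream.
_STAGE_INDEX = {
    "simulate": 0,
    "ordinate": 1,
    "krige": 2,
    "validate": 3,
    "pcnm": 4,
    "varpart": 5,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible child seed for a named pipeline stage."""
    try:
        idx = _STAGE_INDEX[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_INDEX)}")
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0])
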