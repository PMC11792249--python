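"""Deterministic per-subsystem RNG streams.

One master seed drives the whole simulation.  Each named subsystem gets
its own ``numpy`` Generator derived from ``SeedSequence(seed).spawn``,
in a fixed documented order, so a subsystem can be re-run in isolation
and adding draws to one stream never perturbs another.
"""

from __future__ import annotations

import numpy as np

# Fixed spawn order; append only, never reorder.
STREAMS = ("design", "genotypes", "scores", "phenotypes", "pk")


def stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(int(seed)).spawn(len(STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAMS, children)}
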