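"""Named, independent random substreams derived from a single root seed.

Every stochastic stage of the simulation (latent draws, per-predictor
measurement noise, percentile tie-breaks, Bernoulli outcomes, selection
tie-breaks) pulls from its own named substream.  Substreams are derived from
the root seed with :class:`numpy.random.SeedSequence` spawn keys, so the
draws of one stage are unaffected by how many numbers another stage consumes.
This is what lets different admissions policies — and even different predictor
scenarios — be compared on the *same* simulated cohort: swapping the Test
column between valid and invalid leaves every other predictor's noise
bit-for-bit identical.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["RngStreams", "substream"]


def _name_key(name: str) -> int:
    # CRC32 is stable across platforms and Python versions, unlike hash().
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under root ``seed``."""
    seq = np.random.SeedSequence(seed, spawn_key=(_name_key(name),))
    return np.random.default_rng(seq)


class RngStreams:
    """Factory of independent named Generators under one root seed.

    Each call to :meth:`stream` returns a *fresh* generator positioned at the
    start of that named substream, so repeated calls with the same name
    reproduce the same draws — determinism is a property of (seed, name),
    not of call order.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def stream(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStreams(seed={self.seed})"
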