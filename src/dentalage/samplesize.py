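"""Finite-population sample size for estimating a proportion.

The OpenEpi-style formula with finite-population correction and a design
effect:

    n = ceil( DEFF * N * p*(1-p) / ( (d^2/Z^2) * (N-1) + p*(1-p) ) )

with population size N, hypothesized proportion p, absolute precision d,
standard-normal quantile Z (1.96 for 95% confidence) and design effect
DEFF >= 1.  Rounding is conservative (ceiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the finite-population proportion formula.

    ``alpha`` is documentation only — ``z`` is the operative quantile, so a
    non-default confidence level is expressed by passing its Z directly.
    """

    N: int
    p: float = 0.5
    d: float = 0.05
    z: float = 1.96
    deff: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"population size N={self.N} must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"proportion p={self.p} outside [0, 1]")
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"precision d={self.d} outside (0, 1)")
        if self.z <= 0.0:
            raise ValueError(f"quantile Z={self.z} must be positive")
        if self.deff < 1.0:
            raise ValueError(f"design effect {self.deff} must be >= 1")


def required_sample_size(params: SampleSizeParams | None = None, **kwargs) -> int:
    """Required n for the given parameters (``SampleSizeParams`` or keywords).

    With N = 1 the finite-population term vanishes and the formula collapses
    to N; with p = 0 or 1 the outcome has no variance and n = 0.
    """
    if params is None:
        params = SampleSizeParams(**kwargs)
    pq = params.p * (1.0 - params.p)
    numerator = params.deff * params.N * pq
    denominator = (params.d**2 / params.z**2) * (params.N - 1) + pq
    if denominator == 0.0:
        return 0
    return math.ceil(numerator / denominator)
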