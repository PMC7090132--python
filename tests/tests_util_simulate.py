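"""Shared generative-model simulator (the generator is the recovery oracle)."""

import math

import numpy as np

from smrg.mixture import MixtureParams


def simulate_mixture(params: MixtureParams, n: int, rng) -> np.ndarray:
    """Draw n integer intensities from the background/signal mixture."""
    is_signal = rng.random(n) < (1 - params.alpha)
    bg = params.K0 + np.round(rng.normal(0, math.sqrt(params.vB), n)).astype(int)
    sg = params.K0 + rng.negative_binomial(params.r, params.p, n)
    return np.where(is_signal, sg, np.clip(bg, 0, None)).astype(np.int64)
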