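"""Small numerical helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

#: MAD -> SD consistency factor for the normal distribution.
MAD_SCALE = 1.4826


def spawn_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from a top-level seed.

    ``path`` identifies the stage (and sub-stage) so that independent
    stages never share a stream.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(path)))


def derive_seed(seed: int, *path: int) -> int:
    """A child integer seed (< 2**31) for APIs that take seeds, not rngs."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def robust_sd(x: np.ndarray) -> float:
    """Robust SD via the median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


def diff_noise_sd(y: np.ndarray) -> float:
    """Noise SD of a piecewise-constant-plus-noise signal.

    Estimated from first differences, where the (sparse) true steps are
    outliers the MAD ignores; the sqrt(2) removes the variance doubling
    of differencing.
    """
    d = np.diff(np.asarray(y, dtype=float))
    if d.size == 0:
        return 0.0
    return robust_sd(d) / np.sqrt(2.0)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
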