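"""Small sampling helpers shared by the water and breeding modules."""

from __future__ import annotations

import math

import numpy as np


def truncnorm_draw(
    rng: np.random.Generator,
    mu: float,
    sd: float,
    lo: float,
    hi: float,
    max_tries: int = 10_000,
) -> float:
    """One Normal(mu, sd) draw rejection-sampled into the hard bounds [lo, hi].

    The stated parameter ranges are treated as truncation bounds; a zero sd
    degenerates to the mean (clamped into the bounds).
    """
    if sd == 0.0:
        return min(hi, max(lo, mu))
    for _ in range(max_tries):
        x = mu + sd * rng.standard_normal()
        if lo <= x <= hi:
            return x
    raise RuntimeError(
        f"truncated-normal rejection failed: N({mu}, {sd}) vs bounds [{lo}, {hi}]"
    )


def geometric_failure_day(rng: np.random.Generator, p_survive: float) -> float:
    """Index (1-based) of the first failed daily Bernoulli(p_survive) trial.

    Returns ``inf`` when the survival probability is 1.  Sampling one
    uniform and inverting the geometric CDF is distributionally identical
    to drawing day-by-day Bernoulli trials.
    """
    if p_survive >= 1.0:
        return math.inf
    if p_survive <= 0.0:
        return 1.0
    u = rng.random()
    if u <= 0.0:  # pragma: no cover - measure-zero guard
        return 1.0
    # P(T > k) = p^k  =>  T = ceil(log(u) / log(p))
    return math.ceil(math.log(u) / math.log(p_survive))
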