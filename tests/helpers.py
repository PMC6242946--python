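"""Shared simulation helpers for the test suite."""

import numpy as np
from scipy.special import expit


def empirical_d50_crossing(alphas, beta_day, beta_cn, sigma_ramet, n,
                           rng, cn_ref: float = 12.0,
                           u_tree: float = 0.0) -> float:
    """Day at which the simulated fraction of ramets having at most reached
    score 1.5 crosses 50%, for one donor.

    Draws ``n`` ramet intercepts, scores the binary event 'score within the
    four least-advanced categories' on a fine day grid, and interpolates the
    50% crossing of the decreasing empirical fraction.
    """
    alphas = np.asarray(alphas, dtype=float)
    centre = (alphas[3] - beta_cn * cn_ref - u_tree) / beta_day
    days = np.arange(centre - 25.0, centre + 25.0, 0.25)
    u_r = sigma_ramet * rng.standard_normal(n)
    probs = expit(alphas[3] - beta_day * days[:, None] - beta_cn * cn_ref
                  - u_tree - u_r[None, :])
    frac = (rng.random(probs.shape) < probs).mean(axis=1)
    below = np.nonzero(frac <= 0.5)[0]
    if len(below) == 0 or below[0] == 0:
        raise AssertionError("crossing outside simulated day window")
    j = below[0]
    d0, d1 = days[j - 1], days[j]
    f0, f1 = frac[j - 1], frac[j]
    return d0 + (f0 - 0.5) / (f0 - f1) * (d1 - d0)
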