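"""Genetic map functions.

Conversion between genetic distance (centimorgan) and recombination
fraction for gamete simulation and genotype-probability computation.
Haldane (no crossover interference) is the default; Kosambi is available
for users who prefer interference-adjusted distances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["map_function", "inverse_map_function"]

_KINDS = ("haldane", "kosambi")


def map_function(d_cM, kind: str = "haldane"):
    """Convert genetic distance to recombination fraction.

    Parameters
    ----------
    d_cM : float or array-like
        Genetic distance in centimorgan, >= 0.
    kind : {"haldane", "kosambi"}
        Haldane: r = (1 - exp(-2d)) / 2.
        Kosambi: r = tanh(2d) / 2, with d in Morgan.

    Returns
    -------
    Recombination fraction in [0, 0.5), same shape as input.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    m = d / 100.0  # Morgan
    if kind == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * m))
    elif kind == "kosambi":
        r = 0.5 * np.tanh(2.0 * m)
    else:
        raise ValueError(f"unknown map function {kind!r}; choose from {_KINDS}")
    if np.isscalar(d_cM):
        return float(r)
    return r


def inverse_map_function(r, kind: str = "haldane"):
    """Convert recombination fraction in [0, 0.5) back to distance in cM."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if kind == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * rr)
    elif kind == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * rr) / (1.0 - 2.0 * rr))
    else:
        raise ValueError(f"unknown map function {kind!r}; choose from {_KINDS}")
    if np.isscalar(r):
        return float(d)
    return d
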