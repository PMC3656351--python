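"""Small helpers for phase arithmetic on the circle [0, 2*pi)."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap(phi):
    """Wrap phases into [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


def wrap_diff(delta):
    """Wrap phase differences into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(delta), TWO_PI)


def circ_mean(phases):
    """Circular mean of a set of phases, in [0, 2*pi)."""
    z = np.mean(np.exp(1j * np.asarray(phases, dtype=float)))
    return float(np.mod(np.angle(z), TWO_PI))


def circ_spread(phases):
    """Maximum absolute wrapped deviation from the circular mean."""
    m = circ_mean(phases)
    return float(np.max(np.abs(wrap_diff(np.asarray(phases) - m))))
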