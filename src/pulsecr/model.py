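"""Model parameters, ensemble state, and the pulse-resetting function.

The network is ``N`` phase oscillators coupled all-to-all by delta pulses:
between spikes each phase advances at its natural frequency, and when any
neuron's phase crosses 2*pi (a spike) every other phase ``phi`` is mapped by
the resetting function

    mu(phi) = phi + (kappa / N) * Z(phi),

where ``kappa`` is the total coupling strength and ``Z`` the phase response
curve.  If ``n`` neurons spike simultaneously the others receive the n-fold
composition ``mu^n``, which keeps the dynamics continuous in the initial
conditions as clusters split up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from ._angles import TWO_PI
from .prc import PhaseResponseCurve


@dataclass
class ModelParams:
    """Parameters of the globally pulse-coupled ensemble.

    Attributes
    ----------
    N : int
        Number of oscillators (>= 1).
    omega : float or array of length N
        Natural frequency/frequencies, all > 0 [rad / time].
    kappa : float
        Total coupling strength [rad]; each pulse carries weight kappa/N.
    prc : PhaseResponseCurve
        Phase response curve Z.
    """

    N: int
    omega: Union[float, np.ndarray]
    kappa: float
    prc: PhaseResponseCurve

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        om = np.asarray(self.omega, dtype=float)
        if om.ndim == 0:
            if om <= 0:
                raise ValueError("omega must be positive")
        else:
            if om.size != self.N:
                raise ValueError("omega vector must have length N")
            if np.any(om <= 0):
                raise ValueError("all natural frequencies must be positive")
            self.omega = om

    @property
    def omega_scalar(self) -> float:
        """The common frequency; raises if frequencies are heterogeneous."""
        om = np.asarray(self.omega, dtype=float)
        if om.ndim == 0:
            return float(om)
        if np.ptp(om) == 0:
            return float(om[0])
        raise ValueError("operation requires identical natural frequencies")

    def omega_vector(self) -> np.ndarray:
        om = np.asarray(self.omega, dtype=float)
        if om.ndim == 0:
            return np.full(self.N, float(om))
        return om


@dataclass
class EnsembleState:
    """Snapshot of the ensemble: N phases in [0, 2*pi) and the current time."""

    phases: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(self.phases < 0) or np.any(self.phases >= TWO_PI):
            raise ValueError("phases must lie in [0, 2*pi)")

    def copy(self) -> "EnsembleState":
        return EnsembleState(self.phases.copy(), self.time)


def reset_function(phi, params: ModelParams):
    """Pulse-resetting function mu(phi) = phi + (kappa/N) Z(phi).

    The result is not wrapped; callers wrap where appropriate.  mu(0) = 0 and
    mu(2*pi) = 2*pi because the PRC vanishes at the spike phase.
    """
    return phi + (params.kappa / params.N) * params.prc(phi)


def multi_reset(phi, n: int, params: ModelParams):
    """n-fold composition mu^n(phi) — the reset delivered by a simultaneous
    group of n spikers."""
    if n < 1:
        raise ValueError("composition count n must be >= 1")
    out = np.asarray(phi, dtype=float)
    w = params.kappa / params.N
    for _ in range(n):
        out = out + w * params.prc(out)
    if np.isscalar(phi) or np.ndim(phi) == 0:
        return float(out)
    return out


def check_monotonicity(params: ModelParams, grid_size: int = 4096) -> bool:
    """True iff mu is strictly increasing: 1 + (kappa/N) Z'(phi) > 0 on a grid.

    Monotone mu preserves the cyclic ordering of the phases, which the
    event-driven integration relies on.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    phi = np.linspace(0.0, TWO_PI, grid_size)
    slope = 1.0 + (params.kappa / params.N) * params.prc.derivative(phi)
    return bool(np.all(slope > 0.0))
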