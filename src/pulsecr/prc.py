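"""Phase response curves (PRCs).

A PRC ``Z(phi)`` quantifies the phase shift a weak input produces when it
arrives while the oscillator sits at phase ``phi``.  Two kinds are supported:

* the harmonic curve ``Z_H(phi) = -sin(phi)`` typical of oscillators close to
  a Hopf/Bautin bifurcation, and
* tabulated curves interpolated by a periodic cubic spline, so that measured
  or model-derived PRCs can be used.

All curves are 2*pi-periodic and must vanish at the spike phase,
``Z(0) = Z(2*pi) = 0`` — the response of a spiking neuron to input delivered
exactly at the spike is negligible because the vector field is large there.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from ._angles import TWO_PI

_ENDPOINT_TOL = 1e-9


class PhaseResponseCurve:
    """Abstract base: callable Z(phi) with derivative and mean."""

    kind: str = "abstract"

    def __call__(self, phi):
        raise NotImplementedError

    def derivative(self, phi):
        raise NotImplementedError

    @property
    def mean(self) -> float:
        """Mean value Zbar = (2*pi)^-1 * integral of Z over one period."""
        raise NotImplementedError


class HarmonicPRC(PhaseResponseCurve):
    """Z(phi) = -sin(phi): the canonical smooth type-II response curve."""

    kind = "harmonic"

    def __call__(self, phi):
        return -np.sin(phi)

    def derivative(self, phi):
        return -np.cos(phi)

    @property
    def mean(self) -> float:
        return 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return "HarmonicPRC()"


class TabulatedPRC(PhaseResponseCurve):
    """PRC interpolated through user-supplied knots by a periodic cubic spline.

    Parameters
    ----------
    phi_knots :
        Strictly increasing phases in [0, 2*pi]; the first knot must be 0 and
        the last 2*pi.
    z_knots :
        PRC values at the knots.  Both endpoint values must be zero to within
        1e-9 (they are snapped to exactly zero).
    name :
        Optional label carried through reports.

    The interpolant is C^2 and periodic, so the derivative needed by the
    synchrony-stability criterion is well defined everywhere.
    """

    kind = "tabulated"

    def __init__(self, phi_knots, z_knots, name: str = "tabulated"):
        phi = np.asarray(phi_knots, dtype=float)
        z = np.asarray(z_knots, dtype=float).copy()
        if phi.ndim != 1 or phi.shape != z.shape or phi.size < 4:
            raise ValueError("need matching 1-d arrays with at least 4 knots")
        if np.any(np.diff(phi) <= 0):
            raise ValueError("knot phases must be strictly increasing")
        if abs(phi[0]) > _ENDPOINT_TOL or abs(phi[-1] - TWO_PI) > _ENDPOINT_TOL:
            raise ValueError("knots must start at 0 and end at 2*pi")
        if abs(z[0]) > _ENDPOINT_TOL or abs(z[-1]) > _ENDPOINT_TOL:
            raise ValueError(
                "PRC must vanish at the spike phase: Z(0) = Z(2*pi) = 0"
            )
        z[0] = 0.0
        z[-1] = 0.0
        phi = phi.copy()
        phi[0] = 0.0
        phi[-1] = TWO_PI
        self.phi_knots = phi
        self.z_knots = z
        self.name = name
        self._spline = CubicSpline(phi, z, bc_type="periodic")
        self._dspline = self._spline.derivative()
        self._mean = float(self._spline.integrate(0.0, TWO_PI)) / TWO_PI

    def __call__(self, phi):
        return self._spline(np.mod(phi, TWO_PI))

    def derivative(self, phi):
        return self._dspline(np.mod(phi, TWO_PI))

    @property
    def mean(self) -> float:
        return self._mean

    def __repr__(self) -> str:  # pragma: no cover
        return f"TabulatedPRC(name={self.name!r}, knots={self.phi_knots.size})"


def read_prc(path) -> TabulatedPRC:
    """Read a tabulated PRC from a two-column CSV with header ``phi,Z``."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns 'phi,Z'")
    return TabulatedPRC(data[:, 0], data[:, 1], name=str(path))


def write_prc(path, prc: TabulatedPRC) -> None:
    """Write a tabulated PRC to CSV (header ``phi,Z``)."""
    arr = np.column_stack([prc.phi_knots, prc.z_knots])
    np.savetxt(path, arr, delimiter=",", header="phi,Z", comments="")


def ml_like_prc(n_knots: int = 257) -> TabulatedPRC:
    """Synthetic stand-in for a Morris-Lecar-type PRC.

    This is NOT a fit of any published Morris-Lecar response curve; it is a
    synthetic surrogate with the qualitative features of a type-I spiking
    neuron's PRC: a dominant positive hump, a small negative lobe just after
    the spike, a slightly negative slope at the spike phase (so weak
    excitatory pulse coupling still stabilizes in-phase synchrony), and
    Z(0) = Z(2*pi) = 0.  With stimulation intensity I = -10 and omega = 1 it
    has exactly one stable/unstable fixed-point pair of the stimulated flow.

        Z(phi) = 0.5*(1 - cos phi) - 0.3*sin phi + 0.1*sin 2*phi
    """
    phi = np.linspace(0.0, TWO_PI, n_knots)
    z = 0.5 * (1.0 - np.cos(phi)) - 0.3 * np.sin(phi) + 0.1 * np.sin(2 * phi)
    z[0] = 0.0
    z[-1] = 0.0
    return TabulatedPRC(phi, z, name="ml_like_synthetic")


def get_prc(spec) -> PhaseResponseCurve:
    """Resolve a PRC from a name ('harmonic', 'ml_like'), path, or instance."""
    if isinstance(spec, PhaseResponseCurve):
        return spec
    if spec == "harmonic":
        return HarmonicPRC()
    if spec in ("ml_like", "ml-like"):
        return ml_like_prc()
    return read_prc(spec)
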