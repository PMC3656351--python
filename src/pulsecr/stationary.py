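"""Stationary states of the free ensemble and their stability.

Covers three related objects:

* the stationary phase-distribution density ``rho_s`` of the pulse-coupled
  continuity equation, whose flux balance gives
  ``rho_s(phi) = J / (omega + kappa * Z(phi) * rho_s(0))`` with ``rho_s(0)``
  fixed by a scalar implicit equation;
* finite-N splay states (equal intervals between consecutive ensemble
  spikes) and symmetric m-cluster states, both as fixed points of the
  rotating one-firing return map; and
* their characteristic multipliers, reported per collective period (one
  spike of every neuron), so |lambda_max| > 1 means a perturbation grows
  from one spike of a given neuron to its next.

Linear stability of in-phase synchrony is also provided for the pulse
coupling (sign of kappa * Z'(0)), for smooth phase-dependent coupling
``G(phi_k)``, and for the averaged (phase-difference) coupling; the three
criteria coincide in the weak-coupling / pulse-like-G limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, root

from ._angles import TWO_PI, wrap_diff
from .model import ModelParams, multi_reset
from .simulator import _advance_free_raw

_RESIDUAL_TOL = 1e-10


# ---------------------------------------------------------------------------
# synchrony stability
# ---------------------------------------------------------------------------

class StabilityResult(NamedTuple):
    """stable is None when the criterion is marginal (value == 0)."""

    stable: Optional[bool]
    value: float

    @property
    def marginal(self) -> bool:
        return self.stable is None


def _classify(value: float, tol: float = 1e-12) -> StabilityResult:
    if abs(value) <= tol:
        return StabilityResult(None, value)
    return StabilityResult(value < 0.0, value)


def synchrony_stable_pulse(params: ModelParams) -> StabilityResult:
    """In-phase synchrony of the pulse-coupled network is stable iff
    kappa * Z'(0) < 0."""
    value = float(params.kappa * params.prc.derivative(0.0))
    return _classify(value)


@dataclass
class SmoothCoupling:
    """Smooth periodic coupling function G for the non-averaged smooth model,
    with its mean Gbar and the averaged interaction
    H(phi) = (2*pi)^-1 * int Z(psi) G(phi + psi) dpsi."""

    G: Callable
    Gbar: float
    H: Callable
    Hprime: Callable

    @classmethod
    def from_callable(cls, G: Callable, prc, n_grid: int = 2048) -> "SmoothCoupling":
        psi = np.arange(n_grid) * (TWO_PI / n_grid)
        g = np.asarray(G(psi), dtype=float) * np.ones(n_grid)
        z = np.asarray(prc(psi), dtype=float) * np.ones(n_grid)
        gbar = float(np.mean(g))
        # H_j = mean_i Z_i * G_{i+j}: circular cross-correlation via FFT
        h = np.real(np.fft.ifft(np.conj(np.fft.fft(z)) * np.fft.fft(g))) / n_grid
        grid = np.append(psi, TWO_PI)
        hvals = np.append(h, h[0])
        spline = CubicSpline(grid, hvals, bc_type="periodic")
        dspline = spline.derivative()
        return cls(
            G=G,
            Gbar=gbar,
            H=lambda phi: spline(np.mod(phi, TWO_PI)),
            Hprime=lambda phi: dspline(np.mod(phi, TWO_PI)),
        )


def synchrony_stable_smooth(params: ModelParams, coupling: SmoothCoupling,
                            grid_size: int = 8192) -> StabilityResult:
    """Stability integral for the smoothly coupled model:
    kappa * int G Z' / (omega + kappa Z G) dphi < 0."""
    omega = params.omega_scalar
    phi = np.linspace(0.0, TWO_PI, grid_size + 1)
    g = np.asarray(coupling.G(phi), dtype=float) * np.ones(phi.size)
    z = params.prc(phi)
    zp = params.prc.derivative(phi)
    denom = omega + params.kappa * z * g
    if np.any(denom <= 0.0):
        raise ValueError(
            "omega + kappa*Z*G vanishes: the flow is not forward, "
            "stability integral undefined"
        )
    value = float(params.kappa * np.trapezoid(g * zp / denom, phi))
    return _classify(value, tol=1e-10)


def synchrony_stable_averaged(params: ModelParams, coupling: SmoothCoupling,
                              grid_size: int = 8192) -> StabilityResult:
    """Averaged-model criterion -kappa*H'(0) = (kappa/2pi) int G Z' dphi < 0."""
    phi = np.linspace(0.0, TWO_PI, grid_size + 1)
    g = np.asarray(coupling.G(phi), dtype=float) * np.ones(phi.size)
    zp = params.prc.derivative(phi)
    value = float(params.kappa / TWO_PI * np.trapezoid(g * zp, phi))
    return _classify(value, tol=1e-10)


# ---------------------------------------------------------------------------
# stationary densities
# ---------------------------------------------------------------------------

@dataclass
class StationaryDensity:
    """Stationary phase density on a uniform grid over [0, 2*pi]."""

    grid: np.ndarray
    rho: np.ndarray
    rho0: float

    def __call__(self, phi):
        return np.interp(np.mod(phi, TWO_PI), self.grid, self.rho)

    def write_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.rho]),
                   delimiter=",", header="phi,rho", comments="")


def stationary_density_pulse(params: ModelParams,
                             grid_size: int = 4096) -> StationaryDensity:
    """Solve the flux-balance density of the pulse-coupled continuity equation.

    rho_s(phi) = J / v(phi) with drift v(phi) = omega + kappa Z(phi) rho_s(0)
    and flux J fixed by normalization; rho_s(0) solves the scalar implicit
    equation rho_s(0) * omega * int dpsi / v(psi) = 1 (bracketed root search).
    """
    omega = params.omega_scalar
    kappa = params.kappa
    phi = np.linspace(0.0, TWO_PI, grid_size + 1)
    z = params.prc(phi)

    zmin = float(np.min(kappa * z))
    rho0_cap = np.inf if zmin >= 0.0 else omega / (-zmin) * (1.0 - 1e-9)

    def g(rho0: float) -> float:
        v = omega + kappa * z * rho0
        return 1.0 / (omega * np.trapezoid(1.0 / v, phi)) - rho0

    lo, hi = 1e-6, 10.0 / TWO_PI
    hi = min(hi, rho0_cap)
    for _ in range(60):
        if g(lo) * g(hi) < 0.0:
            break
        lo *= 0.5
        hi = min(hi * 2.0, rho0_cap)
        if hi >= rho0_cap and lo < 1e-300:
            break
    else:
        raise ValueError("no stationary density (coupling too strong)")
    if g(lo) * g(hi) >= 0.0:
        raise ValueError("no stationary density (coupling too strong)")
    rho0 = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)

    v = omega + kappa * z * rho0
    if np.any(v <= 0.0):
        raise ValueError("no stationary density (drift reverses sign)")
    rho = (1.0 / v) / np.trapezoid(1.0 / v, phi)
    return StationaryDensity(phi, rho, float(rho[0]))


def stationary_density_first_order(params: ModelParams, phi):
    """First-order (in kappa) expansion of the pulse-coupled stationary
    density: 1/(2*pi) + kappa (Zbar - Z(phi)) / ((2*pi)^2 omega)."""
    omega = params.omega_scalar
    zbar = params.prc.mean
    return 1.0 / TWO_PI + params.kappa * (zbar - params.prc(phi)) / (TWO_PI ** 2 * omega)


def stationary_density_smooth_first_order(params: ModelParams,
                                          coupling: SmoothCoupling, phi):
    """First-order stationary density of the smoothly coupled model:
    1/(2*pi) + kappa Gbar (Zbar - Z(phi)) / (2*pi omega)."""
    omega = params.omega_scalar
    zbar = params.prc.mean
    return 1.0 / TWO_PI + params.kappa * coupling.Gbar * (zbar - params.prc(phi)) / (
        TWO_PI * omega)


# ---------------------------------------------------------------------------
# rotating firing return map, splay and cluster states
# ---------------------------------------------------------------------------

def _firing_map(x: np.ndarray, params: ModelParams, count: int):
    """One application of the rotating firing return map.

    ``x`` holds the phases of the non-leading oscillators in descending order
    (x[0] is next to fire); the just-fired oscillator sits at 0.  Advance
    until x[0] reaches 2*pi, apply the count-fold reset to everyone else,
    and relabel.  Returns (new_x, firing_interval).
    """
    omega = params.omega_scalar
    dt = (TWO_PI - x[0]) / omega
    shifted = np.concatenate([x[1:], [0.0]]) + omega * dt
    return multi_reset(shifted, count, params), dt


@dataclass
class SplayState:
    """Finite-N splay state: equal intervals between consecutive spikes."""

    phases: np.ndarray       # ascending snapshot just after a spike; phases[0] == 0
    isi: float               # interval between consecutive ensemble spikes
    period: float            # N * isi: one spike of every neuron

    def x_descending(self) -> np.ndarray:
        return self.phases[1:][::-1].copy()


def splay_state(params: ModelParams) -> SplayState:
    """Locate the splay state by a scalar self-consistency equation.

    In a splay state every neuron experiences the same history: drift for one
    inter-spike interval T, receive one pulse, repeat.  Following one neuron
    from its own spike through N-1 pulses and requiring it to reach 2*pi
    after the N-th drift gives a single monotone equation for T.  The result
    is verified to be a fixed point of the full rotating return map.
    """
    N = params.N
    omega = params.omega_scalar

    def trace(T: float) -> np.ndarray:
        xs = np.empty(N - 1)
        phi = 0.0
        for k in range(N - 1):
            phi = float(multi_reset(phi + omega * T, 1, params))
            xs[k] = phi
        return xs

    def f(T: float) -> float:
        xs = trace(T)
        last = xs[-1] if N > 1 else 0.0
        return last + omega * T - TWO_PI

    T0 = TWO_PI / (N * omega)
    lo, hi = 0.1 * T0, 5.0 * T0
    for _ in range(60):
        if f(lo) * f(hi) < 0.0:
            break
        lo *= 0.5
        hi *= 2.0
    else:
        raise ValueError("splay state: no bracketing interval for the ISI")
    isi = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    xs = trace(isi)
    phases = np.concatenate([[0.0], xs])
    state = SplayState(phases, float(isi), float(N * isi))

    x = state.x_descending()
    x_new, _ = _firing_map(x, params, 1)
    res = float(np.max(np.abs(x_new - x))) if N > 1 else 0.0
    if res > 1e-8:
        raise ValueError(f"splay state residual too large: {res:.3e}")
    return state


@dataclass
class ClusterState:
    """Symmetric m-cluster state: m internally synchronized groups of N/m
    neurons.  ``psi`` are the cluster phases; for stationary states this is
    the snapshot just after a cluster spike (sorted ascending, psi[0] == 0)
    and ``period`` is the collective return time."""

    psi: np.ndarray
    m: int
    cluster_size: int
    period: Optional[float] = None

    def x_descending(self) -> np.ndarray:
        return np.sort(self.psi[self.psi > 0.0])[::-1].copy()


@dataclass
class MultiplierSpectrum:
    """Moduli of characteristic multipliers per collective period.

    tangential: perturbations inside the cluster manifold (or, for splay
    states, all return-map multipliers); transverse: growth factor of an
    infinitesimal single-neuron split from each cluster.
    """

    tangential: np.ndarray
    transverse: np.ndarray
    lambda_max: float

    def to_dict(self) -> dict:
        return {
            "tangential": list(map(float, self.tangential)),
            "transverse": list(map(float, self.transverse)),
            "lambda_max": float(self.lambda_max),
        }


def _map_jacobian(x_star: np.ndarray, params: ModelParams, count: int,
                  step: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of the rotating firing map."""
    n = x_star.size
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = step
        fp, _ = _firing_map(x_star + e, params, count)
        fm, _ = _firing_map(x_star - e, params, count)
        J[:, j] = (fp - fm) / (2.0 * step)
    return J


def _per_period_moduli(J: np.ndarray, firings_per_period: int) -> np.ndarray:
    lam = np.linalg.eigvals(J)
    moduli = np.abs(lam) ** firings_per_period
    return np.sort(moduli)[::-1]


def splay_multipliers(params: ModelParams, step: float = 1e-7) -> MultiplierSpectrum:
    """Multiplier moduli of the splay state over one collective period,
    from the numerical Jacobian of the one-firing return map."""
    state = splay_state(params)
    J = _map_jacobian(state.x_descending(), params, 1, step)
    moduli = _per_period_moduli(J, params.N)
    return MultiplierSpectrum(moduli, np.array([]), float(moduli[0]))


def cluster_fixed_point(params: ModelParams, m: int) -> ClusterState:
    """Stationary symmetric m-cluster state of the pulse-coupled network.

    The N-oscillator system restricted to m equal clusters is an exact
    m-oscillator pulse-coupled system in which each spike applies the
    (N/m)-fold reset composition.  The state is the fixed point of the
    rotating one-firing return map, found by root search from the
    equidistant configuration.
    """
    if m < 1 or params.N % m != 0:
        raise ValueError("m must divide N")
    n_c = params.N // m
    omega = params.omega_scalar
    if m == 1:
        return ClusterState(np.array([0.0]), 1, n_c, TWO_PI / omega)

    x0 = TWO_PI * np.arange(m - 1, 0, -1) / m

    def G(x):
        fx, _ = _firing_map(x, params, n_c)
        return fx - x

    sol = root(G, x0, method="hybr", tol=1e-13)
    x = sol.x
    res = float(np.max(np.abs(G(x))))
    if res > _RESIDUAL_TOL:
        raise ValueError(
            f"cluster fixed point did not converge (residual {res:.3e})"
        )
    _, dt = _firing_map(x, params, n_c)
    psi = np.concatenate([[0.0], np.sort(x)])
    return ClusterState(psi, m, n_c, float(m * dt))


def cluster_multipliers(params: ModelParams, m: int, *,
                        delta: float = 1e-6, step: float = 1e-7) -> MultiplierSpectrum:
    """Tangential and transverse multiplier moduli of the m-cluster state.

    Tangential: eigenvalues of the reduced return-map Jacobian, raised to the
    m-th power (m firings per collective period).  Transverse: a probe neuron
    is detached from each cluster by an infinitesimal phase offset and the
    full pulse-coupled dynamics (cluster of N/m - 1 plus probe) is run for
    one period; the multiplier is the growth factor of the split.
    """
    state = cluster_fixed_point(params, m)
    n_c = state.cluster_size
    omega = params.omega_scalar

    if m == 1:
        tangential = np.array([])
    else:
        J = _map_jacobian(state.x_descending(), params, n_c, step)
        tangential = _per_period_moduli(J, m)

    transverse = []
    if n_c >= 2:
        if m == 1:
            full = np.array([0.0])
            dt_half = 0.5 * TWO_PI / omega
        else:
            full = np.concatenate([state.x_descending(), [0.0]])
            dt_half = 0.5 * (TWO_PI - full[0]) / omega
        base = full + omega * dt_half  # section halfway between firings
        T = state.period
        for k in range(base.size):
            phases = np.concatenate([base, [base[k] + delta]])
            counts = np.full(base.size + 1, n_c, dtype=int)
            counts[k] = n_c - 1
            counts[-1] = 1
            om = np.full(base.size + 1, omega)
            out, _ = _advance_free_raw(phases, om, counts, params, 0.0, T)
            split = wrap_diff(out[-1] - out[k])
            transverse.append(abs(float(split)) / delta)
    transverse = np.asarray(transverse)

    allm = np.concatenate([tangential, transverse]) if transverse.size else tangential
    return MultiplierSpectrum(tangential, transverse, float(np.max(allm)))


def extrapolate_lambda_infinity(values_by_N: dict) -> float:
    """Estimate the large-N limit of lambda_max from values at several N by a
    least-squares fit lambda(N) = lambda_inf + c / N."""
    Ns = np.array(sorted(values_by_N), dtype=float)
    lams = np.array([values_by_N[int(n)] for n in Ns])
    A = np.column_stack([np.ones_like(Ns), 1.0 / Ns])
    coef, *_ = np.linalg.lstsq(A, lams, rcond=None)
    return float(coef[0])
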