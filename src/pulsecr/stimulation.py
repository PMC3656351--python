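"""Coordinated-reset (CR) stimulation: protocols, targets, and timing optimization.

CR delivers phase-resetting stimulation through ``m`` sites, each wired to a
distinct block of N/m neurons and active exactly once per stimulation cycle
during [t_j, t_j + tau].  While a site is active its neurons follow
``dphi/dt = omega + I * Z(phi)``; for sufficiently strong intensity this flow
has a stable fixed point phi_s (the resetting point) at which the stimulated
neurons are pinned until release.

The released clusters drift and interact, so the ensemble state at the end of
the cycle, Psi(t) (one phase per site), depends on the onset vector t.  The
conventional protocol spaces the releases uniformly, which targets
equidistant clusters — but the stationary cluster states of the pulse-coupled
network are generically NOT equidistant.  ``optimize_onsets`` solves
Psi(t) = Psi* for the stationary (non-equidistant) cluster state Psi* by
derivative-free simplex search, which is appropriate because Psi(t) is only
piecewise smooth (a cluster spike crossing the cycle end produces jumps).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, linear_sum_assignment, minimize

from ._angles import TWO_PI, circ_mean, circ_spread, wrap, wrap_diff
from .model import EnsembleState, ModelParams
from .simulator import advance_stimulated
from .stationary import ClusterState, cluster_fixed_point
from .simulator import _advance_free_raw, _spike_reset

#: reference state for Psi(t): fully synchronized just below the threshold
_SYNC_EPS = 1e-9


@dataclass
class StimulationProtocol:
    """One CR stimulation cycle.

    onsets are cycle-relative (min onset 0); site j is active during
    [t_on + onsets[j], t_on + onsets[j] + tau] with intensity I, acting on
    the neuron indices in assignment[j].  The cycle ends at
    t_off = t_on + tau + max(onsets).
    """

    m: int
    onsets: np.ndarray
    tau: float
    intensity: float
    t_on: float = 0.0
    assignment: Optional[list] = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float).copy()
        if self.onsets.size != self.m:
            raise ValueError("need one onset per site")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        lo = float(self.onsets.min())
        if abs(lo) > 1e-12:
            # re-gauge: onsets are defined relative to the cycle start
            self.onsets -= lo
            self.t_on += lo

    @property
    def releases(self) -> np.ndarray:
        """Cycle-relative site release times onsets + tau."""
        return self.onsets + self.tau

    @property
    def t_off_rel(self) -> float:
        return float(self.tau + self.onsets.max())

    @property
    def t_off(self) -> float:
        return self.t_on + self.t_off_rel

    def with_sites(self, N: int) -> "StimulationProtocol":
        """Attach the contiguous-block site->neuron assignment for N neurons."""
        if N % self.m:
            raise ValueError("site count m must divide N")
        blk = N // self.m
        self.assignment = [np.arange(j * blk, (j + 1) * blk) for j in range(self.m)]
        return self

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "onsets": [float(v) for v in self.onsets],
            "tau": float(self.tau),
            "intensity": float(self.intensity),
            "t_on": float(self.t_on),
            "assignment": None if self.assignment is None
            else [[int(i) for i in idx] for idx in self.assignment],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        p = cls(d["m"], np.asarray(d["onsets"], float), d["tau"],
                d["intensity"], d.get("t_on", 0.0))
        if d.get("assignment") is not None:
            p.assignment = [np.asarray(a, dtype=int) for a in d["assignment"]]
        return p

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "StimulationProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class StimulatedFixedPoints:
    """Fixed points of the stimulated single-neuron flow omega + I Z(phi):
    phi_s stable (the resetting point), phi_u unstable."""

    phi_s: float
    phi_u: float


def stimulated_fixed_points(params: ModelParams, intensity: float,
                            grid_size: int = 8192) -> StimulatedFixedPoints:
    """Locate the unique stable/unstable pair of omega + I Z(phi) = 0.

    Errors unless the flow has exactly one such pair (zero or more than two
    sign changes on a fine grid).
    """
    omega = params.omega_scalar
    if intensity == 0.0:
        raise ValueError("no unique resetting point: intensity is zero")
    phi = np.linspace(0.0, TWO_PI, grid_size + 1)
    f = omega + intensity * params.prc(phi)
    sign_changes = np.where(f[:-1] * f[1:] < 0.0)[0]
    if sign_changes.size != 2:
        raise ValueError(
            f"no unique resetting point: {sign_changes.size} sign changes of "
            "omega + I*Z on [0, 2*pi]"
        )
    roots = []
    for i in sign_changes:
        r = brentq(lambda p: omega + intensity * params.prc(p),
                   phi[i], phi[i + 1], xtol=1e-14)
        roots.append(float(r))
    stab = [float(intensity * params.prc.derivative(r)) for r in roots]
    pairs = sorted(zip(stab, roots))
    if not (pairs[0][0] < 0.0 < pairs[1][0]):
        raise ValueError("no unique resetting point: could not classify roots")
    return StimulatedFixedPoints(phi_s=pairs[0][1], phi_u=pairs[1][1])


def uniform_protocol(params: ModelParams, m: int, tau: float, intensity: float,
                     t_on: float = 0.0) -> StimulationProtocol:
    """Conventional CR protocol (and the optimizer's initial guess).

    Site releases are spaced exactly 2*pi/(m*omega) apart.  With onset gauge
    t_1 = 0 the onset vector is (0, (m-1)*D, (m-2)*D, ..., D): site 1 is
    activated (and released) first, site 2 last, so at the cycle end site 2
    sits at the resetting point and the earlier sites have drifted to the
    equidistant slots above it.
    """
    if m < 2:
        raise ValueError("CR needs at least two stimulation sites")
    omega = params.omega_scalar
    delta = TWO_PI / (m * omega)
    onsets = np.concatenate([[0.0], delta * np.arange(m - 1, 0, -1)])
    proto = StimulationProtocol(m, onsets, tau, intensity, t_on)
    if params.N % m == 0:
        proto.with_sites(params.N)
    return proto


def resetting_map(params: ModelParams, protocol: StimulationProtocol,
                  initial: EnsembleState) -> EnsembleState:
    """Full N-dimensional resetting map Phi(t; phi): the ensemble state at the
    stimulation offset t_off, starting from ``initial`` (free dynamics are
    used up to t_on if the initial state predates it)."""
    if protocol.assignment is None:
        protocol.with_sites(params.N)
    res = advance_stimulated(initial, params, protocol, protocol.t_off,
                             sample_dt=1e9, include_start=False)
    return res.final_state


def _sync_reference(n_osc: int, t_on: float) -> EnsembleState:
    return EnsembleState(np.full(n_osc, TWO_PI - _SYNC_EPS), t_on)


def cluster_outcome(params: ModelParams, protocol: StimulationProtocol,
                    initial: Optional[EnsembleState] = None,
                    dispersion_tol: float = 1e-6) -> ClusterState:
    """Stimulation-induced cluster state Psi(t): per-site phases at t_off.

    By default the fully synchronized reference state is used, for which the
    per-site dynamics is exactly m-dimensional (every neuron of a site shares
    one phase), and the reduced system is integrated directly.  When an
    explicit initial state is given, the full N-dimensional map is run and
    the per-site circular means are returned, with an error if the
    within-site dispersion at t_off exceeds ``dispersion_tol`` (the reset was
    then too weak for the cluster reduction to be meaningful).
    """
    if params.N % protocol.m:
        raise ValueError("site count m must divide N")
    n_c = params.N // protocol.m
    if initial is None:
        ref = _sync_reference(protocol.m, protocol.t_on)
        counts = np.full(protocol.m, n_c, dtype=int)
        res = advance_stimulated(ref, params, protocol, protocol.t_off,
                                 sample_dt=1e9, counts=counts,
                                 include_start=False)
        psi = res.final_state.phases
        return ClusterState(psi.copy(), protocol.m, n_c, None)
    final = resetting_map(params, protocol, initial)
    if protocol.assignment is None:
        protocol.with_sites(params.N)
    psi = np.empty(protocol.m)
    for j, idx in enumerate(protocol.assignment):
        spread = circ_spread(final.phases[idx])
        if spread > dispersion_tol:
            raise ValueError(
                f"reset incomplete at site {j} (dispersion {spread:.2e}); "
                "increase tau or |I|"
            )
        psi[j] = circ_mean(final.phases[idx])
    return ClusterState(psi, protocol.m, n_c, None)


@dataclass
class TargetPattern:
    """Target cluster phases Psi* at the stimulation offset, one per site.

    psi_star[j] is the phase site j should occupy at t_off; the last-released
    site is anchored at the resetting point phi_s, and the others are the
    stationary-cluster phases matched to the sites by their zeroth-order
    (free-drift) predictions under the uniform protocol.
    """

    psi_star: np.ndarray
    source: ClusterState
    phi_s: float


def _stationary_snapshot_at(params: ModelParams, state: ClusterState,
                            phi_ref: float) -> np.ndarray:
    """Snapshot of the stationary cluster orbit at the moment the just-fired
    cluster reaches phase phi_ref (processing any cluster spikes en route)."""
    m = state.m
    omega = params.omega_scalar
    counts = np.full(m, state.cluster_size, dtype=int)
    om = np.full(m, omega)
    phases = np.concatenate([state.x_descending(), [0.0]]) if m > 1 \
        else np.array([0.0])
    ref = m - 1
    for _ in range(4 * m + 4):
        gap = phi_ref - phases[ref]
        if gap <= 1e-13:
            break
        dt_need = gap / omega
        dt_fire = float(np.min((TWO_PI - phases) / om))
        if dt_need < dt_fire - 1e-13:
            phases = phases + om * dt_need
            break
        dts = (TWO_PI - phases) / om
        phases = phases + om * dt_fire
        spikers = np.where(dts <= dt_fire + 1e-12)[0]
        _spike_reset(phases, spikers, counts, params, None, 0.0)
    return wrap(phases)


def build_target_pattern(params: ModelParams, m: int, tau: float,
                         intensity: float,
                         cluster_state: Optional[ClusterState] = None) -> TargetPattern:
    """Construct Psi* from the stationary m-cluster state and phi_s.

    The stationary orbit is rotated so that the just-fired cluster sits at
    phi_s (where the last-released site ends up by construction), then each
    site of the uniform protocol is matched to the circularly nearest
    stationary phase via its kappa -> 0 drift prediction.
    """
    if cluster_state is None:
        cluster_state = cluster_fixed_point(params, m)
    fps = stimulated_fixed_points(params, intensity)
    snapshot = _stationary_snapshot_at(params, cluster_state, fps.phi_s)

    proto = uniform_protocol(params, m, tau, intensity)
    omega = params.omega_scalar
    pred = wrap(fps.phi_s + omega * (proto.t_off_rel - proto.releases))
    dist = np.abs(wrap_diff(pred[:, None] - snapshot[None, :]))
    rows, cols = linear_sum_assignment(dist)
    psi_star = np.empty(m)
    psi_star[rows] = snapshot[cols]
    return TargetPattern(psi_star, cluster_state, fps.phi_s)


def optimize_onsets(params: ModelParams, m: int, tau: float, intensity: float,
                    target: Optional[TargetPattern] = None, *,
                    t_on: float = 0.0, max_restarts: int = 5,
                    maxfev: int = 2000, seed: int = 0):
    """Solve Psi(t) = Psi* for the onset vector by Nelder-Mead simplex search.

    t_1 is fixed at 0 (time-translation gauge); the search starts from the
    uniform protocol and is restarted with a small jitter when trapped (the
    objective is only piecewise smooth).  Returns (protocol, residual) where
    residual is the Euclidean norm of the wrapped phase mismatch.
    """
    if target is None:
        target = build_target_pattern(params, m, tau, intensity)
    psi_star = target.psi_star
    base = uniform_protocol(params, m, tau, intensity)

    def objective(x: np.ndarray) -> float:
        onsets = np.concatenate([[0.0], x])
        proto = StimulationProtocol(m, onsets, tau, intensity, 0.0)
        psi = cluster_outcome(params, proto).psi
        return float(np.linalg.norm(wrap_diff(psi - psi_star)))

    rng = np.random.default_rng(seed)
    x0 = base.onsets[1:].copy()
    best_x, best_f = x0, objective(x0)
    jitter_scale = 0.01 * TWO_PI / (m * params.omega_scalar)
    for attempt in range(max_restarts + 1):
        start = best_x if attempt == 0 else \
            best_x + rng.uniform(-jitter_scale, jitter_scale, best_x.size)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxfev": maxfev})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
        if best_f < 1e-6:
            break
    if best_f > 1e-4:
        warnings.warn(
            f"onset optimization residual {best_f:.3e} > 1e-4; the simplex "
            "search is possibly trapped at a discontinuity of Psi(t)"
        )
    onsets = np.concatenate([[0.0], best_x])
    proto = StimulationProtocol(m, onsets, tau, intensity, t_on)
    if params.N % m == 0:
        proto.with_sites(params.N)
    return proto, best_f


def estimate_critical_duration(params: ModelParams,
                               protocol_template: StimulationProtocol,
                               tau_grid: Sequence[float], *,
                               seeds=(101, 202), tol: float = 1e-4):
    """Smallest tau in the grid for which the stimulation outcome no longer
    depends on the pre-stimulation state (two seeded random initial states
    give per-site phases agreeing within ``tol``).  Returns None when no grid
    value suffices."""
    rngs = [np.random.default_rng(s) for s in seeds]
    inits = [EnsembleState(rng.uniform(0.0, TWO_PI, params.N), 0.0)
             for rng in rngs]
    for tau in sorted(tau_grid):
        proto = StimulationProtocol(protocol_template.m,
                                    protocol_template.onsets, float(tau),
                                    protocol_template.intensity, 0.0)
        proto.with_sites(params.N)
        try:
            outs = [cluster_outcome(params, proto, initial=ini.copy(),
                                    dispersion_tol=tol).psi for ini in inits]
        except ValueError:
            continue
        if np.max(np.abs(wrap_diff(outs[0] - outs[1]))) < tol:
            return float(tau)
    return None


def pin_time(params: ModelParams, intensity: float, phi0: float,
             tol: float = 1e-4) -> float:
    """Time for a single uncoupled stimulated neuron to reach within ``tol``
    of the resetting point phi_s, by quadrature of dphi / (omega + I Z(phi)).

    This is the exact kappa = 0 oracle for the critical stimulation duration:
    tau_c is the maximum of pin_time over the initial phases present.
    """
    omega = params.omega_scalar
    fps = stimulated_fixed_points(params, intensity)

    def speed(phi):
        return omega + intensity * params.prc(phi)

    phi0 = float(wrap(phi0))
    if abs(wrap_diff(phi0 - fps.phi_s)) <= tol:
        return 0.0
    if speed(phi0) < 0.0:
        # approaching phi_s from above
        val, _ = quad(lambda p: -1.0 / speed(p), fps.phi_s + tol, phi0,
                      limit=200)
        return float(val)
    # flowing upward: possibly through the threshold, then up to phi_s - tol
    if phi0 < fps.phi_s - tol:
        val, _ = quad(lambda p: 1.0 / speed(p), phi0, fps.phi_s - tol, limit=200)
        return float(val)
    v1, _ = quad(lambda p: 1.0 / speed(p), phi0, TWO_PI, limit=200)
    v2, _ = quad(lambda p: 1.0 / speed(p), 0.0, fps.phi_s - tol, limit=200)
    return float(v1 + v2)
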