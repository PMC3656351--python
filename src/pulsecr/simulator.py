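"""Exact event-driven and hybrid integration of the pulse-coupled ensemble.

Free network: between spikes every phase advances linearly at its natural
frequency, so the next spike time is known in closed form and the dynamics
can be integrated event by event without discretization error.

Stimulated network: while a stimulation site is active its neurons obey the
smooth flow ``dphi/dt = omega + I * Z(phi)`` in addition to the network pulse
resets, so the active epochs are integrated with an adaptive Runge-Kutta
stepper (RK45, rtol 1e-10 / atol 1e-12) and threshold crossings are located
on the dense output by root bracketing.  Spikes are emitted on upward
crossings of 2*pi only; the flow at the threshold equals omega > 0 because
the PRC vanishes there, so phases never leave [0, 2*pi).

Oscillators can carry integer multiplicities (``counts``): an oscillator of
count ``c`` stands for ``c`` perfectly synchronized neurons and its spike
applies the c-fold reset composition to the others.  This gives an exact
reduced simulation of cluster states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import RK45
from scipy.optimize import brentq

from ._angles import TWO_PI, wrap
from .model import EnsembleState, ModelParams, check_monotonicity, multi_reset

#: spikes closer in time than this are treated as simultaneous (composed mu^n)
SIMULTANEITY_TOL = 1e-12

_RTOL = 1e-10
_ATOL = 1e-12


@dataclass
class SpikeRecord:
    """Ordered spike log: times, spiking oscillator indices, and the total
    multiplicity of the simultaneous group each spike belonged to."""

    times: list = field(default_factory=list)
    indices: list = field(default_factory=list)
    group_sizes: list = field(default_factory=list)

    def add(self, t: float, idx_list, n: int) -> None:
        for j in idx_list:
            self.times.append(t)
            self.indices.append(int(j))
            self.group_sizes.append(int(n))

    def arrays(self):
        return (
            np.asarray(self.times, dtype=float),
            np.asarray(self.indices, dtype=int),
            np.asarray(self.group_sizes, dtype=int),
        )

    def extend(self, other: "SpikeRecord") -> None:
        self.times.extend(other.times)
        self.indices.extend(other.indices)
        self.group_sizes.extend(other.group_sizes)


@dataclass
class SimulationResult:
    """Sampled trajectory: times, order-parameter traces, spikes, final state."""

    times: np.ndarray
    order_params: dict
    spikes: SpikeRecord
    final_state: EnsembleState
    phases: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def order_param(self, n: int) -> np.ndarray:
        return self.order_params[n]

    def traces_table(self) -> np.ndarray:
        cols = [self.times] + [self.order_params[n] for n in sorted(self.order_params)]
        return np.column_stack(cols)

    def write_traces_csv(self, path) -> None:
        header = "time," + ",".join(f"R{n}" for n in sorted(self.order_params))
        np.savetxt(path, self.traces_table(), delimiter=",", header=header, comments="")

    def write_spikes_csv(self, path) -> None:
        t, idx, g = self.spikes.arrays()
        arr = np.column_stack([t, idx.astype(float), g.astype(float)])
        np.savetxt(
            path, arr, delimiter=",", header="time,neuron,group_size", comments="",
            fmt=["%.12g", "%d", "%d"],
        )


def order_parameter(phases, n: int = 1) -> float:
    """Kuramoto order parameter R_n = |N^-1 sum_k exp(i n phi_k)| in [0, 1].

    R_1 close to 1 signals in-phase synchrony; a high R_m together with low
    R_1 signals an m-cluster configuration.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("order parameter of an empty phase vector is undefined")
    if n < 1:
        raise ValueError("harmonic index n must be >= 1")
    return float(np.abs(np.mean(np.exp(1j * n * phases))))


class _Sampler:
    """Collects order-parameter traces on a fixed grid anchored at absolute
    multiples of the sampling interval (so stitched epochs share one grid)."""

    def __init__(self, t0, dt, order_ns, store_phases=False):
        self.dt = float(dt)
        self.order_ns = tuple(order_ns)
        self.store_phases = store_phases
        k = np.floor(t0 / self.dt + 1e-9)
        self.next_t = (k + 1) * self.dt
        self.times = []
        self.R = {n: [] for n in self.order_ns}
        self.phase_rows = [] if store_phases else None

    def _emit(self, t, phases):
        self.times.append(t)
        for n in self.order_ns:
            self.R[n].append(order_parameter(phases, n))
        if self.phase_rows is not None:
            self.phase_rows.append(wrap(np.asarray(phases, dtype=float)).copy())

    def emit_now(self, t, phases):
        self._emit(float(t), phases)

    def sample_linear(self, t, phases, omega, h, inclusive_end=True):
        """Sample the linear flight phases + omega*(ts - t) for grid points in
        (t, t + h] (or [.., t+h) when inclusive_end is False)."""
        hi = t + h + (1e-9 * self.dt if inclusive_end else -1e-9 * self.dt)
        while self.next_t <= hi:
            ts = self.next_t
            self._emit(ts, wrap(phases + omega * (ts - t)))
            self.next_t += self.dt

    def sample_dense(self, t_lo, t_hi, dense):
        hi = t_hi + 1e-9 * self.dt
        while self.next_t <= hi:
            ts = self.next_t
            self._emit(ts, wrap(dense(min(ts, t_hi))))
            self.next_t += self.dt


def _spike_reset(phases, spiker_idx, counts, params, spikes: Optional[SpikeRecord], t):
    """Apply the pulse reset for a simultaneous spike group, including the
    cascade of neurons pushed across the threshold by the reset itself."""
    N = phases.size
    is_spiker = np.zeros(N, dtype=bool)
    is_spiker[spiker_idx] = True
    pending = list(np.atleast_1d(spiker_idx))
    phases[pending] = 0.0  # the primary group crosses exactly at the threshold
    done = np.zeros(N, dtype=bool)
    while pending:
        n_group = int(counts[pending].sum())
        others = ~is_spiker & ~done
        if others.any():
            phases[others] = multi_reset(phases[others], n_group, params)
        done[pending] = True
        if spikes is not None:
            spikes.add(t, pending, n_group)
        # cascade: resets may push other phases past the threshold
        new = np.where(others & (phases >= TWO_PI))[0]
        if new.size:
            phases[new] = np.mod(phases[new], TWO_PI)
            is_spiker[new] = True
            pending = list(new)
        else:
            pending = []
    return phases


def _advance_free_raw(phases, omega, counts, params, t0, t_end,
                      sampler: Optional[_Sampler] = None,
                      spikes: Optional[SpikeRecord] = None):
    """Event-driven integration of the free network from t0 to t_end."""
    t = float(t0)
    phases = np.asarray(phases, dtype=float).copy()
    while True:
        dts = (TWO_PI - phases) / omega
        dt = float(dts.min())
        t_next = t + dt
        if t_next > t_end:
            h = t_end - t
            if sampler is not None and h > 0:
                sampler.sample_linear(t, phases, omega, h, inclusive_end=True)
            phases = phases + omega * h
            np.clip(phases, 0.0, np.nextafter(TWO_PI, 0.0), out=phases)
            return phases, t_end
        if sampler is not None:
            sampler.sample_linear(t, phases, omega, dt, inclusive_end=False)
        phases = phases + omega * dt
        spiker_idx = np.where(dts <= dt + SIMULTANEITY_TOL)[0]
        _spike_reset(phases, spiker_idx, counts, params, spikes, t_next)
        t = t_next


def _rk45_segment(phases, omega, counts, params, ta, tb, intensity_vec,
                  sampler: Optional[_Sampler] = None,
                  spikes: Optional[SpikeRecord] = None):
    """Integrate one constant-activity segment of the stimulated flow, with
    spike events located on the dense output by bisection."""
    prc = params.prc

    def rhs(t, y):
        return omega + intensity_vec * prc(y)

    t = float(ta)
    phases = np.asarray(phases, dtype=float).copy()
    while t < tb - 1e-13:
        solver = RK45(rhs, t, phases, tb, rtol=_RTOL, atol=_ATOL)
        event_hit = False
        while solver.status == "running":
            t_old = solver.t
            solver.step()
            if solver.status == "failed":
                raise RuntimeError(
                    f"adaptive step failed at t={solver.t:.6g} during stimulation"
                )
            crossed = np.where(solver.y >= TWO_PI)[0]
            if crossed.size:
                dense = solver.dense_output()
                t_cross = []
                for j in crossed:
                    f = lambda s, j=j: dense(s)[j] - TWO_PI
                    if f(t_old) >= 0.0:
                        t_cross.append(t_old)
                    else:
                        t_cross.append(brentq(f, t_old, solver.t, xtol=1e-13))
                tc = min(t_cross)
                group = [int(j) for j, tcj in zip(crossed, t_cross)
                         if tcj <= tc + SIMULTANEITY_TOL]
                if sampler is not None:
                    sampler.sample_dense(t_old, tc, dense)
                y_star = np.asarray(dense(tc), dtype=float)
                y_star[group] = TWO_PI
                np.clip(y_star, 0.0, TWO_PI, out=y_star)
                _spike_reset(y_star, np.asarray(group, dtype=int), counts,
                             params, spikes, tc)
                phases = y_star
                t = tc
                event_hit = True
                break
            if sampler is not None:
                sampler.sample_dense(t_old, solver.t, solver.dense_output())
        if not event_hit:
            phases = np.asarray(solver.y, dtype=float)
            np.clip(phases, 0.0, np.nextafter(TWO_PI, 0.0), out=phases)
            t = tb
    return phases, tb


def _advance_stim_raw(phases, omega, counts, params, t0, t_end,
                      on_times, off_times, intensity,
                      sampler=None, spikes=None):
    """Hybrid integration with per-oscillator activation windows [on, off)."""
    on_times = np.asarray(on_times, dtype=float)
    off_times = np.asarray(off_times, dtype=float)
    bps = np.unique(np.concatenate([on_times, off_times]))
    bps = bps[(bps > t0 + 1e-13) & (bps < t_end - 1e-13)]
    t = float(t0)
    for tb in list(bps) + [float(t_end)]:
        if tb <= t + 1e-13:
            continue
        tm = 0.5 * (t + tb)
        active = (on_times <= tm) & (tm < off_times)
        if active.any():
            ivec = np.where(active, float(intensity), 0.0)
            phases, t = _rk45_segment(phases, omega, counts, params, t, tb,
                                      ivec, sampler, spikes)
        else:
            phases, t = _advance_free_raw(phases, omega, counts, params, t, tb,
                                          sampler, spikes)
    return phases, float(t_end)


def _make_counts(counts, N):
    if counts is None:
        return np.ones(N, dtype=int)
    counts = np.asarray(counts, dtype=int)
    if counts.size != N or np.any(counts < 1):
        raise ValueError("counts must be positive and match the phase vector")
    return counts


def advance_free(state: EnsembleState, params: ModelParams, t_end: float,
                 sample_dt: float = 0.05, *, counts=None, order_ns=(1, 4),
                 store_phases: bool = False, include_start: bool = True,
                 check: bool = True) -> SimulationResult:
    """Integrate the free pulse-coupled network exactly from state.time to t_end.

    Refuses to run when the resetting function is not monotone (the exact
    event ordering would then be ill-defined).
    """
    if t_end <= state.time:
        raise ValueError("t_end must exceed the state time")
    if check and not check_monotonicity(params, 512):
        raise ValueError(
            "resetting function mu is not monotone for these parameters "
            "(kappa/N too large); refusing to integrate"
        )
    n_osc = state.phases.size
    counts = _make_counts(counts, n_osc)
    omega = params.omega_vector() if n_osc == params.N else \
        np.full(n_osc, params.omega_scalar)
    sampler = _Sampler(state.time, sample_dt, order_ns, store_phases)
    spikes = SpikeRecord()
    if include_start:
        sampler.emit_now(state.time, state.phases)
    phases, t = _advance_free_raw(state.phases, omega, counts, params,
                                  state.time, t_end, sampler, spikes)
    return _pack(sampler, spikes, phases, t)


def _per_neuron_windows(protocol, n_osc, N):
    """Absolute [on, off) activation window per oscillator for a protocol."""
    on = np.full(n_osc, np.inf)
    off = np.full(n_osc, np.inf)
    if n_osc == N:
        groups = protocol.assignment
    elif n_osc == protocol.m:
        groups = [np.array([j]) for j in range(protocol.m)]
    else:
        raise ValueError("state size matches neither N nor the site count m")
    for j, idx in enumerate(groups):
        on[idx] = protocol.t_on + protocol.onsets[j]
        off[idx] = protocol.t_on + protocol.onsets[j] + protocol.tau
    return on, off


def advance_stimulated(state: EnsembleState, params: ModelParams, protocol,
                       t_end: float, sample_dt: float = 0.05, *, counts=None,
                       order_ns=(1, 4), store_phases: bool = False,
                       include_start: bool = True) -> SimulationResult:
    """Integrate the stimulated network: hybrid event/ODE stepping inside the
    stimulation window, exact event-driven flow outside it."""
    if t_end <= state.time:
        raise ValueError("t_end must exceed the state time")
    n_osc = state.phases.size
    counts = _make_counts(counts, n_osc)
    omega = params.omega_vector() if n_osc == params.N else \
        np.full(n_osc, params.omega_scalar)
    on, off = _per_neuron_windows(protocol, n_osc, params.N)
    w0 = float(np.min(on))
    w1 = float(np.max(off))
    sampler = _Sampler(state.time, sample_dt, order_ns, store_phases)
    spikes = SpikeRecord()
    if include_start:
        sampler.emit_now(state.time, state.phases)
    phases = state.phases.copy()
    t = state.time
    if t < w0:
        seg_end = min(w0, t_end)
        phases, t = _advance_free_raw(phases, omega, counts, params, t,
                                      seg_end, sampler, spikes)
    if t < t_end and t < w1:
        seg_end = min(w1, t_end)
        phases, t = _advance_stim_raw(phases, omega, counts, params, t,
                                      seg_end, on, off, protocol.intensity,
                                      sampler, spikes)
    if t < t_end:
        phases, t = _advance_free_raw(phases, omega, counts, params, t,
                                      t_end, sampler, spikes)
    return _pack(sampler, spikes, phases, t)


def _pack(sampler: _Sampler, spikes: SpikeRecord, phases, t) -> SimulationResult:
    times = np.asarray(sampler.times, dtype=float)
    R = {n: np.asarray(v, dtype=float) for n, v in sampler.R.items()}
    phase_arr = (np.asarray(sampler.phase_rows, dtype=float)
                 if sampler.phase_rows is not None else None)
    final = EnsembleState(wrap(phases), float(t))
    return SimulationResult(times, R, spikes, final, phase_arr)


def concat_results(parts: Sequence[SimulationResult]) -> SimulationResult:
    """Stitch consecutive epoch results into one trace (shared sample grid)."""
    times = np.concatenate([p.times for p in parts])
    ns = sorted(parts[0].order_params)
    R = {n: np.concatenate([p.order_params[n] for p in parts]) for n in ns}
    spikes = SpikeRecord()
    for p in parts:
        spikes.extend(p.spikes)
    phases = None
    if all(p.phases is not None for p in parts):
        phases = np.concatenate([p.phases for p in parts], axis=0)
    meta = {}
    for p in parts:
        meta.update(p.meta)
    return SimulationResult(times, R, spikes, parts[-1].final_state, phases, meta)
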