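# Methods

## Model

We study `N` identical (or weakly detuned) phase oscillators on `[0, 2*pi)`
that spike when their phase crosses 2*pi and are globally pulse-coupled:
a spike instantaneously maps every other phase by the resetting function

    mu(phi) = phi + (kappa/N) Z(phi),

where `Z` is the phase response curve and `kappa` the total coupling
strength. When `n` neurons spike simultaneously, the others receive the
n-fold composition `mu^n`; this choice (rather than adding `n` increments)
keeps the dynamics continuous as clusters split, since staggered resets
`mu(tau_1 + mu(...))` converge to `mu^n` as the stagger vanishes. We assume
`Z(0) = Z(2*pi) = 0` (the response at the spike phase is negligible because
the vector field is large there), which also guarantees that the flow at the
threshold equals `omega > 0`, so phases never cross the threshold backwards
and no "anti-spike" convention is ever needed. `mu` must be monotone
(`1 + (kappa/N) Z'(phi) > 0`), which `check_monotonicity` verifies before
event-driven integration; monotone `mu` preserves the cyclic phase order.

Stimulation through `m` sites adds a smooth drift: while site `j` is active
during `[t_j, t_j + tau]`, its `N/m` neurons obey
`dphi/dt = omega + I Z(phi)` in addition to the network pulses. For
sufficiently large `|I|` this flow has exactly one stable/unstable fixed
point pair `(phi_s, phi_u)`; stimulated neurons are pinned at the resetting
point `phi_s` and released when the site deactivates.

## Numerical integration

Free epochs are integrated exactly, event by event: between spikes every
phase advances linearly, so the next spike time is `min_j (2*pi - phi_j) /
omega_j` in closed form. Spikes within 1e-12 time units are treated as one
simultaneous group (exact ties arise from synchronized and cluster initial
conditions); resets that push another phase across the threshold trigger a
cascade handled at the same time instant.

Stimulated epochs use an adaptive Runge-Kutta stepper (scipy's RK45,
rtol 1e-10, atol 1e-12) restarted at every event. Threshold crossings are
located on the dense output by root bracketing to 1e-13; site on/off
switches are integration breakpoints. The tolerances are deliberately tight
because the stimulation outcome map is only piecewise smooth — whether a
cluster spike falls just before or just after the cycle end changes the
outcome discontinuously — so event times must be sharp. Order parameters
`R_n = |N^-1 sum_k exp(i n phi_k)|` are sampled on a fixed grid
(default `sample_dt = 0.05`, fine enough to resolve the small-scale
oscillations the trajectories show at each threshold crossing) anchored at
absolute multiples of the interval so that stitched epochs share one grid.

Oscillators may carry integer multiplicities ("counts"): an oscillator with
count `c` represents `c` perfectly synchronized neurons and its spike
applies `mu^c`. Because every neuron of a site receives identical input,
the stimulation outcome from a fully synchronized reference state is
*exactly* reproduced by the m-oscillator reduced system; `cluster_outcome`
exploits this, and the equivalence to the full N-dimensional map is tested.

## Stationary states

The stationary density of the pulse-coupled continuity equation satisfies
flux balance `rho_s(phi) * (omega + kappa Z(phi) rho_s(0)) = const`; the
scalar unknown `rho_s(0)` solves an implicit normalization equation by
bracketed root search on `[1e-6, 10/(2*pi)]` (expanded geometrically, and
capped where the drift would lose positivity). Quadratures use the
composite trapezoid on 4096-point uniform grids — spectrally accurate for
smooth periodic integrands. The first-order expansion
`1/(2*pi) + kappa (Zbar - Z(phi)) / ((2*pi)^2 omega)` is kept as a separate
function; the package tests that the gap between the two shrinks
quadratically in `kappa`.

Splay states (equal intervals between consecutive ensemble spikes) are
located by a scalar self-consistency equation: in a splay state every neuron
experiences the same periodic history — drift one inter-spike interval,
receive one pulse — so following a single neuron from its own spike through
`N-1` pulses and requiring it to reach 2*pi after the N-th drift determines
the interval by a one-dimensional bracketed root search. This replaces an
(N-1)-dimensional root search, is well conditioned at any N, and the result
is verified to be a fixed point of the full rotating return map to 1e-8.

Symmetric m-cluster states are fixed points of the rotating one-firing
return map of the exact m-oscillator reduction (pulse weight `mu^(N/m)`),
found by a quasi-Newton root search from the equidistant configuration with
residual tolerance 1e-10. The collective period is `m` times the firing
interval at the fixed point.

Multipliers are reported per collective period (one spike of every neuron),
so `|lambda_max| > 1` means a perturbation grows from one spike of a neuron
to its next: the one-firing return-map Jacobian (central finite differences,
step 1e-7) has its eigenvalue moduli raised to the N-th (splay) or m-th
(cluster) power. Transverse cluster multipliers detach a probe neuron from
each cluster by 1e-6 rad on a section halfway between firings (so that
events never straddle the measurement times) and measure the growth of the
split over one period under the full pulse dynamics; this single-probe
construction is equivalent to the full transverse block for identical
neurons by permutation symmetry. The large-N limit `lambda_inf` can be
estimated by a least-squares `lambda + c/N` fit over several N.

## CR timing optimization

The uniform protocol spaces site *releases* exactly `2*pi/(m*omega)` apart,
with the onset gauge `t_1 = 0` (onset vector `(0, (m-1)D, ..., D)`): site 1
is released first and drifts to the highest slot, the last-released site
ends at `phi_s`. The target pattern `Psi*` is the stationary m-cluster
state rotated so the just-fired cluster sits at `phi_s` (propagating the
orbit, with any en-route cluster spikes processed); each site is matched to
the circularly nearest target phase via its zeroth-order free-drift
prediction under the uniform protocol — a clean bijection because the
stationary phases deviate from equidistance only at O(kappa).

`optimize_onsets` minimizes the Euclidean norm of the component-wise
circularly wrapped difference `Psi(t) - Psi*` over `(t_2, ..., t_m)` by
Nelder-Mead (xatol 1e-10, fatol 1e-12, up to 2000 evaluations), restarted
up to five times from the best point jittered by 1% of `2*pi/(m*omega)`
when the residual exceeds 1e-4, because the objective is only piecewise
smooth. The wrapped norm avoids spurious 2*pi penalties; the reference
state for `Psi(t)` is the fully synchronized ensemble just below threshold
(synchrony is the pre-stimulus condition in all experiments, and
independence from the initial state above the critical duration is verified
separately). Psi(t) is evaluated on the exact m-oscillator reduction, so
one objective evaluation costs milliseconds.

The critical duration `tau_c` is estimated as the smallest grid value for
which two seeded random initial states give outcomes agreeing within 1e-4
per phase. For `kappa = 0` this has an exact oracle: the pinning time of
the slowest neuron by quadrature of `dphi / (omega + I Z)`, which the tests
use. Note the outcome map has genuine discontinuity points (e.g. parameter
combinations for which a cluster's post-release spike coincides exactly
with the cycle end); at such points initial-state independence fails at any
duration, which is a property of the dynamics, not of the estimator.

## Synthetic inputs and what they do (not) show

Initial phases are drawn uniformly on `[0, 2*pi)` and natural frequencies
uniformly on `[1 - dw, 1 + dw]`, each from an independent named substream of
a single seed, so detuning sweeps vary only the frequencies. These inputs
emulate an initially incoherent population that synchronizes through the
pulse coupling before stimulation; they contain no measurement noise,
heterogeneous coupling, conduction delays, or plasticity, so passing tests
demonstrate correctness of the model's dynamics and of the timing
optimization, not clinical efficacy.

The tabulated Morris-Lecar-like PRC shipped as `ml_like_prc()` is a
synthetic surrogate — a three-harmonic curve with a type-I-like dominant
positive hump, a small negative lobe after the spike, and a slightly
negative slope at the spike phase. It exercises every tabulated-PRC code
path and shows the same structural phenomena (non-equidistant stationary
clusters, onset gaps a few percent off uniform, anchoring of the last
cluster at `phi_s`), but numbers tied to the true Morris-Lecar curve
(specific target phases, `tau_c` values, which m is stable) are
surrogate-dependent.

## Transient metric and experiment sizes

The post-stimulation desynchronization transient is the time from the
stimulation offset until `R1` exceeds `theta = 0.9` and stays above it for
the rest of the horizon; the threshold is ours (no standard definition
exists) and `0.9` is robust to the small-scale oscillations of the order
parameter. The horizon defaults to ten times the observed pre-stimulation
synchronization time; censored transients (no resynchronization) are scored
at the horizon, a conservative lower bound. Protocol comparisons reuse the
same pre-stimulation trajectory per seed for both protocols, so the ratio
reflects timing only.

Reference experiments use `N = 240`, `omega = 1`, `kappa = 0.5`, `m = 4`,
`tau = 10`, `|I| = 10`, `t_on = 250`; the cluster states are insensitive to
N beyond ~100. Validation against the fixed-step brute-force oracle uses
`N = 5`, `T = 50`, step 1e-5; stability cross-checks use `N = 20` over 20
periods; sweep drivers default to a coarser `sample_dt = 0.25` since they
produce heat-map matrices rather than precise event statistics. Sweeps
compute optimized onsets once at reference parameter values and reuse them
across the grid — the sweep then probes robustness of a single timing
pattern, mirroring how detuning robustness is assessed (onsets from the
homogeneous system applied to detuned ensembles).

## Known limitations

* Only first-order PRCs and instantaneous pulses; no delays, no
  spike-timing-dependent plasticity, no repeated ON-OFF CR cycling.
* The optimizer assumes one activation per site per cycle and equal group
  sizes; `m` must divide `N`.
* Near discontinuities of the outcome map the simplex search can stall at
  residuals above 1e-4 (it warns); jittered restarts usually escape.
* Transverse multipliers require at least two neurons per cluster
  (`N/m >= 2`); for `N = m` the transverse list is empty.
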