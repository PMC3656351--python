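"""Independent brute-force oracle for the pulse-coupled dynamics.

A fixed-step integrator that advances all phases linearly by a small step dt
and applies the pulse resets whenever phases cross the threshold within a
step.  It shares no code with the event-driven simulator (events are
quantized to the step instead of being located exactly), so agreement between
the two validates the event logic.  The PRC is passed as a dense lookup
table so the loop can be jit-compiled.
"""

import numba
import numpy as np

TWO_PI = 2.0 * np.pi


@numba.njit(cache=False)
def _brute_force_loop(phases, omega, weight, z_grid, z_vals, dt, n_steps):
    n = phases.size
    for _ in range(n_steps):
        phases = phases + omega * dt
        n_spikers = 0
        for j in range(n):
            if phases[j] >= TWO_PI:
                n_spikers += 1
        if n_spikers:
            for j in range(n):
                if phases[j] >= TWO_PI:
                    phases[j] -= TWO_PI
                else:
                    for _k in range(n_spikers):
                        z = np.interp(phases[j], z_grid, z_vals)
                        phases[j] += weight * z
    return phases


def brute_force_free(phases, params, t_end, dt=1e-5):
    """Integrate the free network with fixed step dt from t=0 to t_end."""
    grid = np.linspace(0.0, TWO_PI, 65537)
    z_vals = np.asarray(params.prc(grid), dtype=float)
    omega = np.asarray(params.omega, dtype=float) * np.ones(len(phases))
    n_steps = int(round(t_end / dt))
    return _brute_force_loop(
        np.asarray(phases, dtype=float).copy(), omega,
        params.kappa / params.N, grid, z_vals, dt, n_steps,
    )
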