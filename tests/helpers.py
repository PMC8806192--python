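"""Independent oracles shared by the unit and acceptance suites."""

import numpy as np


def lattice_decay_search(t, y, onset_grid, n_points: int = 201):
    """Exhaustive dense-lattice fit of the two-phase decay model.

    Evaluates the SSE on a (m0, steady-state, gamma) lattice at every onset
    of ``onset_grid`` and returns (min SSE, argmin onset).  The model
    m = ss*(1-E) + m0*E with E = exp(-gamma*(t-onset)+) lets the SSE over
    the (m0, ss) plane expand into inner products of u=E and v=1-E, so the
    whole lattice is evaluated exactly without forming the full tensor.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    m0_grid = np.linspace(0.2 * y.max(), 1.3 * y.max(), n_points)
    ss_grid = np.linspace(0.0, y.max(), n_points)
    gamma_grid = np.geomspace(1e-3, 0.2, n_points)
    a = m0_grid[:, None]
    b = ss_grid[None, :]
    syy = float(y @ y)
    best = (np.inf, None)
    for onset in onset_grid:
        dt = np.clip(t - onset, 0.0, None)
        for g in gamma_grid:
            u = np.exp(-g * dt)
            v = 1.0 - u
            sse = (a**2 * (u @ u) + b**2 * (v @ v) + 2 * a * b * (u @ v)
                   - 2 * a * (u @ y) - 2 * b * (v @ y) + syy)
            m = float(sse.min())
            if m < best[0]:
                best = (m, float(onset))
    return best
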