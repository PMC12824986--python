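"""Brute-force reference implementations, independent of the package's fitters.

Used only to cross-check results: a profiled grid search over the decay
rate (with A, b solved linearly at each grid point), a 1-D grid search
for the zero-order phase, and a direct DFT magnitude spectrum.
"""

import numpy as np


def grid_search_alpha(t, y, alpha_lo, alpha_hi, step=1e-4):
    """Best decay rate on a regular grid; A and b solved by linear LS.

    Returns (alpha, a, b) minimizing sum((a*exp(-alpha*t) + b - y)^2).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    alphas = np.arange(alpha_lo, alpha_hi + step, step)
    e = np.exp(-np.outer(alphas, t))  # (n_grid, n_points)
    n = t.size
    se = e.sum(axis=1)
    see = (e * e).sum(axis=1)
    sy = y.sum()
    sey = e @ y
    det = see * n - se * se
    a = (sey * n - se * sy) / det
    b = (see * sy - se * sey) / det
    sse = (y * y).sum() - a * sey - b * sy  # residual SS via normal equations
    k = int(np.argmin(sse))
    return float(alphas[k]), float(a[k]), float(b[k])


def grid_search_phase(signal, step=1e-5, window_frac=0.5):
    """Phase minimizing total squared imaginary power over the early window."""
    n = max(3, int(round(window_frac * signal.size)))
    s = np.asarray(signal)[:n]
    phis = np.arange(-np.pi, np.pi, step)
    # |Im(s * exp(-i phi))|^2 summed; vectorized over the grid.  The
    # objective is pi-periodic: keep the branch with a positive rotated
    # real channel (a decay, not its negation).
    rot = np.outer(np.exp(-1j * phis), s)
    power = (rot.imag**2).sum(axis=1)
    power[rot.real.sum(axis=1) <= 0] = np.inf
    return float(phis[int(np.argmin(power))])


def dft_magnitudes(y, dt):
    """(frequencies, magnitudes) of the one-sided DFT, computed directly."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ks = np.arange(n // 2 + 1)
    freqs = ks / (n * dt)
    w = np.exp(-2j * np.pi * np.outer(ks, np.arange(n)) / n)
    return freqs, np.abs(w @ y)
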