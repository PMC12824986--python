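import numpy as np
import pytest

from wnmr.io import AcquisitionMeta, DecayTrace
from wnmr.synth import LabProfile


def make_trace(t, real, imag=None, quadrature=None, **meta_kw):
    """Build a DecayTrace from plain arrays."""
    t = np.asarray(t, dtype=float)
    real = np.asarray(real, dtype=float)
    if imag is None:
        signal = real.astype(complex)
        quad = False if quadrature is None else quadrature
    else:
        signal = real + 1j * np.asarray(imag, dtype=float)
        quad = True if quadrature is None else quadrature
    meta = AcquisitionMeta(tau=float(t[0]) / 2.0, **meta_kw)
    return DecayTrace(time=t, signal=signal, is_quadrature=quad, meta=meta)


def decay_trace(alpha, a=100.0, b=1.0, n=200, t_max=None, noise_sd=0.0,
                seed=0, quadrature=True):
    """A mono-exponential test trace with optional complex Gaussian noise."""
    if t_max is None:
        t_max = 4.0 / alpha
    t = np.linspace(t_max / n, t_max, n)
    clean = a * np.exp(-alpha * t) + b
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        sig = clean + rng.normal(0, noise_sd, n) + 1j * rng.normal(0, noise_sd, n)
    else:
        sig = clean.astype(complex) + (0j if quadrature else 0)
    if not quadrature:
        sig = sig.real.astype(complex)
    meta = AcquisitionMeta(tau=float(t[0]) / 2.0)
    return DecayTrace(time=t, signal=sig, is_quadrature=quadrature, meta=meta)


@pytest.fixture
def clean_profile():
    """A fast, artifact-free time-domain lab for recovery experiments."""
    return LabProfile("CleanLab", tau=2000e-6, n_echoes=1500, n_scans=16,
                      noise_sd=1.0)
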