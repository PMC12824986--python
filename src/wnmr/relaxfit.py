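"""Offset mono-exponential fitting: S(t) = A*exp(-alpha*t) + b.

The decay rate alpha is the water-proton transverse relaxation rate
R2(1H2O) in s^-1 (T2 = 1/alpha); b is an offset compensating signals that
decay to nonzero values.  Fits run on the real channel (after phase
correction) by nonlinear least squares with an analytic Jacobian;
magnitude fitting is deliberately avoided because the Rician noise floor
biases the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FlatSignalError, InsufficientDataError
from .io import DecayTrace

__all__ = [
    "FitConfig",
    "FitResult",
    "initial_guess",
    "fit_monoexponential",
    "correction_impact",
    "correction_impact_rms",
    "departure_metric",
    "DEFAULT_DEPARTURE_THRESHOLD",
]

#: residual_rms / noise_sd above which multi-exponential behaviour is suspected
DEFAULT_DEPARTURE_THRESHOLD = 2.0


@dataclass(frozen=True)
class FitConfig:
    """Numerical settings for the nonlinear fit (one object holds them all)."""

    xtol: float = 1e-12  # relative parameter tolerance
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 200  # iteration budget


@dataclass(frozen=True)
class FitResult:
    """Parameters and diagnostics of one offset mono-exponential fit."""

    amplitude: float  # A, echo intensity at t = 0
    alpha: float  # decay rate, s^-1 == R2(1H2O)
    offset: float  # b
    param_se: tuple[float, float, float] | None  # SEs for (A, alpha, b)
    residual_rms: float
    n_points: int
    converged: bool
    flags: tuple[str, ...] = field(default=())

    @property
    def t2(self) -> float:
        """Transverse relaxation time T2 = 1/alpha, seconds."""
        return 1.0 / self.alpha


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, alpha, b = params
    return a * np.exp(-alpha * t) + b


def initial_guess(trace: DecayTrace) -> tuple[float, float, float]:
    """Starting values (A0, alpha0, b0) for the nonlinear fit.

    b0 is the mean of the last 5% of points (at least 2); A0 the first
    point minus b0; alpha0 comes from a log-linear regression of
    (signal - b0) over points standing 3x above the local noise floor.
    Raises FlatSignalError when no decay is resolvable.
    """
    t = trace.time
    y = trace.real
    n = y.size
    n_tail = max(2, int(np.ceil(0.05 * n)))
    tail = y[-n_tail:]
    b0 = float(np.mean(tail))
    # local noise floor from the tail spread (robust, zero for noiseless data)
    floor = 1.4826 * float(np.median(np.abs(tail - np.median(tail))))
    a0 = float(y[0] - b0)

    excess = y - b0
    mask = excess > max(3.0 * floor, 1e-12 * max(abs(a0), 1.0))
    if mask.sum() < 2 or a0 <= 0:
        raise FlatSignalError(
            "no resolvable decay: signal is flat relative to its noise floor"
        )
    slope = np.polyfit(t[mask], np.log(excess[mask]), 1)[0]
    alpha0 = float(-slope)
    if not np.isfinite(alpha0) or alpha0 <= 0:
        # fall back to a rate that decays once over the observed span
        alpha0 = 1.0 / (t[-1] - t[0])
    return a0, alpha0, b0


def fit_monoexponential(
    trace: DecayTrace,
    guess: tuple[float, float, float] | None = None,
    config: FitConfig | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit S(t) = A*exp(-alpha*t) + b to the trace's real channel.

    Unweighted least squares by default; optional ``weights`` are
    inverse-variance weights applied per point.  Non-convergence or a
    nonpositive decay rate is flagged on the result, not raised.
    """
    if trace.n_points < 4:
        raise InsufficientDataError(
            "need >= 4 points for a 3-parameter fit with a residual dof"
        )
    cfg = config or FitConfig()
    t = trace.time
    y = trace.real
    sw = np.sqrt(weights) if weights is not None else None

    p0 = np.asarray(guess if guess is not None else initial_guess(trace), dtype=float)

    def residuals(p):
        r = _model(p, t) - y
        return r * sw if sw is not None else r

    def jac(p):
        a, alpha, b = p
        e = np.exp(-alpha * t)
        j = np.column_stack([e, -a * t * e, np.ones_like(t)])
        return j * sw[:, None] if sw is not None else j

    res = least_squares(
        residuals, p0, jac=jac,
        xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol, max_nfev=cfg.max_nfev,
        method="lm" if t.size >= 3 else "trf",
    )
    a, alpha, b = (float(v) for v in res.x)

    flags: list[str] = []
    converged = bool(res.status > 0)
    if not converged:
        flags.append("max_iterations")
    if alpha <= 0:
        flags.append("alpha_nonpositive")
        converged = False

    r = _model(res.x, t) - y
    residual_rms = float(np.sqrt(np.mean(r**2)))

    param_se = None
    dof = t.size - 3
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (float(r @ r) / dof)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                param_se = tuple(float(s) for s in np.sqrt(diag))
        except np.linalg.LinAlgError:
            flags.append("singular_jacobian")

    return FitResult(
        amplitude=a, alpha=alpha, offset=b,
        param_se=param_se, residual_rms=residual_rms,
        n_points=int(t.size), converged=converged, flags=tuple(flags),
    )


def correction_impact(fit_before: FitResult, fit_after: FitResult) -> float:
    """Percent change of the fitted rate due to a correction step.

    100 * |alpha_after - alpha_before| / alpha_before.
    """
    if fit_before.alpha <= 0:
        raise DomainError("alpha before correction must be > 0")
    return 100.0 * abs(fit_after.alpha - fit_before.alpha) / fit_before.alpha


def correction_impact_rms(percent_changes) -> float:
    """RMS of per-trace percent changes, the aggregate correction impact."""
    pcts = np.asarray(list(percent_changes), dtype=float)
    if pcts.size == 0:
        raise DomainError("need at least one percent change")
    return float(np.sqrt(np.mean(pcts**2)))


def departure_metric(fit: FitResult, noise_sd: float) -> float:
    """Ratio residual_rms / noise_sd, a departure-from-monoexponential score.

    ~1 for a well-described mono-exponential decay; values above
    DEFAULT_DEPARTURE_THRESHOLD suggest multi-exponential relaxation.
    A zero noise_sd with nonzero residual returns +inf.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if noise_sd == 0.0:
        return 0.0 if fit.residual_rms == 0.0 else float("inf")
    return fit.residual_rms / noise_sd
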