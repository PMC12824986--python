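"""Interlaboratory study statistics over fitted R2(1H2O) values.

Per lab and sample class, R2 is regressed on concentration to give the
relaxivity calibration R2(C) = R2,0 + r2*C (slope r2 = relaxivity).
Across labs the dispersion of relaxivities is summarized by the span
(max - min) and the coefficient of variance CV = (sigma/mu)*100%.
Freeze/thaw stressed vials are compared against their unstressed mates by
%change = [1 - R2(frozen)/R2(unfrozen)]*100, flagged against the larger
of a fixed threshold (default 10%) and an error band propagated from the
calibration's RMSD.  ETFE particle series act as negative controls whose
relaxivity must be consistent with zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, IntegrityError
from .io import StudyManifest
from .relaxfit import FitResult

__all__ = [
    "RelaxivityFit",
    "OutlierAssessment",
    "StudyReport",
    "fit_relaxivity",
    "slope_span",
    "relaxivity_cv",
    "cv_from_stats",
    "slope_stats",
    "freeze_thaw_change",
    "assess_outlier",
    "zero_slope_test",
    "build_report",
]

#: classes whose concentration series define a calibration line
CALIBRATION_CLASSES = ("mAb", "AH", "AP", "ETFE")


@dataclass(frozen=True)
class RelaxivityFit:
    """Linear calibration of R2 against concentration for one lab/class."""

    lab_id: str
    sample_class: str
    slope: float  # relaxivity r2, (mg/mL)^-1 s^-1
    intercept: float  # R2,0, s^-1
    slope_se: float | None  # absent for a 2-point exact interpolation
    rmsd: float  # RMS of measured R2 minus the line, s^-1
    n_points: int

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass(frozen=True)
class OutlierAssessment:
    """Freeze/thaw comparison of one stressed vial against its mate."""

    lab_id: str
    sample_class: str
    ratio: float  # R2(frozen) / R2(unfrozen)
    percent_change: float  # (1 - ratio) * 100; positive = decrease
    band_halfwidth: float  # % band from the calibration RMSD
    flagged: bool
    direction: str  # decrease | increase | none

    def __post_init__(self):
        if not math.isclose(self.percent_change, (1.0 - self.ratio) * 100.0,
                            rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("percent_change must equal (1 - ratio)*100")


@dataclass(frozen=True)
class StudyReport:
    """Aggregate of the whole interlab analysis."""

    relaxivity_table: tuple[RelaxivityFit, ...]
    span: dict[str, float]  # class -> max-min of slopes across labs
    cv: dict[str, float]  # class -> CV %, across labs
    outliers: tuple[OutlierAssessment, ...]
    control_tests: dict[str, dict[str, str]]  # class -> lab -> verdict
    anomalies: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def relaxivity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lab_id": f.lab_id,
                    "sample_class": f.sample_class,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "slope_se": f.slope_se,
                    "rmsd": f.rmsd,
                    "n_points": f.n_points,
                }
                for f in self.relaxivity_table
            ]
        )

    def outlier_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lab_id": o.lab_id,
                    "sample_class": o.sample_class,
                    "ratio": o.ratio,
                    "percent_change": o.percent_change,
                    "band_halfwidth": o.band_halfwidth,
                    "flagged": o.flagged,
                    "direction": o.direction,
                }
                for o in self.outliers
            ]
        )

    def to_json_dict(self) -> dict:
        return {
            "relaxivity_table": self.relaxivity_frame().to_dict(orient="records"),
            "span": self.span,
            "cv": self.cv,
            "outliers": self.outlier_frame().to_dict(orient="records"),
            "control_tests": self.control_tests,
            "anomalies": list(self.anomalies),
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# elementary statistics


def fit_relaxivity(
    points: Sequence[tuple],
    lab_id: str = "",
    sample_class: str = "",
) -> RelaxivityFit:
    """OLS calibration line through (concentration, R2) points.

    ``points`` are (concentration, r2) or (concentration, r2, se) tuples.
    The line itself is always unweighted OLS and rmsd is sqrt(mean squared
    residual).  When every point carries a standard error from its decay
    fit, slope_se propagates those known per-point variances through the
    OLS slope (Var(b) = sum((x-xbar)^2 se^2)/Sxx^2), which keeps the
    zero-slope criterion calibrated even for short series; otherwise
    slope_se falls back to the residual-based OLS formula and is absent
    for the 2-point exact fit.
    """
    conc = np.asarray([p[0] for p in points], dtype=float)
    r2 = np.asarray([p[1] for p in points], dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise DomainError(
            "relaxivity fit needs >= 2 points at distinct concentrations"
        )
    ses = [p[2] if len(p) > 2 else None for p in points]
    have_ses = all(s is not None for s in ses)

    def _propagated_se(slope_points: np.ndarray) -> float:
        se = np.asarray(ses, dtype=float)
        xc = slope_points - slope_points.mean()
        sxx = float((xc**2).sum())
        return float(np.sqrt(((xc * se) ** 2).sum()) / sxx)

    if np.unique(conc).size == conc.size == 2:
        slope = float((r2[1] - r2[0]) / (conc[1] - conc[0]))
        intercept = float(r2[0] - slope * conc[0])
        slope_se = _propagated_se(conc) if have_ses else None
        return RelaxivityFit(lab_id, sample_class, slope, intercept,
                             slope_se=slope_se, rmsd=0.0, n_points=2)
    model = sm.OLS(r2, sm.add_constant(conc)).fit()
    resid = np.asarray(model.resid)
    rmsd = float(np.sqrt(np.mean(resid**2)))
    if have_ses:
        slope_se = _propagated_se(conc)
    else:
        slope_se = float(model.bse[1]) if conc.size > 2 else None
    return RelaxivityFit(
        lab_id, sample_class,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_se=slope_se, rmsd=rmsd, n_points=int(conc.size),
    )


def slope_span(slopes: Iterable[float]) -> float:
    """max - min of a set of relaxivities (same units as the slopes)."""
    arr = np.asarray(list(slopes), dtype=float)
    if arr.size == 0:
        raise DomainError("span of an empty slope set is undefined")
    return float(arr.max() - arr.min())


def slope_stats(slopes: Iterable[float], ddof: int = 1) -> tuple[float, float]:
    """(mean, standard deviation) of relaxivities; sample sd by default."""
    arr = np.asarray(list(slopes), dtype=float)
    if arr.size < 2:
        raise DomainError("need >= 2 slopes for dispersion statistics")
    return float(arr.mean()), float(arr.std(ddof=ddof))


def cv_from_stats(mu: float, sigma: float) -> float:
    """CV = (sigma/mu)*100%, directly from summary statistics."""
    if mu == 0:
        raise DomainError("CV undefined for zero mean")
    return 100.0 * sigma / mu


def relaxivity_cv(slopes: Iterable[float], ddof: int = 1) -> float:
    """Coefficient of variance of relaxivities across labs, percent."""
    mu, sigma = slope_stats(slopes, ddof=ddof)
    return cv_from_stats(mu, sigma)


def freeze_thaw_change(r2_frozen: float, r2_unfrozen: float) -> float:
    """%R2 change = [1 - R2(frozen)/R2(unfrozen)] * 100; positive = decrease."""
    if r2_unfrozen <= 0:
        raise DomainError("unfrozen R2 must be > 0")
    return (1.0 - r2_frozen / r2_unfrozen) * 100.0


def _r2_of(value) -> float:
    return value.alpha if isinstance(value, FitResult) else float(value)


def assess_outlier(
    pair: tuple,
    calib: RelaxivityFit,
    threshold: float = 10.0,
    *,
    lab_id: str | None = None,
    sample_class: str | None = None,
) -> OutlierAssessment:
    """Flag a stressed vial whose R2 moved outside the error band.

    ``pair`` is (frozen, unfrozen) as FitResults or bare rates.  The band
    half-width projects the calibration RMSD onto the ratio scale at the
    unfrozen rate; the flag fires when |%change| exceeds the larger of the
    fixed ``threshold`` and that band.
    """
    if lab_id is not None and lab_id != calib.lab_id:
        raise IntegrityError(f"calibration is for {calib.lab_id!r}, pair for {lab_id!r}")
    if sample_class is not None and sample_class != calib.sample_class:
        raise IntegrityError(
            f"calibration is for class {calib.sample_class!r}, pair for {sample_class!r}"
        )
    r2_frozen = _r2_of(pair[0])
    r2_unfrozen = _r2_of(pair[1])
    pct = freeze_thaw_change(r2_frozen, r2_unfrozen)
    band = 100.0 * calib.rmsd / r2_unfrozen
    flagged = abs(pct) > max(threshold, band)
    direction = "decrease" if pct > 0 else ("increase" if pct < 0 else "none")
    return OutlierAssessment(
        lab_id=calib.lab_id, sample_class=calib.sample_class,
        ratio=r2_frozen / r2_unfrozen, percent_change=pct,
        band_halfwidth=band, flagged=flagged, direction=direction,
    )


def zero_slope_test(calib: RelaxivityFit) -> str:
    """Negative-control verdict: is the slope consistent with zero?

    consistent_with_zero when |slope| <= 2*slope_se; indeterminate when no
    standard error is available (2-point fit).
    """
    if calib.slope_se is None:
        return "indeterminate"
    return "consistent_with_zero" if abs(calib.slope) <= 2.0 * calib.slope_se else "nonzero"


# ---------------------------------------------------------------------------
# whole-study aggregation


def build_report(
    fits: Mapping[tuple[str, str], FitResult] | Iterable[tuple[str, str, FitResult]],
    manifest: StudyManifest,
    *,
    threshold: float = 10.0,
    ddof: int = 1,
    provenance: dict | None = None,
) -> StudyReport:
    """Aggregate per-trace fits into the full interlab study report.

    ``fits`` maps (lab_id, sample_code) to a FitResult, or is an iterable
    of (lab_id, sample_code, FitResult) records; duplicate records for the
    same vial are resolved in favour of the later submission and logged as
    an anomaly.  Buffer vials enter the mAb series as 0 mg/mL points.
    """
    anomalies: list[str] = []

    records: dict[tuple[str, str], FitResult] = {}
    if isinstance(fits, Mapping):
        items = [(lab, code, fr) for (lab, code), fr in fits.items()]
    else:
        items = list(fits)
    for lab, code, fr in items:
        if (lab, code) in records:
            anomalies.append(
                f"duplicate measurement for ({lab}, {code}); using the later submission"
            )
        records[(lab, code)] = fr

    labs: list[str] = []
    for lab, _ in records:
        if lab not in labs:
            labs.append(lab)

    def series_class(entry) -> str:
        # buffer is the 0 mg/mL point of the mAb concentration series
        return "mAb" if entry.sample_class == "buffer" else entry.sample_class

    calibs: dict[tuple[str, str], RelaxivityFit] = {}
    table: list[RelaxivityFit] = []
    for lab in labs:
        for cls in CALIBRATION_CLASSES:
            pts = []
            for entry in manifest:
                if entry.stressed or series_class(entry) != cls:
                    continue
                fr = records.get((lab, entry.sample_code))
                if fr is None:
                    continue
                if not fr.converged:
                    anomalies.append(
                        f"non-converged fit for ({lab}, {entry.sample_code}) "
                        "excluded from calibration"
                    )
                    continue
                alpha_se = fr.param_se[1] if fr.param_se else None
                pts.append((entry.concentration, fr.alpha, alpha_se))
            if len(pts) >= 2 and len({p[0] for p in pts}) >= 2:
                calib = fit_relaxivity(pts, lab_id=lab, sample_class=cls)
                calibs[(lab, cls)] = calib
                table.append(calib)

    span: dict[str, float] = {}
    cv: dict[str, float] = {}
    for cls in CALIBRATION_CLASSES:
        slopes = [c.slope for (lab, c_cls), c in calibs.items() if c_cls == cls]
        if slopes:
            span[cls] = slope_span(slopes)
        if len(slopes) >= 2 and np.mean(slopes) != 0:
            cv[cls] = relaxivity_cv(slopes, ddof=ddof)

    outliers: list[OutlierAssessment] = []
    for entry in manifest:
        if not entry.stressed:
            continue
        mates = [
            e for e in manifest
            if not e.stressed
            and e.sample_class == entry.sample_class
            and e.concentration == entry.concentration
        ]
        for lab in labs:
            frozen = records.get((lab, entry.sample_code))
            unfrozen = records.get((lab, mates[0].sample_code)) if mates else None
            calib = calibs.get((lab, entry.sample_class))
            if frozen is None or unfrozen is None or calib is None:
                anomalies.append(
                    f"stressed vial {entry.sample_code} unassessable for {lab}: "
                    "missing unstressed mate or calibration"
                )
                continue
            outliers.append(
                assess_outlier((frozen, unfrozen), calib, threshold=threshold)
            )

    control_tests: dict[str, dict[str, str]] = {}
    for cls in CALIBRATION_CLASSES:
        verdicts = {
            lab: zero_slope_test(calibs[(lab, cls)])
            for lab in labs
            if (lab, cls) in calibs
        }
        if verdicts:
            control_tests[cls] = verdicts

    return StudyReport(
        relaxivity_table=tuple(table),
        span=span,
        cv=cv,
        outliers=tuple(outliers),
        control_tests=control_tests,
        anomalies=tuple(anomalies),
        provenance=provenance or {},
    )
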