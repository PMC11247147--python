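"""Calibration utilities.

KRT prevalence is calibrated against historical registry datapoints by
extrapolating an ordinary least-squares trend to the target year and
searching a multiplicative knob (KRT access, CKD incidence or diagnosis
rate) until the simulated output matches the extrapolated target. The knob
search is a plain bisection run with a fixed seed, so the simulated summary
is a deterministic, monotone function of the multiplier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

KNOBS = ("krt_access", "ckd_incidence", "diagnosis")


def extrapolate_krt_target(points, target_year: int,
                           log_linear: bool = False) -> float:
    """OLS line through historical (year, prevalent count) datapoints.

    With ``log_linear=True`` the regression is on log counts (exponential
    growth trend) instead of counts.
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least 2 historical datapoints")
    years = np.array([p[0] for p in points], dtype=float)
    counts = np.array([p[1] for p in points], dtype=float)
    if np.all(years == years[0]):
        raise ValueError("historical datapoints must span distinct years")
    if log_linear:
        if np.any(counts <= 0):
            raise ValueError("log-linear extrapolation requires positive counts")
        fit = stats.linregress(years, np.log(counts))
        return float(np.exp(fit.intercept + fit.slope * target_year))
    fit = stats.linregress(years, counts)
    return float(fit.intercept + fit.slope * target_year)


@dataclass
class CalibrationResult:
    """Outcome of a bisection knob search."""

    knob: str
    multiplier: float
    achieved: float
    target: float
    relative_error: float
    iterations: int
    converged: bool
    history: list = field(default_factory=list)


def calibrate_multiplier(simulate, observed_target: float,
                         knob: str = "krt_access",
                         bracket: tuple[float, float] = (0.0, 1.0),
                         tol: float = 0.05,
                         max_iter: int = 60) -> CalibrationResult:
    """Bisection search for the multiplier matching an observed target.

    ``simulate(m)`` must be deterministic (fixed seed) and monotone in ``m``
    over the bracket. Raises if the bracket does not straddle the target or
    the tolerance is not reached within ``max_iter`` iterations.
    """
    if knob not in KNOBS:
        raise ValueError(f"unknown knob {knob!r}; expected one of {KNOBS}")
    if observed_target == 0:
        raise ValueError("observed_target must be non-zero")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    f_lo = simulate(lo) - observed_target
    f_hi = simulate(hi) - observed_target
    history = [(lo, f_lo + observed_target), (hi, f_hi + observed_target)]
    for m, f in ((lo, f_lo), (hi, f_hi)):
        if abs(f) / abs(observed_target) <= tol:
            return CalibrationResult(knob, m, f + observed_target,
                                     observed_target,
                                     abs(f) / abs(observed_target),
                                     0, True, history)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"bracket [{lo}, {hi}] does not straddle the target "
            f"{observed_target} (simulate gives {f_lo + observed_target} "
            f"and {f_hi + observed_target})")
    increasing = f_hi > f_lo
    best = (lo, f_lo) if abs(f_lo) < abs(f_hi) else (hi, f_hi)
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid = simulate(mid) - observed_target
        history.append((mid, f_mid + observed_target))
        if abs(f_mid) < abs(best[1]):
            best = (mid, f_mid)
        rel = abs(f_mid) / abs(observed_target)
        if rel <= tol:
            return CalibrationResult(knob, mid, f_mid + observed_target,
                                     observed_target, rel, it, True, history)
        if (f_mid < 0) == increasing:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} iterations; best "
        f"multiplier {best[0]} with value {best[1] + observed_target} "
        f"(target {observed_target})")


@dataclass
class ValidationReport:
    """Per-year relative errors of a projected series against a target."""

    years: list
    projected: list
    target: list
    relative_errors: list
    tol: float
    passed: bool
    failing_years: list


def validate_calibration(projected: dict, target: dict,
                         tol: float = 0.05) -> ValidationReport:
    """Compare aligned {year: value} series; pass iff all errors <= tol."""
    if set(projected) != set(target):
        raise ValueError(
            f"year mismatch: projected has {sorted(projected)}, "
            f"target has {sorted(target)}")
    years = sorted(projected)
    errors, failing = [], []
    for y in years:
        t = target[y]
        if t == 0:
            raise ValueError(f"target for {y} is zero")
        err = abs(projected[y] - t) / abs(t)
        errors.append(err)
        if err > tol:
            failing.append(y)
    return ValidationReport(
        years=years, projected=[projected[y] for y in years],
        target=[target[y] for y in years], relative_errors=errors,
        tol=tol, passed=not failing, failing_years=failing)
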