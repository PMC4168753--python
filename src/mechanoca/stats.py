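"""Dose-response statistics over per-cell stimulation series.

Aggregates the per-stimulation outputs (curve features + transients) into
the study-level quantities:

* the amplitude decay rate alpha (s^-1): the OLS slope of
  first-response-normalized amplitudes versus response onset time within
  one series of consecutive stimulations;
* the exponential recovery fit f(x) = a exp(-x b) + c of alpha versus
  recovery time (time off contact between stimulations), whose time
  constant tau = 1/b measures how fast responsiveness recovers;
* the linear fit of transient FWHM duration versus probe contact time;
* responder fractions per condition with binomial standard errors;
* Fisher's exact test for categorical comparisons and the two-sample
  Student's t-test for continuous ones (significance at p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .errors import FitFailedError, InsufficientDataError, InvalidTableError

from .calcium import Transient
from .force_curves import CurveFeatures


@dataclass
class StimulationSeries:
    """Ordered indentations of one cell and the resulting transients.

    ``stimulations`` pairs each indentation's CurveFeatures with the
    transient it evoked (or None); ``recovery_times`` are the off-contact
    intervals between consecutive stimulations (length n-1).
    """

    cell_id: str
    condition: str
    stimulations: list[tuple[Optional[CurveFeatures], Optional[Transient]]]
    recovery_times: list[float] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.stimulations)
        if self.recovery_times and len(self.recovery_times) != n - 1:
            raise InsufficientDataError(
                f"recovery_times must have length n-1 = {n - 1}, "
                f"got {len(self.recovery_times)}"
            )
        onsets = [
            tr.onset_time for _, tr in self.stimulations if tr is not None
        ]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InsufficientDataError("response onset times must be increasing")

    @property
    def responses(self) -> list[Transient]:
        return [tr for _, tr in self.stimulations if tr is not None]


@dataclass(frozen=True)
class DecayFit:
    """Amplitude decay of consecutive responses: alpha in s^-1 (slope of
    first-response-normalized amplitude vs onset time); percent_decay =
    100 x alpha."""

    alpha: float
    percent_decay: float
    n_responses: int


@dataclass(frozen=True)
class RecoveryFit:
    """Exponential fit a exp(-x b) + c of decay rate vs recovery time;
    tau = 1/b is the characteristic recovery time."""

    a: float
    b: float
    c: float
    tau: float
    rmse: float
    r_squared: float


@dataclass(frozen=True)
class DurationFit:
    """OLS line of transient duration (s) vs contact time (s)."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")


@dataclass(frozen=True)
class ConditionSummary:
    """Responder count / fraction for one experimental condition."""

    condition: str
    responders: int
    total: int
    fraction: float
    se: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def _ols(x: np.ndarray, y: np.ndarray):
    res = sps.linregress(x, y)
    return res


def decay_rate_from_amplitudes(
    times: Sequence[float], amplitudes: Sequence[float]
) -> DecayFit:
    """Alpha from raw response times (s) and amplitudes: OLS slope of
    first-response-normalized amplitude vs time since the first response.
    Invariant under rescaling of the raw amplitudes."""
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.size < 2:
        raise InsufficientDataError(f"decay rate needs >= 2 responses, got {t.size}")
    if a[0] <= 0:
        raise InsufficientDataError("first response amplitude must be > 0")
    y = a / a[0]
    t = t - t[0]
    if np.ptp(t) == 0:
        raise InsufficientDataError("response onset times are all equal")
    res = _ols(t, y)
    return DecayFit(
        alpha=float(res.slope),
        percent_decay=100.0 * float(res.slope),
        n_responses=int(t.size),
    )


def amplitude_decay_rate(series: StimulationSeries) -> DecayFit:
    """Alpha for one cell's stimulation series (see
    :func:`decay_rate_from_amplitudes`)."""
    responses = series.responses
    return decay_rate_from_amplitudes(
        [r.onset_time for r in responses], [r.amplitude for r in responses]
    )


def fit_recovery_exponential(
    recovery_times: Sequence[float], alphas: Sequence[float]
) -> RecoveryFit:
    """Nonlinear least squares of f(x) = a exp(-x b) + c, b > 0.

    Initialization: c0 = mean of the values at the two largest recovery
    times (the asymptote), a0 = min(y) - c0, b0 = 1 s^-1; deterministic on
    study-scale data.
    """
    x = np.asarray(recovery_times, dtype=float)
    y = np.asarray(alphas, dtype=float)
    if x.size < 4 or np.unique(x).size < 2:
        raise InsufficientDataError(
            "recovery fit needs >= 4 points over >= 2 distinct recovery times"
        )
    if np.ptp(y) == 0:
        raise FitFailedError("constant decay rates: b is unidentifiable")

    order = np.argsort(x)
    c0 = float(y[order][-2:].mean())
    a0 = float(y.min() - c0)
    if a0 == 0:
        a0 = float(y.max() - c0) or 1e-3

    def model(x, a, b, c):
        return a * np.exp(-x * b) + c

    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            y,
            p0=[a0, 1.0, c0],
            bounds=([-np.inf, 1e-8, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailedError(f"recovery fit did not converge: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    resid = y - model(x, a, b, c)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return RecoveryFit(a=a, b=b, c=c, tau=1.0 / b, rmse=rmse, r_squared=r2)


def fit_duration_vs_contact(
    contact_times: Sequence[float], durations: Sequence[float]
) -> DurationFit:
    """OLS line of transient duration on contact time."""
    x = np.asarray(contact_times, dtype=float)
    y = np.asarray(durations, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("duration fit needs >= 3 points")
    if np.unique(x).size < 2:
        raise FitFailedError("all contact times equal: slope unidentifiable")
    res = _ols(x, y)
    return DurationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def responder_fraction(
    responded: Sequence[bool], condition: str = ""
) -> ConditionSummary:
    """Fraction of responding cells with binomial SE = sqrt(p(1-p)/n)."""
    n = len(responded)
    if n < 1:
        raise InsufficientDataError("responder fraction needs >= 1 cell")
    k = int(sum(bool(r) for r in responded))
    p = k / n
    return ConditionSummary(
        condition=condition,
        responders=k,
        total=n,
        fraction=p,
        se=float(np.sqrt(p * (1 - p) / n)),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value (probability-mass criterion: the sum
    of hypergeometric probabilities of all tables with fixed margins that
    are no more probable than the observed one)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InvalidTableError(f"table must be 2x2, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise InvalidTableError("counts must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise InvalidTableError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise InvalidTableError("both margins must be positive")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def students_t(
    sample_a: Sequence[float], sample_b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample two-sided Student's t-test (equal-variance by default).

    Zero pooled variance is handled explicitly: equal means give t = 0,
    p = 1; unequal means are flagged degenerate (the difference is exact).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(
            t=float(np.sign(a.mean() - b.mean()) * np.inf), p=0.0, degenerate=True
        )
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p))
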