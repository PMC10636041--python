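"""Four-parameter logistic standard curves, LOD and quantifiable range.

The response model is the ascending 4PL

    f(x) = D + (A - D) / (1 + (x / C)**B)

with ``A`` the zero-concentration asymptote (the curve's y-intercept),
``D`` the saturation asymptote, ``C`` the inflection concentration
(molar) and ``B`` a positive slope.  Fits minimize the 1/y**2-weighted
sum of squares (observed-signal weighting), the standard choice for
assay data whose noise is roughly proportional to signal.

The blank-based limit of detection backfits ``mean(blanks) + k*sd`` and
``A + k*sd`` through the inverse curve and takes the larger
concentration; ``k`` is 2.5 in single-plex (qPCR) mode and 3 in
multiplex (NGS) mode.  The quantifiable range is the widest contiguous
run of standards whose replicate CVs stay below 30% and whose recoveries
stay within 30%, with at most one interior recovery exception.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

DEFAULT_CV_LIMIT = 30.0        # percent
DEFAULT_RECOVERY_LIMIT = 30.0  # percent deviation from nominal
DEFAULT_MAX_RECOVERY_EXCEPTIONS = 1
K_SINGLEPLEX = 2.5
K_MULTIPLEX = 3.0


class FitError(RuntimeError):
    pass


class BackfitError(ValueError):
    pass


@dataclass(frozen=True)
class FourPLParams:
    A: float  # zero-concentration asymptote (y-intercept)
    D: float  # saturation asymptote
    C: float  # inflection concentration, molar
    B: float  # slope, > 0
    converged: bool = True
    weighted_rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.C <= 0 or self.B <= 0:
            raise ValueError("C and B must be positive")
        if self.A == self.D:
            raise ValueError("degenerate curve: A == D")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (x / self.C) ** self.B, 0.0)
        return self.D + (self.A - self.D) / (1.0 + ratio)


@dataclass
class StandardSeries:
    """Replicate signals at each nominal standard concentration, plus blanks."""

    levels: list[tuple[float, np.ndarray]]  # (nominal molar, signals)
    blanks: np.ndarray

    def __post_init__(self) -> None:
        self.levels = [(float(c), np.asarray(y, dtype=float))
                       for c, y in self.levels]
        self.levels.sort(key=lambda cv: cv[0])
        self.blanks = np.asarray(self.blanks, dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels])

    def mean_signals(self) -> np.ndarray:
        return np.array([y.mean() for _, y in self.levels])

    def validate_for_fit(self) -> None:
        if sum(1 for c, _ in self.levels if c > 0) < 4:
            raise FitError("need >= 4 distinct positive levels for a 4PL fit")

    def validate_for_lod(self) -> None:
        if self.blanks.size < 2:
            raise FitError("need >= 2 blank replicates for LOD")


@dataclass
class AssayLimits:
    lod: float | None = None
    lloq: float | None = None
    uloq: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def dynamic_range_log10(self) -> float | None:
        if self.lloq is None or self.uloq is None:
            return None
        return math.log10(self.uloq / self.lloq)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_4pl(series: StandardSeries, include_blanks: bool = True,
            xtol: float = 1e-14, ftol: float = 1e-14) -> FourPLParams:
    """Weighted 4PL fit with multi-start initialization.

    Minimizes ``sum w_i (y_i - f(x_i))**2`` with ``w_i = 1 / y_i**2`` over
    all replicate points.  Asymptote starts come from the extreme mean
    signals, ``C`` from the geometric mid-concentration, and the slope is
    started at 0.5, 1 and 2; the best converged start wins.
    """
    series.validate_for_fit()
    xs, ys = [], []
    for c, ysig in series.levels:
        xs.extend([c] * ysig.size)
        ys.extend(ysig)
    if include_blanks and series.blanks.size:
        xs.extend([0.0] * series.blanks.size)
        ys.extend(series.blanks)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.any(y <= 0):
        raise FitError("signals must be positive for 1/y**2 weighting")
    if np.ptp(y) == 0:
        raise FitError("degenerate series: all signals identical (A == D)")
    w = 1.0 / y  # residuals scaled by 1/y => squared loss weighted 1/y**2

    pos = x > 0
    cmid = math.sqrt(x[pos].min() * x[pos].max())
    means = series.mean_signals()
    a0 = series.blanks.mean() if (include_blanks and series.blanks.size) \
        else means[0]
    a0 = max(a0, 1e-12)
    d0 = max(means[-1], a0 * 1.0001)

    def residuals(theta):
        A, D, logC, logB = theta
        C, B = math.exp(logC), math.exp(logB)
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(pos, (x / C) ** B, 0.0)
        return w * (D + (A - D) / (1.0 + ratio) - y)

    best = None
    for b0 in (0.5, 1.0, 2.0):
        theta0 = np.array([a0, d0, math.log(cmid), math.log(b0)])
        try:
            res = least_squares(residuals, theta0, xtol=xtol, ftol=ftol,
                                gtol=1e-14, max_nfev=20000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("4PL fit failed to converge from every start")
    A, D, logC, logB = best.x
    if abs(A - D) < 1e-12 * max(abs(A), abs(D), 1.0):
        raise FitError("degenerate fit: asymptotes collapsed (A ~= D)")
    return FourPLParams(A=float(A), D=float(D), C=float(math.exp(logC)),
                        B=float(math.exp(logB)), converged=bool(best.success),
                        weighted_rss=float(2 * best.cost))


def backfit(params: FourPLParams, signal: float) -> float:
    """Exact inverse of the 4PL: signal -> concentration.

    Defined only for signals strictly between the asymptotes; at or
    beyond an asymptote the concentration is unbounded/undefined.
    """
    lo, hi = sorted((params.A, params.D))
    if not lo < signal < hi:
        raise BackfitError(
            f"signal {signal!r} outside the open asymptote interval "
            f"({lo!r}, {hi!r})")
    ratio = (params.A - params.D) / (signal - params.D) - 1.0
    return params.C * ratio ** (1.0 / params.B)


def lod(params: FourPLParams, blanks: Sequence[float],
        k: float = K_MULTIPLEX) -> AssayLimits:
    """Blank-based limit of detection.

    Candidate signals are ``mean(blanks) + k*sd(blanks)`` and
    ``A + k*sd(blanks)`` (sample sd, n-1); each is backfitted through the
    inverse curve and the larger concentration is the LOD.  Candidates
    outside the curve's open signal range are skipped; if both are
    unusable the LOD is undetermined.
    """
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 2:
        raise FitError("need >= 2 blank replicates for LOD")
    sd = float(blanks.std(ddof=1))
    candidates = (float(blanks.mean()) + k * sd, params.A + k * sd)
    concs = []
    for s in candidates:
        try:
            concs.append(backfit(params, s))
        except BackfitError:
            continue
    if not concs:
        return AssayLimits(lod=None, flags=["lod_undetermined"])
    return AssayLimits(lod=max(concs))


def recovery(params: FourPLParams, series: StandardSeries) -> dict[float, float]:
    """Percent recovery per level: 100 * backfit(mean signal) / nominal.

    Levels whose mean signal cannot be backfitted get ``nan`` (treated as
    failing by the range search).
    """
    out = {}
    for c, y in series.levels:
        if c <= 0:
            continue
        try:
            out[c] = 100.0 * backfit(params, float(y.mean())) / c
        except BackfitError:
            out[c] = float("nan")
    return out


def _cv_percent(values: np.ndarray) -> float:
    return 100.0 * values.std(ddof=1) / values.mean()


def quant_range(params: FourPLParams, series: StandardSeries,
                cv_limit: float = DEFAULT_CV_LIMIT,
                recovery_limit: float = DEFAULT_RECOVERY_LIMIT,
                max_recovery_exceptions: int = DEFAULT_MAX_RECOVERY_EXCEPTIONS,
                ) -> AssayLimits:
    """Widest contiguous run of standards passing CV and recovery criteria.

    A window of consecutive levels is valid when every level's replicate
    CV is below ``cv_limit``, both endpoint levels recover within
    ``recovery_limit`` percent of nominal, and at most
    ``max_recovery_exceptions`` interior levels fail recovery.  The window
    maximizing log10 width wins; ties prefer the lower LLOQ.  Endpoints of
    the winning window are the LLOQ and ULOQ.
    """
    rec = recovery(params, series)
    levels = [(c, y) for c, y in series.levels if c > 0]
    concs = [c for c, _ in levels]
    cv_ok = [_cv_percent(y) < cv_limit if y.size >= 2 else False
             for _, y in levels]
    lo_r, hi_r = 100.0 - recovery_limit, 100.0 + recovery_limit
    rec_ok = [not math.isnan(rec[c]) and lo_r <= rec[c] <= hi_r
              for c in concs]

    best: tuple[float, float, float] | None = None  # (width, -lloq ordering)
    n = len(levels)
    for i, j in itertools.combinations_with_replacement(range(n), 2):
        if not (rec_ok[i] and rec_ok[j]):
            continue
        if not all(cv_ok[i:j + 1]):
            continue
        interior_fail = sum(1 for m in range(i + 1, j) if not rec_ok[m])
        if interior_fail > max_recovery_exceptions:
            continue
        width = math.log10(concs[j] / concs[i])
        if best is None or width > best[0] + 1e-12 or \
                (abs(width - best[0]) <= 1e-12 and concs[i] < best[1]):
            best = (width, concs[i], concs[j])
    if best is None:
        return AssayLimits(flags=["range_undetermined"])
    return AssayLimits(lloq=best[1], uloq=best[2])


def assay_limits(params: FourPLParams, series: StandardSeries,
                 k: float = K_MULTIPLEX, **range_kwargs) -> AssayLimits:
    """Convenience wrapper combining :func:`lod` and :func:`quant_range`."""
    series.validate_for_lod()
    lims = quant_range(params, series, **range_kwargs)
    lod_res = lod(params, series.blanks, k=k)
    lims.lod = lod_res.lod
    lims.flags.extend(lod_res.flags)
    return lims
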