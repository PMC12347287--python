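"""CMC estimation from fluorescence titrations by two-line intersection.

Below the CMC a hydrophobic fluorescent probe (e.g. diphenylhexatriene)
sees only monomers and the relative fluorescence follows a flat or gently
drifting baseline; above the CMC the probe partitions into micellar cores
and fluorescence rises steeply and roughly linearly with amphiphile
concentration.  The CMC is read off as the intersection of the
pre-micellar baseline line and the post-micellar trend line.

The estimator searches exhaustively over all admissible partitions of the
concentration axis into a pre- and a post-micellar segment (each holding
at least three distinct concentration levels), fits an ordinary
least-squares line to each segment, and keeps the partition with the
smallest total sum of squared residuals.  The reported CMC is the
analytic intersection of the two selected lines, not the abscissa of the
split point.

When the sampled concentrations span more than two decades a straight
line in linear concentration is meaningless, so fitting switches to a
log10 concentration axis and the intersection is transformed back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import (
    FlatSignalError,
    NoMicellizationError,
    FitError,
    ValidationError,
)

__all__ = [
    "Medium",
    "ConditionSpec",
    "TitrationCurve",
    "BreakpointFit",
    "BreakpointOptions",
    "BatchOutcome",
    "estimate_cmc",
    "estimate_cmc_batch",
]


class Medium(Enum):
    """Reaction medium used for the titration."""

    PBS_100MM = "PBS_100mM"
    MILLIQ_WATER = "MilliQ_water"
    BORATE_100MM = "borate_100mM"


@dataclass(frozen=True)
class ConditionSpec:
    """Physicochemical condition of one experiment: pH, temperature, medium."""

    ph: float = 7.0
    temperature_c: float = 35.0
    medium: Medium = Medium.PBS_100MM
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.ph < 14.0:
            raise ValidationError(f"ph must lie in (0, 14), got {self.ph}")
        if not 0.0 <= self.temperature_c <= 60.0:
            raise ValidationError(
                f"temperature_c must lie in [0, 60] degC, got {self.temperature_c}"
            )


@dataclass(frozen=True)
class TitrationCurve:
    """One fluorescence-vs-concentration experiment at a fixed CD level.

    Points are stored sorted by concentration; replicate points (same
    concentration, distinct ``replicate`` id) are kept individually and
    fitted jointly.
    """

    conc_um: np.ndarray
    rel_fluorescence_pct: np.ndarray
    replicate: np.ndarray
    cd_conc_m: float
    condition: ConditionSpec = ConditionSpec()
    guest: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc_um, dtype=float)
        fluo = np.asarray(self.rel_fluorescence_pct, dtype=float)
        rep = np.asarray(self.replicate, dtype=int)
        if conc.shape != fluo.shape or conc.shape != rep.shape:
            raise ValidationError("conc, fluorescence and replicate must align")
        if conc.size < 6:
            raise ValidationError(f"need at least 6 points, got {conc.size}")
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise ValidationError("concentrations must be finite and non-negative")
        if not np.all(np.isfinite(fluo)):
            raise ValidationError("fluorescence values must be finite")
        if self.cd_conc_m < 0:
            raise ValidationError("cd_conc_m must be non-negative")
        order = np.lexsort((rep, conc))
        object.__setattr__(self, "conc_um", conc[order])
        object.__setattr__(self, "rel_fluorescence_pct", fluo[order])
        object.__setattr__(self, "replicate", rep[order])

    @property
    def n_levels(self) -> int:
        return np.unique(self.conc_um).size


@dataclass(frozen=True)
class BreakpointFit:
    """Two fitted lines and their intersection, the estimated CMC.

    Slopes and intercepts are in the fitting axis: % per µM on a linear
    axis, % per decade when ``log_axis`` is set.
    """

    cmc_um: float
    pre_slope: float
    pre_intercept: float
    post_slope: float
    post_intercept: float
    split_index: int
    sse: float
    n_pre: int
    n_post: int
    log_axis: bool = False
    cmc_se_um: float | None = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class BreakpointOptions:
    """Tuning knobs for :func:`estimate_cmc`.

    ``min_segment_levels`` is the minimum number of distinct concentration
    levels per segment.  ``axis`` selects the fitting axis; ``"auto"``
    uses log10 concentration when the positive concentrations span more
    than ``log_decades_threshold`` decades.  ``fix_baseline_slope``
    constrains the pre-micellar line to be horizontal.  A break is only
    accepted when the post slope exceeds the pre slope by more than
    ``slope_tol_sigma`` pooled standard errors of the slope difference.
    """

    min_segment_levels: int = 3
    axis: str = "auto"  # "auto" | "linear" | "log"
    log_decades_threshold: float = 2.0
    fix_baseline_slope: bool = False
    slope_tol_sigma: float = 3.0


def _ols_line(x: np.ndarray, y: np.ndarray, fix_slope_zero: bool = False):
    """Least-squares line; returns (slope, intercept, sse, slope_var)."""
    n = x.size
    if fix_slope_zero:
        b = float(np.mean(y))
        resid = y - b
        sse = float(resid @ resid)
        return 0.0, b, sse, 0.0
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise FitError("degenerate segment: all concentrations equal")
    m = float(((x - xm) * (y - y.mean())).sum() / sxx)
    b = float(y.mean() - m * xm)
    resid = y - (m * x + b)
    sse = float(resid @ resid)
    df = n - 2
    slope_var = (sse / df / sxx) if df > 0 else 0.0
    return m, b, sse, slope_var


def estimate_cmc(
    curve: TitrationCurve, options: BreakpointOptions | None = None
) -> BreakpointFit:
    """Estimate the CMC of one titration curve by two-line intersection.

    Raises
    ------
    ValidationError
        Fewer than twice ``min_segment_levels`` distinct concentrations.
    FlatSignalError
        All fluorescence values identical (no break exists).
    NoMicellizationError
        Best two-line fit has no significantly steeper post segment.
    """
    opts = options or BreakpointOptions()
    x_raw = curve.conc_um
    y = curve.rel_fluorescence_pct

    if np.ptp(y) == 0.0:
        raise FlatSignalError("fluorescence is constant across the titration")

    levels = np.unique(x_raw)
    m = opts.min_segment_levels
    if levels.size < 2 * m:
        raise ValidationError(
            f"need at least {2 * m} distinct concentration levels, got {levels.size}"
        )

    # choose fitting axis
    log_axis = opts.axis == "log"
    if opts.axis == "auto":
        pos = levels[levels > 0]
        if pos.size >= 2 and pos.max() / pos.min() > 10.0**opts.log_decades_threshold:
            log_axis = True
    if log_axis:
        if np.any(levels <= 0):
            raise ValidationError("log-axis fitting requires strictly positive concentrations")
        x = np.log10(x_raw)
        xlev = np.log10(levels)
    else:
        x = x_raw
        xlev = levels

    best = None
    for k in range(m, levels.size - m + 1):
        cut = levels[k - 1]
        pre = x_raw <= cut
        post = ~pre
        try:
            pm, pb, psse, pvar = _ols_line(x[pre], y[pre], opts.fix_baseline_slope)
            qm, qb, qsse, qvar = _ols_line(x[post], y[post])
        except FitError:
            continue
        total = psse + qsse
        if best is None or total < best[0]:
            best = (total, k, pm, pb, pvar, qm, qb, qvar, int(pre.sum()), int(post.sum()))
    if best is None:
        raise FitError("no admissible two-line partition")

    total, k, pm, pb, pvar, qm, qb, qvar, n_pre, n_post = best

    slope_diff = qm - pm
    tol = opts.slope_tol_sigma * math.sqrt(pvar + qvar)
    if slope_diff <= tol:
        raise NoMicellizationError(
            "post-micellar slope does not exceed the baseline slope "
            f"(diff {slope_diff:.4g} <= tol {tol:.4g})"
        )

    x_star = (pb - qb) / slope_diff
    warnings: list[str] = []
    lo, hi = xlev[k - 1], xlev[k]
    if not lo <= x_star <= hi:
        warnings.append(
            "intersection falls outside the gap between the last pre-micellar "
            "and first post-micellar concentration"
        )
    cmc = 10.0**x_star if log_axis else float(x_star)
    if not math.isfinite(cmc) or cmc <= 0:
        raise FitError(f"non-positive or non-finite CMC intersection ({cmc!r})")

    return BreakpointFit(
        cmc_um=cmc,
        pre_slope=pm,
        pre_intercept=pb,
        post_slope=qm,
        post_intercept=qb,
        split_index=k,
        sse=total,
        n_pre=n_pre,
        n_post=n_post,
        log_axis=log_axis,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class BatchOutcome:
    """Result of one curve in a batch: either a fit or an error message."""

    cd_conc_m: float
    fit: BreakpointFit | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.fit is not None


def estimate_cmc_batch(
    curves: Sequence[TitrationCurve], options: BreakpointOptions | None = None
) -> list[BatchOutcome]:
    """Estimate the CMC for each curve of one guest/condition across CD levels.

    All curves must share guest and condition and carry distinct CD
    levels.  Per-curve failures are recorded in the returned outcomes
    without aborting the batch; order is preserved.
    """
    if not curves:
        return []
    guest = curves[0].guest
    condition = curves[0].condition
    seen: set[float] = set()
    for c in curves:
        if c.guest != guest or c.condition != condition:
            raise ValidationError("all curves in a batch must share guest and condition")
        if c.cd_conc_m in seen:
            raise ValidationError(f"duplicate CD level {c.cd_conc_m} M in batch")
        seen.add(c.cd_conc_m)
    out: list[BatchOutcome] = []
    for c in curves:
        try:
            out.append(BatchOutcome(c.cd_conc_m, estimate_cmc(c, options)))
        except (ValidationError, FitError) as exc:
            out.append(BatchOutcome(c.cd_conc_m, None, error=str(exc)))
    return out
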