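"""Micellar-diagram fitting: stoichiometry selection and binding constants.

A micellar diagram plots the apparent CMC of an amphiphilic guest against
the concentration of added cyclodextrin.  A linear rise indicates 1:1
inclusion complexes and its slope yields the association constant Kc; an
upward-curved (quadratic) rise indicates sequential 1:2 binding with
stepwise constants K1 and K2 (see :mod:`lipocd.equilibria` for the
forward models).

By default the zero-CD intercept CMC0 is pinned to the measured CMC at
[CD] = 0 — it is a characteristic constant of the compound under the
given condition — and only the association constants are free.  Passing
``cmc0="fitted"`` frees the intercept.

Stoichiometry selection compares the linear and quadratic diagram models
with a one-sided extra-sum-of-squares test on the curvature term (the
signed square root of the nested F statistic, referred to Student's t):
since K1*K2 >= 0 only upward curvature is evidence for 1:2 binding.  The
selection regressions use inverse-squared-fitted-value weights, i.e. a
constant-coefficient-of-variation error model, which is how replicate
scatter of CMC estimates behaves.  A significant test must additionally
clear a curvature floor — the quadratic term must contribute at least 1%
of the linear term at the largest CD level — before 1:2 is declared, so
that statistically detectable but chemically negligible curvature does
not flip the model.

Uncertainties come from residual-resampling bootstrap with percentile
intervals; CD levels are designed, not sampled, so residuals rather than
pairs are resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .breakpoint import BreakpointFit, ConditionSpec
from .equilibria import BindingModelKind, BindingParams, eval_cmc
from .errors import FitError, ValidationError

__all__ = [
    "MicellarDiagram",
    "BindingFit",
    "build_diagram",
    "fit_1to1",
    "fit_1to2",
    "select_stoichiometry",
    "bootstrap_binding",
]


@dataclass(frozen=True)
class MicellarDiagram:
    """Apparent CMC (µM) as a function of CD concentration (M).

    Levels are strictly increasing and must include a zero-CD anchor (the
    CMC0 measurement).  ``cmc_se_um``, when present, holds per-level
    standard errors used for inverse-variance weighting.
    """

    cd_conc_m: np.ndarray
    cmc_um: np.ndarray
    cmc_se_um: np.ndarray | None = None
    condition: ConditionSpec = ConditionSpec()
    guest: str = ""

    def __post_init__(self) -> None:
        cd = np.asarray(self.cd_conc_m, dtype=float)
        cmc = np.asarray(self.cmc_um, dtype=float)
        if cd.shape != cmc.shape or cd.ndim != 1:
            raise ValidationError("cd_conc_m and cmc_um must be matched 1-d arrays")
        if cd.size < 3:
            raise ValidationError("a micellar diagram needs at least 3 CD levels")
        if cd[0] != 0.0:
            raise ValidationError("the first CD level must be 0 (CMC0 anchor)")
        if np.any(np.diff(cd) <= 0):
            raise ValidationError("CD levels must be strictly increasing")
        if np.any(cmc <= 0) or not np.all(np.isfinite(cmc)):
            raise ValidationError("all CMC values must be positive and finite")
        object.__setattr__(self, "cd_conc_m", cd)
        object.__setattr__(self, "cmc_um", cmc)
        if self.cmc_se_um is not None:
            se = np.asarray(self.cmc_se_um, dtype=float)
            if se.shape != cd.shape or np.any(se < 0):
                raise ValidationError("cmc_se_um must match cd levels and be >= 0")
            object.__setattr__(self, "cmc_se_um", se)

    @property
    def n_levels(self) -> int:
        return self.cd_conc_m.size


@dataclass(frozen=True)
class BindingFit:
    """A fitted CMC-shift binding model with diagnostics.

    ``f_statistic``/``f_pvalue`` refer to the one-sided curvature test of
    the quadratic against the linear diagram model (populated by
    :func:`select_stoichiometry`); ``aicc_delta`` is AICc(1:2) - AICc(1:1).
    ``ci_lower``/``ci_upper`` map parameter names to bootstrap percentile
    bounds.  ``rival`` carries the competing model's fit after selection.
    """

    model: BindingModelKind
    params: BindingParams
    cmc0_source: str  # "measured_at_zero" | "fitted"
    sse: float
    r_squared: float
    f_statistic: float | None = None
    f_pvalue: float | None = None
    aicc_delta: float | None = None
    ci_lower: Mapping[str, float] | None = None
    ci_upper: Mapping[str, float] | None = None
    n_boot: int | None = None
    seed: int | None = None
    warnings: tuple[str, ...] = ()
    rival: "BindingFit | None" = None

    def predicted(self, cd) -> np.ndarray:
        return np.asarray(eval_cmc(self.params, cd), dtype=float)


def build_diagram(
    fits: Sequence[tuple[float, BreakpointFit]] | Mapping[float, BreakpointFit],
    condition: ConditionSpec = ConditionSpec(),
    guest: str = "",
    cd_unit: str = "mM",
) -> MicellarDiagram:
    """Assemble a micellar diagram from per-CD-level breakpoint fits.

    ``fits`` maps CD level (in ``cd_unit``, default mM as used in data
    files) to the corresponding :class:`BreakpointFit`.  Levels are sorted;
    a level at 0 is required as the CMC0 anchor.  Per-level standard
    errors are propagated when every fit carries one.
    """
    if cd_unit == "mM":
        scale = 1e-3
    elif cd_unit == "M":
        scale = 1.0
    else:
        raise ValidationError(f"cd_unit must be 'mM' or 'M', got {cd_unit!r}")
    pairs = list(fits.items()) if isinstance(fits, Mapping) else list(fits)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 breakpoint fits")
    cds = [p[0] for p in pairs]
    if len(set(cds)) != len(cds):
        raise ValidationError("duplicate CD levels in diagram input")
    if 0.0 not in cds:
        raise ValidationError("a CD = 0 fit is required as the CMC0 anchor")
    pairs.sort(key=lambda p: p[0])
    cd = np.array([p[0] for p in pairs], dtype=float) * scale
    cmc = np.array([p[1].cmc_um for p in pairs], dtype=float)
    ses = [p[1].cmc_se_um for p in pairs]
    se = np.array(ses, dtype=float) if all(s is not None for s in ses) else None
    return MicellarDiagram(cd, cmc, cmc_se_um=se, condition=condition, guest=guest)


def _weights(diagram: MicellarDiagram) -> np.ndarray | None:
    """Inverse-variance weights when standard errors are available."""
    se = diagram.cmc_se_um
    if se is None or np.any(se <= 0):
        return None
    return 1.0 / se**2


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> tuple[float, list[str]]:
    sstot = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    if sstot == 0.0:
        return float("nan"), ["flat diagram: r_squared undefined"]
    return 1.0 - sse / sstot, []


def _resolve_cmc0(diagram: MicellarDiagram, cmc0: str) -> tuple[float | None, str]:
    if cmc0 == "measured":
        return float(diagram.cmc_um[0]), "measured_at_zero"
    if cmc0 == "fitted":
        return None, "fitted"
    raise ValidationError(f"cmc0 must be 'measured' or 'fitted', got {cmc0!r}")


def fit_1to1(diagram: MicellarDiagram, cmc0: str = "measured") -> BindingFit:
    """Fit the linear 1:1 model CMC = CMC0*(1 + Kc*[CD]) to a diagram.

    With ``cmc0="measured"`` (default) CMC0 is pinned to the zero-CD
    measurement and Kc has a closed-form non-negative least-squares
    solution.  A significantly negative slope is clamped to Kc = 0 with a
    warning.
    """
    cd = diagram.cd_conc_m
    y = diagram.cmc_um
    w = _weights(diagram)
    wv = w if w is not None else np.ones_like(y)
    c0, source = _resolve_cmc0(diagram, cmc0)
    warnings: list[str] = []

    if c0 is None:
        # weighted straight line, then reparameterize
        W = np.diag(wv)
        X = np.column_stack([np.ones_like(cd), cd])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(wv) * y, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        if intercept <= 0:
            raise FitError("fitted CMC0 is non-positive")
        c0 = intercept
        kc = slope / c0
    else:
        denom = float((wv * cd**2).sum())
        kc = float((wv * cd * (y - c0)).sum() / (c0 * denom)) if denom > 0 else 0.0
    if kc < 0:
        warnings.append("CMC decreases with CD; Kc clamped to 0")
        kc = 0.0
    params = BindingParams.one_to_one(c0, kc)
    yhat = np.asarray(eval_cmc(params, cd), dtype=float)
    sse = float((wv * (y - yhat) ** 2).sum())
    r2, r2_warn = _r_squared(y, yhat)
    return BindingFit(
        model=BindingModelKind.ONE_TO_ONE,
        params=params,
        cmc0_source=source,
        sse=sse,
        r_squared=r2,
        warnings=tuple(warnings + r2_warn),
    )


_K2_STARTS = (0.0, 0.1, 1.0, 10.0)


def fit_1to2(
    diagram: MicellarDiagram,
    cmc0: str = "measured",
    k2_starts: Sequence[float] = _K2_STARTS,
) -> BindingFit:
    """Fit the quadratic 1:2 model CMC = CMC0*(1 + K1*[CD] + K1*K2*[CD]^2).

    Bounded nonlinear least squares over (K1, K2) >= 0 (and CMC0 > 0 when
    freed), multistarted from the linear-fit slope for K1 and a grid of
    K2 values; the lowest-SSE converged solution wins.
    """
    if diagram.n_levels < 4:
        raise ValidationError("the 1:2 model needs at least 4 distinct CD levels")
    cd = diagram.cd_conc_m
    y = diagram.cmc_um
    w = _weights(diagram)
    sw = np.sqrt(w) if w is not None else np.ones_like(y)
    c0_fixed, source = _resolve_cmc0(diagram, cmc0)
    yscale = float(np.mean(y))

    lin = fit_1to1(diagram, cmc0=cmc0)
    k1_start = max(lin.params.kc, 1e-12)

    free_c0 = c0_fixed is None

    def residuals(theta: np.ndarray) -> np.ndarray:
        if free_c0:
            c0, k1, k2 = theta
        else:
            c0 = c0_fixed
            k1, k2 = theta
        pred = c0 * (1.0 + k1 * cd + k1 * k2 * cd**2)
        return sw * (pred - y) / yscale

    best = None
    trace: list[str] = []
    for k2_0 in k2_starts:
        x0 = np.array([lin.params.cmc0, k1_start, k2_0]) if free_c0 else np.array([k1_start, k2_0])
        lb = np.array([1e-300, 0.0, 0.0]) if free_c0 else np.array([0.0, 0.0])
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, np.inf),
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=500 * (3 if free_c0 else 2),
            )
        except Exception as exc:  # pragma: no cover - optimizer internals
            trace.append(f"start k2={k2_0}: {exc}")
            continue
        if not sol.success and not np.isfinite(sol.cost):
            trace.append(f"start k2={k2_0}: {sol.message}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("1:2 fit failed from all starts: " + "; ".join(trace))

    if free_c0:
        c0, k1, k2 = (float(v) for v in best.x)
    else:
        c0 = float(c0_fixed)
        k1, k2 = (float(v) for v in best.x)
    params = BindingParams.one_to_two(c0, k1, k2)
    yhat = np.asarray(eval_cmc(params, cd), dtype=float)
    wv = w if w is not None else np.ones_like(y)
    sse = float((wv * (y - yhat) ** 2).sum())
    r2, r2_warn = _r_squared(y, yhat)
    return BindingFit(
        model=BindingModelKind.ONE_TO_TWO,
        params=params,
        cmc0_source=source,
        sse=sse,
        r_squared=r2,
        warnings=tuple(r2_warn),
    )


def _aicc(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _curvature_test(cd: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided test for upward curvature in the diagram.

    Fits free-intercept linear and quadratic polynomials in [CD] by
    weighted least squares (weights 1/fitted^2 from a preliminary linear
    fit, i.e. constant-CV errors) and returns ``(t, p)`` for the
    hypothesis that the quadratic coefficient is positive.  With n levels
    the residual degrees of freedom are n - 3.
    """
    n = cd.size
    X1 = np.column_stack([np.ones(n), cd])
    X2 = np.column_stack([np.ones(n), cd, cd**2])
    # preliminary unweighted linear fit for the variance model
    beta0, *_ = np.linalg.lstsq(X1, y, rcond=None)
    yhat0 = X1 @ beta0
    if np.all(yhat0 > 0):
        sw = 1.0 / yhat0
    else:
        sw = np.ones(n)
    yw = sw * y
    b1, *_ = np.linalg.lstsq(X1 * sw[:, None], yw, rcond=None)
    b2, *_ = np.linalg.lstsq(X2 * sw[:, None], yw, rcond=None)
    r1 = yw - (X1 * sw[:, None]) @ b1
    r2 = yw - (X2 * sw[:, None]) @ b2
    sse1 = float(r1 @ r1)
    sse2 = float(r2 @ r2)
    df = n - 3
    if df <= 0:
        raise ValidationError("curvature test needs at least 4 CD levels")
    sstot = float(((yw - yw.mean()) ** 2).sum())
    scale = max(sstot, 1e-300)
    if sse2 / scale < 1e-18:
        # numerically exact quadratic fit: decide by whether it improves on the line
        improve = (sse1 - sse2) / scale
        sign = 1.0 if b2[2] > 0 else -1.0
        if improve > 1e-12 and sign > 0:
            return math.inf, 0.0
        return 0.0, 1.0
    f = max(sse1 - sse2, 0.0) / (sse2 / df)
    t = math.copysign(math.sqrt(f), b2[2])
    p = float(stats.t.sf(t, df))
    return t, p


def select_stoichiometry(
    diagram: MicellarDiagram, alpha: float = 0.05, cmc0: str = "measured"
) -> BindingFit:
    """Fit both stoichiometries and pick one.

    Declares 1:2 binding iff the one-sided curvature test rejects at
    ``alpha`` AND the fitted quadratic term clears the curvature floor
    (K2 * cd_max > 0.01 with K1 > 0, i.e. the quadratic contribution at
    the largest CD level exceeds 1% of the linear one); otherwise 1:1.
    The returned fit carries the test statistics and the rival model.
    """
    if not 0.0 < alpha <= 0.5:
        raise ValidationError(f"alpha must lie in (0, 0.5], got {alpha}")
    fit1 = fit_1to1(diagram, cmc0=cmc0)
    fit2 = fit_1to2(diagram, cmc0=cmc0)
    t, p = _curvature_test(diagram.cd_conc_m, diagram.cmc_um)
    cd_max = float(diagram.cd_conc_m[-1])
    k1, k2 = fit2.params.k1, fit2.params.k2
    # floor: K1*K2*cd_max^2 > 0.01 * K1*cd_max, i.e. K2*cd_max > 0.01
    floor_ok = k1 > 0 and k2 * cd_max > 0.01
    n = diagram.n_levels
    aicc_delta = _aicc(fit2.sse, n, 2) - _aicc(fit1.sse, n, 1)
    chosen, rival = (fit2, fit1) if (p < alpha and floor_ok) else (fit1, fit2)
    f_stat = t * abs(t) if math.isfinite(t) else math.inf
    return replace(
        chosen,
        f_statistic=f_stat,
        f_pvalue=p,
        aicc_delta=aicc_delta,
        rival=rival,
    )


def bootstrap_binding(
    fit: BindingFit,
    diagram: MicellarDiagram,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> BindingFit:
    """Residual-resampling percentile intervals for a fitted model.

    Residuals from the point fit are resampled with replacement and added
    back to the fitted values; the model is refitted to each pseudo
    diagram (warm-started from the point estimate for the 1:2 model) and
    per-parameter percentile intervals at ``ci_level`` are attached.
    Deterministic for a fixed ``seed``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    if seed is None:
        raise ValidationError("a seed is required for reproducible intervals")
    cd = diagram.cd_conc_m
    y = diagram.cmc_um
    yhat = fit.predicted(cd)
    resid = y - yhat
    names = (
        ["cmc0", "kc"]
        if fit.model is BindingModelKind.ONE_TO_ONE
        else ["cmc0", "k1", "k2"]
    )

    def values(p: BindingParams) -> list[float]:
        return [p.cmc0, p.kc] if p.kc is not None else [p.cmc0, p.k1, p.k2]

    point = values(fit.params)
    if np.allclose(resid, 0.0):
        lo = dict(zip(names, point))
        hi = dict(zip(names, point))
        return replace(
            fit,
            ci_lower=lo,
            ci_upper=hi,
            n_boot=n_boot,
            seed=seed,
            warnings=fit.warnings + ("zero residuals: intervals collapse to the point estimate",),
        )

    rng = np.random.default_rng(seed)
    cmc0_mode = "measured" if fit.cmc0_source == "measured_at_zero" else "fitted"
    draws = np.empty((n_boot, len(names)))
    floor = float(np.min(yhat)) * 1e-6
    n_fail = 0
    for b in range(n_boot):
        ystar = yhat + rng.choice(resid, size=resid.size, replace=True)
        ystar = np.maximum(ystar, floor)
        dstar = MicellarDiagram(
            cd, ystar, cmc_se_um=diagram.cmc_se_um,
            condition=diagram.condition, guest=diagram.guest,
        )
        try:
            if fit.model is BindingModelKind.ONE_TO_ONE:
                refit = fit_1to1(dstar, cmc0=cmc0_mode)
            else:
                refit = fit_1to2(dstar, cmc0=cmc0_mode, k2_starts=(fit.params.k2,))
        except (FitError, ValidationError):
            n_fail += 1
            draws[b] = point
            continue
        draws[b] = values(refit.params)
    q = (1.0 - ci_level) / 2.0
    lo = dict(zip(names, np.quantile(draws, q, axis=0).tolist()))
    hi = dict(zip(names, np.quantile(draws, 1.0 - q, axis=0).tolist()))
    warnings = fit.warnings
    if n_fail:
        warnings = warnings + (f"{n_fail}/{n_boot} bootstrap refits failed; point estimate substituted",)
    return replace(fit, ci_lower=lo, ci_upper=hi, n_boot=n_boot, seed=seed, warnings=warnings)
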