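"""Synthetic fluorescence titrations and micellar diagrams with known truth.

No raw instrument data accompany the study conditions this package
models, so every pipeline stage is exercised against simulated data whose
ground truth is known exactly.  The generator emulates the two-segment
fluorescence response of a hydrophobic probe: a flat or gently drifting
pre-micellar baseline, then a steep linear rise once micelles form, with
the breakpoint placed at the CMC predicted by a 1:1 or 1:2 CMC-shift
model (:mod:`lipocd.equilibria`) at the curve's CD level.  The join is
continuous and deliberately not smoothed: the downstream estimator fits
two straight lines, and an unmodelled sigmoidal transition would inject
a model mismatch of unknown size.

Noise models: additive Gaussian noise (in % fluorescence units) on
titration points; multiplicative Gaussian noise (constant CV) on
diagram-level CMC values.  All randomness flows from the explicit seed
carried by each spec; there is no global random state.

For breakpoints below 1 µM (the nanomolar regime of the most hydrophobic
conjugates) concentration grids are log-spaced and the response is
piecewise-linear in log10 concentration, with slopes read as % per
decade — matching the axis on which such curves are plotted and fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .breakpoint import ConditionSpec, Medium, TitrationCurve
from .binding import MicellarDiagram
from .equilibria import BindingModelKind, BindingParams, eval_cmc
from .errors import ValidationError

__all__ = [
    "ConcGrid",
    "SyntheticTitrationSpec",
    "SyntheticDiagramSpec",
    "make_titration",
    "make_diagram",
    "condition_presets",
    "get_preset",
]


@dataclass(frozen=True)
class ConcGrid:
    """Rule for an amphiphile concentration grid (µM).

    ``kind`` is ``"linear"``, ``"log"`` or ``"auto"``; with ``"auto"``
    the grid is log-spaced when the breakpoint lies below 1 µM.  When
    ``lo``/``hi`` are omitted they default to breakpoint/4 .. 2.5x
    breakpoint (linear) or breakpoint/30 .. 30x breakpoint (log).
    """

    kind: str = "auto"
    n: int = 12
    lo: float | None = None
    hi: float | None = None

    def resolve(self, breakpoint_um: float) -> tuple[np.ndarray, bool]:
        kind = self.kind
        if kind == "auto":
            kind = "log" if breakpoint_um < 1.0 else "linear"
        if kind == "linear":
            lo = self.lo if self.lo is not None else breakpoint_um / 4.0
            hi = self.hi if self.hi is not None else breakpoint_um * 2.5
            return np.linspace(lo, hi, self.n), False
        if kind == "log":
            lo = self.lo if self.lo is not None else breakpoint_um / 30.0
            hi = self.hi if self.hi is not None else breakpoint_um * 30.0
            if lo <= 0:
                raise ValidationError("log grids need a positive lower bound")
            return np.geomspace(lo, hi, self.n), True
        raise ValidationError(f"grid kind must be linear/log/auto, got {kind!r}")


@dataclass(frozen=True)
class SyntheticTitrationSpec:
    """Recipe for one synthetic titration curve.

    ``binding`` is the ground-truth CMC-shift model; the breakpoint is its
    evaluation at ``cd_conc_m``.  ``baseline_slope`` and ``post_slope``
    are % per µM on a linear grid, % per decade on a log grid; the post
    slope must exceed the baseline slope.  ``noise_sd`` is the additive
    Gaussian noise, in % fluorescence units.
    """

    binding: BindingParams
    cd_conc_m: float = 0.0
    seed: int = 0
    baseline_level: float = 5.0
    baseline_slope: float = 0.0
    post_slope: float = 8.0
    grid: ConcGrid | Sequence[float] = field(default_factory=ConcGrid)
    noise_sd: float = 2.0
    n_replicates: int = 3
    condition: ConditionSpec = ConditionSpec()
    guest: str = "synthetic"

    def __post_init__(self) -> None:
        if self.baseline_slope < 0 or self.post_slope <= self.baseline_slope:
            raise ValidationError("need post_slope > baseline_slope >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.cd_conc_m < 0:
            raise ValidationError("cd_conc_m must be >= 0")


def make_titration(spec: SyntheticTitrationSpec) -> TitrationCurve:
    """Generate one titration curve; deterministic for a fixed seed.

    Raises :class:`ValidationError` when the breakpoint falls outside the
    concentration grid (the CMC would be undetectable).
    """
    cmc = float(eval_cmc(spec.binding, spec.cd_conc_m))
    if isinstance(spec.grid, ConcGrid):
        conc, log_axis = spec.grid.resolve(cmc)
    else:
        conc = np.asarray(spec.grid, dtype=float)
        pos = conc[conc > 0]
        log_axis = pos.size >= 2 and pos.max() / pos.min() > 100.0
    conc = np.sort(conc)
    if not conc[0] < cmc < conc[-1]:
        raise ValidationError(
            f"breakpoint {cmc:g} µM outside the sampled range "
            f"[{conc[0]:g}, {conc[-1]:g}] µM"
        )
    if log_axis:
        if np.any(conc <= 0):
            raise ValidationError("log-axis curves need strictly positive concentrations")
        x = np.log10(conc)
        xb = np.log10(cmc)
        pre = spec.baseline_level + spec.baseline_slope * (x - xb)
        post = spec.baseline_level + spec.post_slope * (x - xb)
    else:
        x = conc
        pre = spec.baseline_level + spec.baseline_slope * x
        f_break = spec.baseline_level + spec.baseline_slope * cmc
        post = f_break + spec.post_slope * (x - cmc)
    clean = np.where(x <= (np.log10(cmc) if log_axis else cmc), pre, post)

    rng = np.random.default_rng(spec.seed)
    concs = np.tile(conc, spec.n_replicates)
    fluo = np.tile(clean, spec.n_replicates)
    if spec.noise_sd > 0:
        fluo = fluo + rng.normal(0.0, spec.noise_sd, size=fluo.size)
    reps = np.repeat(np.arange(spec.n_replicates), conc.size)
    return TitrationCurve(
        conc_um=concs,
        rel_fluorescence_pct=fluo,
        replicate=reps,
        cd_conc_m=spec.cd_conc_m,
        condition=spec.condition,
        guest=spec.guest,
    )


@dataclass(frozen=True)
class SyntheticDiagramSpec:
    """Recipe for a synthetic micellar diagram.

    ``cd_grid_m`` must start at 0 and increase strictly.  Each CMC value
    is the model evaluation times ``(1 + eps)`` with
    ``eps ~ N(0, noise_cv)``; with ``n_replicates > 1`` the per-level
    replicates are averaged and a standard error attached.
    """

    binding: BindingParams
    cd_grid_m: Sequence[float]
    seed: int = 0
    noise_cv: float = 0.05
    n_replicates: int = 1
    condition: ConditionSpec = ConditionSpec()
    guest: str = "synthetic"

    def __post_init__(self) -> None:
        cd = np.asarray(self.cd_grid_m, dtype=float)
        if cd.size < 3 or cd[0] != 0.0 or np.any(np.diff(cd) <= 0):
            raise ValidationError("cd_grid_m must be strictly increasing from 0 with >= 3 levels")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def make_diagram(spec: SyntheticDiagramSpec) -> MicellarDiagram:
    """Generate a micellar diagram directly at the CMC level.

    Bypasses curve-level simulation for fast statistical experiments on
    the fitting and selection machinery; deterministic per seed.
    """
    cd = np.asarray(spec.cd_grid_m, dtype=float)
    truth = np.asarray(eval_cmc(spec.binding, cd), dtype=float)
    rng = np.random.default_rng(spec.seed)
    se = None
    if spec.noise_cv == 0.0:
        cmc = truth.copy()
    else:
        eps = rng.normal(0.0, spec.noise_cv, size=(spec.n_replicates, cd.size))
        reps = truth[None, :] * (1.0 + eps)
        reps = np.maximum(reps, truth[None, :] * 1e-6)
        cmc = reps.mean(axis=0)
        if spec.n_replicates > 1:
            se = reps.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
    return MicellarDiagram(
        cd_conc_m=cd,
        cmc_um=cmc,
        cmc_se_um=se,
        condition=spec.condition,
        guest=spec.guest,
    )


_PRESETS: tuple[dict, ...] = (
    # guest, ph, temp_C, medium, model, cmc0_um, kc, k1, k2, note
    dict(guest="LA", ph=7.0, temp_c=35.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=43.0, kc=7432.0,
         note="reference condition, pH 7.0 / 35 degC / 100 mM PBS"),
    dict(guest="DHA", ph=7.0, temp_c=35.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=70.0, kc=7557.0,
         note="reference condition, pH 7.0 / 35 degC / 100 mM PBS"),
    dict(guest="Resv-4'-LA", ph=7.0, temp_c=35.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=6.0, kc=720.0,
         note="reference condition, pH 7.0 / 35 degC / 100 mM PBS"),
    dict(guest="Resv-4'-LA", ph=2.0, temp_c=35.0, medium=Medium.BORATE_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=0.54, kc=4264.0,
         note="acidified medium, pH 2.0 / 35 degC"),
    dict(guest="Resv-4'-LA", ph=7.0, temp_c=25.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=0.27, kc=8157.0,
         note="reduced temperature, 25 degC"),
    dict(guest="Resv-4'-LA", ph=7.0, temp_c=15.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=0.14, kc=10432.0,
         note="reduced temperature, 15 degC"),
    dict(guest="Resv-4'-LA", ph=7.0, temp_c=35.0, medium=Medium.MILLIQ_WATER,
         model=BindingModelKind.ONE_TO_ONE, cmc0_um=0.11, kc=42535.0,
         note="salt-free medium (MilliQ water)"),
    dict(guest="Resv-4'-DHA", ph=7.0, temp_c=35.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_TWO, cmc0_um=0.001, k1=17.0, k2=0.18,
         note="reference condition, pH 7.0 / 35 degC / 100 mM PBS"),
    dict(guest="Resv-4'-DHA", ph=2.0, temp_c=35.0, medium=Medium.BORATE_100MM,
         model=BindingModelKind.ONE_TO_TWO, cmc0_um=5e-4, k1=97.0, k2=0.45,
         note="acidified medium, pH 2.0 / 35 degC"),
    dict(guest="Resv-4'-DHA", ph=7.0, temp_c=25.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_TWO, cmc0_um=6e-4, k1=787.0, k2=0.1,
         note="reduced temperature, 25 degC"),
    dict(guest="Resv-4'-DHA", ph=7.0, temp_c=15.0, medium=Medium.PBS_100MM,
         model=BindingModelKind.ONE_TO_TWO, cmc0_um=3e-4, k1=898.0, k2=0.33,
         note="reduced temperature, 15 degC"),
    dict(guest="Resv-4'-DHA", ph=7.0, temp_c=35.0, medium=Medium.MILLIQ_WATER,
         model=BindingModelKind.ONE_TO_TWO, cmc0_um=5e-4, k1=707.0, k2=0.33,
         note="salt-free medium (MilliQ water)"),
)


def condition_presets() -> pd.DataFrame:
    """Published condition grid as simulation presets.

    One row per (guest, pH, temperature, medium) with the reported ground
    truth: CMC0 (µM) and either Kc (1:1) or K1/K2 (1:2), all in M^-1.
    """
    rows = []
    for p in _PRESETS:
        rows.append(
            dict(
                guest=p["guest"],
                ph=p["ph"],
                temp_c=p["temp_c"],
                medium=p["medium"].value,
                model=p["model"].value,
                cmc0_um=p["cmc0_um"],
                kc=p.get("kc", float("nan")),
                k1=p.get("k1", float("nan")),
                k2=p.get("k2", float("nan")),
                note=p["note"],
            )
        )
    return pd.DataFrame(rows)


def get_preset(
    guest: str,
    ph: float = 7.0,
    temp_c: float = 35.0,
    medium: Medium = Medium.PBS_100MM,
) -> tuple[BindingParams, ConditionSpec]:
    """Ground-truth binding parameters and condition for one preset."""
    for p in _PRESETS:
        if (
            p["guest"] == guest
            and p["ph"] == ph
            and p["temp_c"] == temp_c
            and p["medium"] is medium
        ):
            if p["model"] is BindingModelKind.ONE_TO_ONE:
                params = BindingParams.one_to_one(p["cmc0_um"], p["kc"])
            else:
                params = BindingParams.one_to_two(p["cmc0_um"], p["k1"], p["k2"])
            cond = ConditionSpec(ph=ph, temperature_c=temp_c, medium=medium)
            return params, cond
    raise ValidationError(
        f"no preset for guest={guest!r}, ph={ph}, temp_c={temp_c}, medium={medium}"
    )
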