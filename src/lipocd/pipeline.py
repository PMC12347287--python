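"""End-to-end analysis: titration curves -> CMC fits -> binding model -> report."""

from __future__ import annotations

from typing import Sequence

from .binding import bootstrap_binding, build_diagram, select_stoichiometry
from .breakpoint import BreakpointOptions, TitrationCurve, estimate_cmc_batch
from .errors import FitError, ValidationError
from .workbench import FitReport, FoldChange

__all__ = ["analyze_titrations"]


def analyze_titrations(
    curves: Sequence[TitrationCurve],
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
    options: BreakpointOptions | None = None,
    provenance: dict | None = None,
) -> FitReport:
    """Run the full inference chain for one guest/condition batch.

    Estimates a CMC per CD level, assembles the micellar diagram, selects
    the stoichiometry, bootstraps parameter intervals (when ``seed`` and
    ``n_boot`` are given), and attaches the fold change of each apparent
    CMC over CMC0.
    """
    if not curves:
        raise ValidationError("no titration curves supplied")
    outcomes = estimate_cmc_batch(curves, options)
    good = [(o.cd_conc_m, o.fit) for o in outcomes if o.ok]
    failed = [o for o in outcomes if not o.ok]
    if len(good) < 3:
        raise FitError(
            f"only {len(good)} usable CMC fits (need >= 3); "
            + "; ".join(f"cd={o.cd_conc_m:g} M: {o.error}" for o in failed)
        )
    diagram = build_diagram(
        good, condition=curves[0].condition, guest=curves[0].guest, cd_unit="M"
    )
    fit = select_stoichiometry(diagram, alpha=alpha)
    if seed is not None and n_boot:
        fit = bootstrap_binding(fit, diagram, n_boot=n_boot, seed=seed)
    cmc0 = diagram.cmc_um[0]
    folds = tuple(
        FoldChange(
            label=f"CMC at {cd * 1e3:g} mM CD vs CMC0",
            numerator=float(cmc),
            denominator=float(cmc0),
            decimals=1,
        )
        for cd, cmc in zip(diagram.cd_conc_m[1:], diagram.cmc_um[1:])
    )
    prov = dict(provenance or {})
    if failed:
        prov["skipped_cd_levels"] = [
            {"cd_conc_mM": o.cd_conc_m * 1e3, "error": o.error} for o in failed
        ]
    return FitReport(
        guest=curves[0].guest,
        condition=curves[0].condition,
        breakpoints=tuple(good),
        binding=fit,
        fold_changes=folds,
        provenance=prov,
    )
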