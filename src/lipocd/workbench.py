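"""Delimited-text I/O, fold-change arithmetic and report assembly.

File conventions (all plain text, comma- or tab-delimited, decimal
point '.'):

* titrations — columns ``guest, cd_conc_mM, conc_uM, rel_fluorescence_pct,
  replicate, ph, temp_C, medium``; one row per measured point, grouped on
  read into :class:`~lipocd.breakpoint.TitrationCurve` objects per
  (guest, condition, CD level).
* micellar diagrams — columns ``guest, cd_conc_mM, cmc_uM, ph, temp_C,
  medium`` plus optional ``cmc_se_uM``.
* guest tables — columns ``name, formula, binding_energy_kcal_mol``.

CD concentrations are mM in files (the unit used at the bench) and mol/L
in memory; amphiphile concentrations are µM everywhere.

Narrative fold changes (e.g. "adding 0.25 mM CD raised the CMC
3.2-fold") use half-away-from-zero rounding at a stated number of
decimals, computed in decimal arithmetic so printed ratios are exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingFit, MicellarDiagram
from .breakpoint import BreakpointFit, ConditionSpec, Medium, TitrationCurve
from .equilibria import BindingModelKind
from .errors import AssemblyError, DomainError, SchemaError, ValidationError

__all__ = [
    "TITRATION_COLUMNS",
    "read_titrations",
    "write_titrations",
    "read_diagram",
    "write_diagram",
    "read_guests",
    "fold_change",
    "FoldChange",
    "FitReport",
    "ReportFormat",
    "render_report",
]

TITRATION_COLUMNS = (
    "guest",
    "cd_conc_mM",
    "conc_uM",
    "rel_fluorescence_pct",
    "replicate",
    "ph",
    "temp_C",
    "medium",
)

DIAGRAM_COLUMNS = ("guest", "cd_conc_mM", "cmc_uM", "ph", "temp_C", "medium")
GUEST_COLUMNS = ("name", "formula", "binding_energy_kcal_mol")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a delimited file with comma/tab auto-detection."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _check_nonneg(df: pd.DataFrame, column: str, path) -> None:
    bad = df.index[df[column] < 0]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        line = int(bad[0]) + 2
        raise ValidationError(f"{path}: negative {column} at line {line}")


def read_titrations(path: str | Path) -> list[TitrationCurve]:
    """Parse a titration file into curves grouped by guest, condition and CD level.

    Row order is irrelevant; the delimiter (comma or tab) is detected
    automatically.
    """
    df = _read_table(path, TITRATION_COLUMNS)
    _check_nonneg(df, "conc_uM", path)
    _check_nonneg(df, "cd_conc_mM", path)
    curves = []
    keys = ["guest", "ph", "temp_C", "medium", "cd_conc_mM"]
    for (guest, ph, temp, medium, cd_mm), grp in sorted(
        df.groupby(keys), key=lambda kv: kv[0]
    ):
        cond = ConditionSpec(ph=float(ph), temperature_c=float(temp), medium=Medium(medium))
        curves.append(
            TitrationCurve(
                conc_um=grp["conc_uM"].to_numpy(float),
                rel_fluorescence_pct=grp["rel_fluorescence_pct"].to_numpy(float),
                replicate=grp["replicate"].to_numpy(int),
                cd_conc_m=float(cd_mm) * 1e-3,
                condition=cond,
                guest=str(guest),
            )
        )
    return curves


def write_titrations(
    curves: Iterable[TitrationCurve], path: str | Path, delimiter: str = ","
) -> None:
    """Write curves in the schema :func:`read_titrations` parses (round-trip safe)."""
    rows = []
    for c in curves:
        for conc, fluo, rep in zip(c.conc_um, c.rel_fluorescence_pct, c.replicate):
            rows.append(
                dict(
                    guest=c.guest,
                    cd_conc_mM=c.cd_conc_m * 1e3,
                    conc_uM=conc,
                    rel_fluorescence_pct=fluo,
                    replicate=int(rep),
                    ph=c.condition.ph,
                    temp_C=c.condition.temperature_c,
                    medium=c.condition.medium.value,
                )
            )
    pd.DataFrame(rows, columns=list(TITRATION_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_diagram(path: str | Path) -> MicellarDiagram:
    """Read one micellar diagram (single guest/condition per file)."""
    df = _read_table(path, DIAGRAM_COLUMNS)
    _check_nonneg(df, "cd_conc_mM", path)
    if df["guest"].nunique() != 1:
        raise ValidationError(f"{path}: a diagram file must hold exactly one guest")
    df = df.sort_values("cd_conc_mM")
    cond = ConditionSpec(
        ph=float(df["ph"].iloc[0]),
        temperature_c=float(df["temp_C"].iloc[0]),
        medium=Medium(df["medium"].iloc[0]),
    )
    se = df["cmc_se_uM"].to_numpy(float) if "cmc_se_uM" in df.columns else None
    return MicellarDiagram(
        cd_conc_m=df["cd_conc_mM"].to_numpy(float) * 1e-3,
        cmc_um=df["cmc_uM"].to_numpy(float),
        cmc_se_um=se,
        condition=cond,
        guest=str(df["guest"].iloc[0]),
    )


def write_diagram(diagram: MicellarDiagram, path: str | Path, delimiter: str = ",") -> None:
    data = dict(
        guest=diagram.guest,
        cd_conc_mM=diagram.cd_conc_m * 1e3,
        cmc_uM=diagram.cmc_um,
        ph=diagram.condition.ph,
        temp_C=diagram.condition.temperature_c,
        medium=diagram.condition.medium.value,
    )
    if diagram.cmc_se_um is not None:
        data["cmc_se_uM"] = diagram.cmc_se_um
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def read_guests(path: str | Path):
    """Read a guest table into :class:`~lipocd.ligand.GuestMolecule` records."""
    from .ligand import GuestMolecule

    df = _read_table(path, GUEST_COLUMNS)
    out = []
    for _, row in df.iterrows():
        energy = row["binding_energy_kcal_mol"]
        out.append(
            GuestMolecule(
                name=str(row["name"]),
                formula=str(row["formula"]),
                binding_energy=None if pd.isna(energy) else float(energy),
            )
        )
    return out


def fold_change(numerator: float, denominator: float, decimals: int) -> float:
    """Ratio ``numerator/denominator`` rounded half-away-from-zero.

    >>> fold_change(136, 43, 1)
    3.2
    """
    if decimals < 0:
        raise DomainError("decimals must be >= 0")
    if denominator <= 0:
        raise DomainError(f"denominator must be positive, got {denominator}")
    q = Decimal(1).scaleb(-decimals)
    ratio = Decimal(repr(numerator)) / Decimal(repr(denominator))
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldChange:
    """A labelled narrative ratio; ``ratio`` is recomputed on construction."""

    label: str
    numerator: float
    denominator: float
    decimals: int
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ratio", fold_change(self.numerator, self.denominator, self.decimals)
        )


class ReportFormat(Enum):
    JSON_DOC = "json"
    TEXT_TABLE = "text"


@dataclass(frozen=True)
class FitReport:
    """Complete analysis record for one guest under one condition."""

    guest: str
    condition: ConditionSpec
    breakpoints: tuple[tuple[float, BreakpointFit], ...]  # (cd_conc_M, fit)
    binding: BindingFit | None
    fold_changes: tuple[FoldChange, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)


def file_digest(path: str | Path) -> str:
    """SHA256 of a file, for provenance records."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _binding_dict(fit: BindingFit) -> dict:
    p = fit.params
    params = {"cmc0_um": p.cmc0}
    if p.kind is BindingModelKind.ONE_TO_ONE:
        params["kc_per_m"] = p.kc
    else:
        params["k1_per_m"] = p.k1
        params["k2_per_m"] = p.k2
    def _num(x):
        return None if x is None or not np.isfinite(x) else float(x)

    d = {
        "model": p.kind.value,
        "params": params,
        "cmc0_source": fit.cmc0_source,
        "sse": fit.sse,
        "r_squared": _num(fit.r_squared),
        "f_statistic": _num(fit.f_statistic),
        "f_pvalue": fit.f_pvalue,
        "aicc_delta": fit.aicc_delta,
        "ci_lower": dict(fit.ci_lower) if fit.ci_lower else None,
        "ci_upper": dict(fit.ci_upper) if fit.ci_upper else None,
        "n_boot": fit.n_boot,
        "seed": fit.seed,
        "warnings": list(fit.warnings),
    }
    if fit.rival is not None:
        rival = fit.rival
        d["rival"] = {
            "model": rival.params.kind.value,
            "sse": rival.sse,
            "r_squared": _num(rival.r_squared),
        }
    return d


def report_to_dict(report: FitReport) -> dict:
    """Plain-dict form of a report (the JSON document layout)."""
    if report.binding is None:
        raise AssemblyError("report is incomplete: missing binding fit")
    if not report.breakpoints:
        raise AssemblyError("report is incomplete: no breakpoint fits")
    return {
        "guest": report.guest,
        "condition": {
            "ph": report.condition.ph,
            "temp_C": report.condition.temperature_c,
            "medium": report.condition.medium.value,
            "label": report.condition.label,
        },
        "breakpoints": [
            {
                "cd_conc_mM": cd * 1e3,
                "cmc_uM": bf.cmc_um,
                "pre_slope": bf.pre_slope,
                "post_slope": bf.post_slope,
                "sse": bf.sse,
                "n_pre": bf.n_pre,
                "n_post": bf.n_post,
                "log_axis": bf.log_axis,
                "warnings": list(bf.warnings),
            }
            for cd, bf in report.breakpoints
        ],
        "binding": _binding_dict(report.binding),
        "fold_changes": [
            {
                "label": fc.label,
                "numerator": fc.numerator,
                "denominator": fc.denominator,
                "decimals": fc.decimals,
                "ratio": fc.ratio,
            }
            for fc in report.fold_changes
        ],
        "provenance": dict(report.provenance),
    }


def render_report(report: FitReport, fmt: ReportFormat = ReportFormat.JSON_DOC) -> str:
    """Serialize a report; byte-stable for identical inputs."""
    doc = report_to_dict(report)
    if fmt is ReportFormat.JSON_DOC:
        return json.dumps(doc, indent=2, sort_keys=True, allow_nan=False) + "\n"
    lines = [
        f"guest: {doc['guest']}",
        "condition: pH {ph} | {temp_C} degC | {medium}".format(**doc["condition"]),
        "",
        "breakpoints (apparent CMC per CD level):",
        f"  {'cd_mM':>10} {'cmc_uM':>14} {'n_pre':>6} {'n_post':>7}",
    ]
    for bp in doc["breakpoints"]:
        lines.append(
            f"  {bp['cd_conc_mM']:>10.4g} {bp['cmc_uM']:>14.6g} "
            f"{bp['n_pre']:>6d} {bp['n_post']:>7d}"
        )
    b = doc["binding"]
    lines += ["", f"binding model: {b['model']} (CMC0 {b['cmc0_source']})"]
    for name, val in b["params"].items():
        ci = ""
        if b["ci_lower"] and name.split("_")[0] in {k.split("_")[0] for k in b["ci_lower"]}:
            key = {"cmc0_um": "cmc0", "kc_per_m": "kc", "k1_per_m": "k1", "k2_per_m": "k2"}[name]
            if key in b["ci_lower"]:
                ci = f"  [{b['ci_lower'][key]:.6g}, {b['ci_upper'][key]:.6g}]"
        lines.append(f"  {name} = {val:.6g}{ci}")
    if b["f_pvalue"] is not None:
        lines.append(f"  curvature test p = {b['f_pvalue']:.4g}")
    if doc["fold_changes"]:
        lines += ["", "fold changes:"]
        for fc in doc["fold_changes"]:
            lines.append(
                f"  {fc['label']}: {fc['numerator']:g} / {fc['denominator']:g} "
                f"= {fc['ratio']:g} ({fc['decimals']} dp)"
            )
    return "\n".join(lines) + "\n"
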