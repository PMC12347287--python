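"""Ligand-efficiency metrics for host-guest binding energies.

End-point binding free energies (MM-GBSA convention, kcal/mol, more
negative = stronger) scale with molecular size, so raw energies favour
large guests.  Ligand efficiency (LE) — binding energy divided by the
number of non-hydrogen ("heavy") atoms — normalizes for size and often
reorders a guest series, reconciling computed energies with measured
association constants.

Formulas are plain element+count token strings (Hill-style, e.g.
``"C18H32O2"``); hydrogen and its isotopes D/T are excluded from the
heavy-atom count.  Charges, isotope labels and structural grouping are
not supported — guests here are simple neutral organics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable

from .errors import FormatError, ValidationError

__all__ = [
    "GuestMolecule",
    "LigandEfficiencyResult",
    "RankMetric",
    "heavy_atom_count",
    "ligand_efficiency",
    "rank_guests",
    "PAPER_GUESTS",
]

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og D T".split()
)
_HYDROGENS = frozenset({"H", "D", "T"})
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class GuestMolecule:
    """A guest compound: name, molecular formula, optional binding energy.

    ``binding_energy`` is in kcal/mol with the sign convention that more
    negative means stronger binding.
    """

    name: str
    formula: str
    binding_energy: float | None = None

    def __post_init__(self) -> None:
        heavy_atom_count(self.formula)  # validates


@dataclass(frozen=True)
class LigandEfficiencyResult:
    """Binding energy per heavy atom for one guest."""

    name: str
    binding_energy: float
    heavy_atoms: int
    le: float

    @property
    def le_rounded(self) -> float:
        """LE rounded half-away-from-zero to 3 decimals, for summaries."""
        return _round_half_away(self.le, 3)


class RankMetric(Enum):
    RAW_ENERGY = "raw_energy"
    LE = "ligand_efficiency"


def _round_half_away(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an element+count token string into an element->count map."""
    if not formula or not isinstance(formula, str):
        raise FormatError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormatError(f"unparseable formula {formula!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise FormatError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormatError(f"zero count for element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(formula) or not counts:
        raise FormatError(f"unparseable formula {formula!r}")
    return counts


def heavy_atom_count(formula: str) -> int:
    """Number of non-hydrogen atoms in a molecular formula.

    >>> heavy_atom_count("C18H32O2")
    20
    """
    counts = parse_formula(formula)
    return sum(n for sym, n in counts.items() if sym not in _HYDROGENS)


def ligand_efficiency(guest: GuestMolecule) -> LigandEfficiencyResult:
    """Binding energy per heavy atom (kcal/mol per atom).

    The ratio is computed in decimal arithmetic so that summary rounding
    reproduces printed values exactly; full float precision is retained
    in ``le``.
    """
    if guest.binding_energy is None:
        raise ValidationError(f"guest {guest.name!r} has no binding energy")
    heavy = heavy_atom_count(guest.formula)
    le = float(Decimal(repr(guest.binding_energy)) / heavy)
    return LigandEfficiencyResult(
        name=guest.name,
        binding_energy=guest.binding_energy,
        heavy_atoms=heavy,
        le=le,
    )


def rank_guests(
    guests: Iterable[GuestMolecule], metric: RankMetric = RankMetric.RAW_ENERGY
) -> list[GuestMolecule]:
    """Order guests by the chosen metric, most negative (strongest) first.

    Stable for ties: input order is preserved.
    """
    guests = list(guests)
    if not guests:
        return []
    for g in guests:
        if g.binding_energy is None:
            raise ValidationError(f"guest {g.name!r} has no binding energy")
    if metric is RankMetric.RAW_ENERGY:
        key = lambda g: g.binding_energy
    else:
        key = lambda g: g.binding_energy / heavy_atom_count(g.formula)
    return sorted(guests, key=key)


# Reference guest set: the two lipophenol conjugates, their parent fatty
# acids, the parent polyphenol and the fluorescent probe, with published
# MM-GBSA binding energies toward HP-beta-cyclodextrin.  Formulas follow
# the standard structures (esterification condenses out one H2O).
PAPER_GUESTS: tuple[GuestMolecule, ...] = (
    GuestMolecule("LA", "C18H32O2", -47.24),
    GuestMolecule("DHA", "C22H32O2", -51.05),
    GuestMolecule("resveratrol", "C14H12O3", -45.52),
    GuestMolecule("Resv-4'-LA", "C32H42O4", -64.36),
    GuestMolecule("Resv-4'-DHA", "C36H42O4", -58.34),
    GuestMolecule("DPHT", "C18H16", -47.38),
)
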