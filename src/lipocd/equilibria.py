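"""Forward equilibrium models for cyclodextrin--amphiphile complexation.

An amphiphilic guest (a fatty acid or a lipophenol conjugate) micellizes
above its critical micelle concentration.  Adding a cyclodextrin (CD) host
sequesters monomers into inclusion complexes and thereby raises the
apparent CMC.  For a 1:1 complex with association constant ``Kc`` the
apparent CMC grows linearly with total CD concentration,

    CMC([CD]) = CMC0 * (1 + Kc * [CD]),

while sequential 1:2 binding (a second CD capping the same guest, with
stepwise constants ``K1`` and ``K2``) adds a quadratic term,

    CMC([CD]) = CMC0 * (1 + K1*[CD] + K1*K2*[CD]**2).

These closed forms are the package's forward models: the fitting module
inverts them against measured micellar diagrams, and the synthetic-data
module uses them as ground truth.

Unit convention: CD concentrations in mol/L (M), CMC values in µM, all
association constants in M^-1.  Conversions from the mM used in data
files happen at the I/O boundary only.  The CD concentration entering
these equations is the *total* added CD, matching how micellar diagrams
are plotted; no free-CD correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DomainError

__all__ = [
    "BindingModelKind",
    "BindingParams",
    "SpeciesFractions",
    "eval_cmc",
    "eval_cmc_1to1",
    "eval_cmc_1to2",
    "species_fractions",
]


class BindingModelKind(Enum):
    """Stoichiometry of the host-guest inclusion complex."""

    ONE_TO_ONE = "1:1"
    ONE_TO_TWO = "1:2"


@dataclass(frozen=True)
class BindingParams:
    """Parameters of a CMC-shift binding model.

    Exactly the constants matching ``kind`` must be present: ``kc`` for a
    1:1 model, ``k1`` and ``k2`` for a sequential 1:2 model.

    Parameters
    ----------
    kind :
        Complex stoichiometry.
    cmc0 :
        CMC in the absence of CD (µM); must be positive.
    kc, k1, k2 :
        Association constants (M^-1); must be non-negative.
    """

    kind: BindingModelKind
    cmc0: float
    kc: float | None = None
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cmc0) or self.cmc0 <= 0:
            raise DomainError(f"cmc0 must be positive and finite, got {self.cmc0}")
        if self.kind is BindingModelKind.ONE_TO_ONE:
            if self.kc is None or self.k1 is not None or self.k2 is not None:
                raise DomainError("a 1:1 model takes exactly the constant kc")
            if self.kc < 0:
                raise DomainError(f"kc must be non-negative, got {self.kc}")
        else:
            if self.kc is not None or self.k1 is None or self.k2 is None:
                raise DomainError("a 1:2 model takes exactly the constants k1, k2")
            if self.k1 < 0 or self.k2 < 0:
                raise DomainError("k1 and k2 must be non-negative")

    @classmethod
    def one_to_one(cls, cmc0: float, kc: float) -> "BindingParams":
        return cls(BindingModelKind.ONE_TO_ONE, cmc0, kc=kc)

    @classmethod
    def one_to_two(cls, cmc0: float, k1: float, k2: float) -> "BindingParams":
        return cls(BindingModelKind.ONE_TO_TWO, cmc0, k1=k1, k2=k2)


@dataclass(frozen=True)
class SpeciesFractions:
    """Equilibrium fractions of guest species at a given free CD level.

    ``free`` + ``complex_1_1`` + ``complex_1_2`` sums to one: every guest
    monomer is either free, bound by one CD, or capped by two.
    """

    free: float
    complex_1_1: float
    complex_1_2: float


def _check_cd(cd):
    cd = np.asarray(cd, dtype=float)
    if np.any(cd < 0) or not np.all(np.isfinite(cd)):
        raise DomainError("CD concentration must be finite and non-negative")
    return cd


def eval_cmc_1to1(params: BindingParams, cd):
    """Apparent CMC (µM) under the 1:1 model at total CD concentration ``cd`` (M).

    Accepts a scalar or array ``cd``; strictly increasing in ``cd`` when
    ``kc > 0``.
    """
    if params.kind is not BindingModelKind.ONE_TO_ONE:
        raise DomainError("eval_cmc_1to1 requires 1:1 parameters")
    cd = _check_cd(cd)
    out = params.cmc0 * (1.0 + params.kc * cd)
    return out if out.ndim else float(out)


def eval_cmc_1to2(params: BindingParams, cd):
    """Apparent CMC (µM) under the sequential 1:2 model at total CD ``cd`` (M).

    Reduces exactly to the 1:1 model with ``kc = k1`` when ``k2 == 0``.
    """
    if params.kind is not BindingModelKind.ONE_TO_TWO:
        raise DomainError("eval_cmc_1to2 requires 1:2 parameters")
    cd = _check_cd(cd)
    out = params.cmc0 * (1.0 + params.k1 * cd + params.k1 * params.k2 * cd**2)
    return out if out.ndim else float(out)


def eval_cmc(params: BindingParams, cd):
    """Apparent CMC under whichever model ``params`` encodes."""
    if params.kind is BindingModelKind.ONE_TO_ONE:
        return eval_cmc_1to1(params, cd)
    return eval_cmc_1to2(params, cd)


def species_fractions(k1: float, k2: float, cd_free: float) -> SpeciesFractions:
    """Fractions of free, singly and doubly complexed guest at free CD ``cd_free`` (M).

    From the stepwise mass-action laws
    ``K1 = [GC]/([G][C])`` and ``K2 = [GC2]/([GC][C])`` the normalized
    closed form is ``f0 = 1/(1 + K1*c + K1*K2*c**2)``, ``f1 = K1*c*f0``,
    ``f2 = K1*K2*c**2*f0``.  Free CD is taken as an explicit argument; the
    ternary mass balance over total CD is not solved here.
    """
    if k1 < 0 or k2 < 0 or cd_free < 0:
        raise DomainError("k1, k2 and cd_free must be non-negative")
    denom = 1.0 + k1 * cd_free + k1 * k2 * cd_free**2
    f0 = 1.0 / denom
    return SpeciesFractions(
        free=f0,
        complex_1_1=k1 * cd_free * f0,
        complex_1_2=k1 * k2 * cd_free**2 * f0,
    )
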