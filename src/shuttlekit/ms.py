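"""Exact-mass identification arithmetic for small-molecule HRMS.

Covers the calculations used to pin down an unknown metabolite from
high-resolution ESI-MS data: molecular-formula parsing, adduct m/z with and
without the electron-mass correction, ppm mass error, exchangeable-hydrogen
counting from a functional-group profile, and the mass shift expected in a
D₂O-exchange (HDX) experiment.

Two m/z conventions coexist in the literature for a singly charged cation:
with the electron-mass correction (the physically exact ion mass) and
without it (summing neutral-atom masses).  Both are first-class here because
published values mix them freely; ``electron_correction=True`` is the
default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .masses import (
    DEUTERIUM_SHIFT,
    ELECTRON_MASS,
    MASS_TABLE_VERSION,
    MONOISOTOPIC_MASS,
)

__all__ = [
    "FormulaError",
    "AdductError",
    "MolecularFormula",
    "IonSpecies",
    "LabileHydrogenProfile",
    "CandidateMatch",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "count_labile_hydrogens",
    "hdx_mass_shift",
    "screen_candidates",
]


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula."""


class AdductError(ValueError):
    """Adduct arithmetic cannot be applied to the given neutral formula."""


# Hill-style token: either a labelled isotope like [15N] or an element symbol,
# followed by an optional count.
_TOKEN = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with the pinned mass-table version it refers to."""

    composition: dict[str, int]
    mass_table_version: str = MASS_TABLE_VERSION

    def __post_init__(self) -> None:
        for symbol, count in self.composition.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"element {symbol!r} not in pinned mass table")
            if count < 1:
                raise FormulaError(f"count for {symbol!r} must be >= 1, got {count}")

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.composition.items())

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.composition)
        for s, n in other.composition.items():
            merged[s] = merged.get(s, 0) + n
        return MolecularFormula(merged)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C11H7NO4"``.

    Bare symbols carry an implicit count of 1.  Labelled isotopes are
    written in brackets, e.g. ``"C11H7[15N]O4"`` for the ¹⁵N species.

    Raises
    ------
    FormulaError
        On unknown elements, explicit zero counts, or any text that is not
        a sequence of element-count tokens.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    composition: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:m.start()]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for {symbol!r} in {text!r}")
        composition[symbol] = composition.get(symbol, 0) + count
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r}")
    return MolecularFormula(composition)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.monoisotopic_mass


# adduct name → (composition delta, signed charge)
ADDUCTS: dict[str, tuple[dict[str, int], int]] = {
    "[M+H]+": ({"H": +1}, +1),
    "[M+Na]+": ({"Na": +1}, +1),
    "[M+D]+": ({"D": +1}, +1),
    "[M-H2O+H]+": ({"H": -1, "O": -1}, +1),
    "[M+NH4]+": ({"N": +1, "H": +4}, +1),
    "[M-H]-": ({"H": -1}, -1),
}

#: Adducts whose ionizing species is a proton (relevant to HDX conventions).
PROTONATED_ADDUCTS = frozenset({"[M+H]+", "[M+D]+", "[M-H2O+H]+"})


@dataclass(frozen=True)
class IonSpecies:
    """A neutral formula ionized as one of the supported ESI adducts."""

    formula: MolecularFormula
    adduct: str
    electron_correction: bool = True

    def __post_init__(self) -> None:
        if self.adduct not in ADDUCTS:
            raise AdductError(
                f"unsupported adduct {self.adduct!r}; supported: {sorted(ADDUCTS)}"
            )

    @property
    def charge(self) -> int:
        return ADDUCTS[self.adduct][1]

    def ion_composition(self) -> dict[str, int]:
        """Adduct-adjusted element counts of the ion.

        Raises :class:`AdductError` if the delta would drive any element
        count negative (e.g. water loss from a formula without enough H/O).
        """
        delta, _ = ADDUCTS[self.adduct]
        comp = dict(self.formula.composition)
        for s, dn in delta.items():
            comp[s] = comp.get(s, 0) + dn
            if comp[s] < 0:
                raise AdductError(
                    f"adduct {self.adduct} removes more {s} than present in "
                    f"{self.formula.composition}"
                )
            if comp[s] == 0:
                del comp[s]
        return comp


def ion_mz(ion: IonSpecies, decimals: int | None = 4) -> float:
    """Calculated m/z of an ion species in Da.

    Sums the pinned monoisotopic masses of the adduct-adjusted composition,
    subtracts ``charge × electron mass`` when the electron correction is on,
    and divides by ``|charge|``.  ``decimals=None`` returns the unrounded
    value; the default (4) matches the precision at which HRMS m/z values
    are customarily reported.
    """
    comp = ion.ion_composition()
    mass = sum(MONOISOTOPIC_MASS[s] * n for s, n in comp.items())
    charge = ion.charge
    if ion.electron_correction:
        mass -= charge * ELECTRON_MASS
    mz = mass / abs(charge)
    return round(mz, decimals) if decimals is not None else mz


def ppm_error(observed: float, calculated: float, *, signed: bool = False) -> float:
    """Relative mass error in parts per million.

    ``(observed − calculated) / calculated × 10⁶``; the absolute value is
    returned unless ``signed=True``.  The calculated mass sits in the
    denominator.  Values are customarily reported rounded to one decimal.
    """
    if calculated <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calculated}")
    err = (observed - calculated) / calculated * 1e6
    return err if signed else abs(err)


# exchangeable hydrogens contributed per functional group
_LABILE_WEIGHTS = {
    "primary_amine": 2,
    "secondary_amine": 1,
    "carboxylic_acid": 1,
    "hydroxyl": 1,
    "thiol": 1,
    "amide_nh": 1,  # count is the number of amide N–H hydrogens
}


@dataclass(frozen=True)
class LabileHydrogenProfile:
    """Counts of functional groups bearing solvent-exchangeable hydrogens.

    ``amide_nh`` counts individual N–H hydrogens (a primary amide
    contributes 2, a secondary amide 1).
    """

    primary_amine: int = 0
    secondary_amine: int = 0
    carboxylic_acid: int = 0
    hydroxyl: int = 0
    thiol: int = 0
    amide_nh: int = 0

    def __post_init__(self) -> None:
        for name in _LABILE_WEIGHTS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")


def count_labile_hydrogens(profile: LabileHydrogenProfile) -> int:
    """Total exchangeable hydrogens implied by a functional-group profile."""
    return sum(getattr(profile, g) * w for g, w in _LABILE_WEIGHTS.items())


def hdx_mass_shift(
    n_labile: int,
    adduct: str,
    convention: str = "exchange-only",
) -> tuple[float, int]:
    """Mass shift expected in a D₂O-exchange experiment.

    Parameters
    ----------
    n_labile
        Number of solvent-exchangeable hydrogens on the neutral molecule.
    adduct
        Ion adduct observed (determines whether the ionizing deuteron can
        add an extra H→D increment).
    convention
        ``"exchange-only"`` counts only the molecule's labile hydrogens
        (k = n_labile); ``"include-ionizing-deuteron"`` adds one increment
        for the charging deuteron (k = n_labile + 1) and is only defined
        for protonated adducts.

    Returns
    -------
    (exact_da, nominal_da)
        Exact shift ``k × (m_D − m_H)`` and its nearest-integer nominal
        value.
    """
    if n_labile < 0:
        raise ValueError("n_labile must be >= 0")
    if adduct not in ADDUCTS:
        raise AdductError(f"unsupported adduct {adduct!r}")
    if convention == "exchange-only":
        k = n_labile
    elif convention == "include-ionizing-deuteron":
        if adduct not in PROTONATED_ADDUCTS:
            raise AdductError(
                "include-ionizing-deuteron convention requires a protonated "
                f"adduct, got {adduct}"
            )
        k = n_labile + 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    exact = k * DEUTERIUM_SHIFT
    return exact, round(exact)


@dataclass(frozen=True)
class CandidateMatch:
    """One candidate ion that matched an observed m/z within tolerance."""

    ion: IonSpecies
    calculated_mz: float
    ppm: float  # signed

    @property
    def abs_ppm(self) -> float:
        return abs(self.ppm)


def screen_candidates(
    observed: float,
    candidates: list[IonSpecies],
    tolerance_ppm: float,
) -> list[CandidateMatch]:
    """Screen candidate ions against an observed m/z.

    Returns the candidates whose |ppm error| is within ``tolerance_ppm``,
    each annotated with its calculated m/z (at the default reporting
    precision, 4 decimals, matching how printed ppm values are derived)
    and signed ppm, sorted by |ppm| ascending.
    """
    if observed <= 0:
        raise ValueError(f"observed m/z must be positive, got {observed}")
    if tolerance_ppm <= 0:
        raise ValueError(f"tolerance_ppm must be positive, got {tolerance_ppm}")
    matches = []
    for ion in candidates:
        mz = ion_mz(ion)
        ppm = ppm_error(observed, mz, signed=True)
        if abs(ppm) <= tolerance_ppm:
            matches.append(CandidateMatch(ion=ion, calculated_mz=mz, ppm=ppm))
    return sorted(matches, key=lambda m: m.abs_ppm)
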