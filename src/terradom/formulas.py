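"""Molecular formulas of dissolved organic matter: parsing, DBE-O, element ratios.

DOM molecular formula assignments from FT-MS are restricted here to the
CHNOS element space, which covers the compositions reported for marine and
terrestrial end members.  The double-bond-equivalents-minus-oxygen (DBE-O)
criterion is the standard plausibility filter for natural organic matter
formula sets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "dbe_o",
    "element_ratio",
    "filter_formula_space",
]

#: Supported element symbols, in Hill order (C, H, then alphabetical).
ELEMENTS = ("C", "H", "N", "O", "S")

#: Monoisotopic masses in Da of the most abundant isotopes.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or out-of-scope formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """A CHNOS molecular formula with an optional neutral mass.

    Parameters
    ----------
    counts
        Mapping of element symbol to a non-negative integer count.  Every
        element of :data:`ELEMENTS` is present; carbon and hydrogen counts
        must be at least one (CHNOS organic matter convention).
    neutral_mass
        Neutral monoisotopic mass in Da; computed from the counts when not
        supplied.
    """

    counts: dict = field(hash=False)
    neutral_mass: float | None = None

    def __post_init__(self):
        counts = {el: int(self.counts.get(el, 0)) for el in ELEMENTS}
        for el, n in counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
        if counts["C"] < 1 or counts["H"] < 1:
            raise FormulaError(
                f"formula must contain C and H (got {counts})"
            )
        object.__setattr__(self, "counts", counts)
        if self.neutral_mass is None:
            mass = sum(n * MONOISOTOPIC_MASS[el] for el, n in counts.items())
            object.__setattr__(self, "neutral_mass", mass)
        elif self.neutral_mass <= 0:
            raise FormulaError("neutral mass must be positive")

    @property
    def label(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for el in ELEMENTS:
            n = self.counts[el]
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __getitem__(self, element: str) -> int:
        return self.counts[element]

    def __eq__(self, other):
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self):
        return hash(tuple(self.counts[el] for el in ELEMENTS))

    def __repr__(self):
        return f"MolecularFormula({self.label!r})"


def parse_formula(label: str) -> MolecularFormula:
    """Parse a Hill-notation CHNOS formula string.

    An absent count means one ("CH4" has one carbon).  Unknown elements —
    including phosphorus, which the CHNOS formula space deliberately
    excludes — raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(label, str) or not label.strip():
        raise FormulaError("empty formula string")
    label = label.strip()
    pos = 0
    counts = {el: 0 for el in ELEMENTS}
    for match in _TOKEN.finditer(label):
        if match.start() != pos:
            bad = label[pos:match.start()]
            raise FormulaError(f"unparseable token {bad!r} in {label!r}")
        if not match.group(0):
            continue
        el, digits = match.group(1), match.group(2)
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element {el!r} in {label!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {el!r} in {label!r}")
        if counts[el]:
            raise FormulaError(f"repeated element {el!r} in {label!r}")
        counts[el] = n
        pos = match.end()
    if pos != len(label):
        raise FormulaError(f"unparseable token {label[pos:]!r} in {label!r}")
    return MolecularFormula(counts)


def dbe_o(formula: MolecularFormula) -> float:
    """Double-bond equivalents minus oxygen.

    DBE uses the standard halogen-free CHNOS form 1 + C - H/2 + N/2,
    where sulfur and oxygen do not contribute to the ring-and-double-bond
    count; oxygen is then subtracted.
    """
    c = formula.counts
    return 1.0 + c["C"] - c["H"] / 2.0 + c["N"] / 2.0 - c["O"]


def element_ratio(formula, num: str, den: str) -> float:
    """Atomic ratio ``num``/``den``, e.g. N/C or S/C.

    Also accepts plain mappings with fractional counts, as produced by
    weighted-average compositions.
    """
    counts = formula.counts if isinstance(formula, MolecularFormula) else formula
    d = counts[den]
    if d == 0:
        raise FormulaError(f"zero denominator count for element {den!r}")
    return counts[num] / d


def filter_formula_space(formulas, max_dbe_o: float = 10.0):
    """Keep formulas with DBE-O at most ``max_dbe_o``; order preserved."""
    return [f for f in formulas if dbe_o(f) <= max_dbe_o or math.isinf(max_dbe_o)]
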