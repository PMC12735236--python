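"""Elemental-formula arithmetic for negative-mode small-molecule MS.

Everything downstream of the mass spectrometer reduces to sums of
monoisotopic atomic masses: theoretical [M-H]^- values for dereplication,
neutral-loss targets for diagnostic fragmentation rules, and candidate
formulas for observed mass deltas. This module is the single source of
those numbers.

Masses are IUPAC monoisotopic values; ionic m/z for a singly charged
anion includes the electron mass (without it the printed 4-decimal
calcd values cannot be reproduced). Supported elements: C, H, N, O, P, S
-- sufficient for every composition encountered in sponge triterpenoid
and lyso-lipid work.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "mz_anion",
    "nominal_mass",
    "rdbe",
    "ppm_error",
    "infer_delta_formula",
]

#: Monoisotopic atomic masses, Da (IUPAC / CODATA).
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Electron rest mass, Da.
ELECTRON_MASS: float = 0.00054857990946

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings / operations."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map for a neutral molecule, ion, or neutral loss.

    Zero counts are normalized away, so two formulas compare equal iff
    they denote the same composition. Supports ``+`` (union of atoms)
    and ``-`` (removal; raises if any count would go negative).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"cannot remove {n} {el} from {self}: only {merged.get(el, 0)} present"
                )
            merged[el] = left
        return ElementalFormula(merged)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self.counts == other.counts

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging sugar
        return f"ElementalFormula({format_formula(self)!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C30H40O4"``.

    Raises :class:`FormulaError` naming the offending token for empty
    input, unsupported element symbols, or stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:m.start()]!r}"
            )
        if not m.group(0):
            continue
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unsupported element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(
            f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
        )
    return ElementalFormula(counts)


_HILL_ORDER = ("C", "H", "N", "O", "P", "S")


def format_formula(f: ElementalFormula) -> str:
    """Serialize in Hill order (C, H, then alphabetic); '' for the empty formula."""
    parts = []
    for el in _HILL_ORDER:
        n = f[el]
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of count-weighted atomic masses)."""
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts.items())


H = ElementalFormula({"H": 1})


def mz_deprotonated(neutral: ElementalFormula) -> float:
    """Theoretical m/z of the singly charged [M-H]^- ion of a neutral molecule.

    m/z = mass(M) - mass(H) + mass(electron). Requires at least one
    removable hydrogen.
    """
    if neutral["H"] < 1:
        raise FormulaError(
            f"{format_formula(neutral) or 'empty formula'} has no hydrogen to remove"
        )
    return monoisotopic_mass(neutral) - ATOMIC_MASS["H"] + ELECTRON_MASS


def mz_anion(anion: ElementalFormula) -> float:
    """m/z of a singly charged anion given its ionic composition.

    The composition already accounts for the lost proton (e.g. C30H39O4
    for the [M-H]^- ion of C30H40O4); only the electron mass is added.
    """
    return monoisotopic_mass(anion) + ELECTRON_MASS


def nominal_mass(mz: float) -> int:
    """Nominal (integer) mass: the monoisotopic value rounded to nearest integer."""
    return int(round(mz))


def rdbe(f: ElementalFormula) -> float:
    """Ring-and-double-bond equivalents of a neutral CHNOPS formula.

    RDBE = C - H/2 + N/2 + P/2 + 1 (P trivalent; O and S ignored).
    Integer-valued for even-electron neutral molecules.
    """
    return f["C"] - f["H"] / 2.0 + f["N"] / 2.0 + f["P"] / 2.0 + 1.0


def ppm_error(measured: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


def infer_delta_formula(
    delta_mass: float,
    tol_ppm: float = 10.0,
    bounds: Mapping[str, int] | None = None,
) -> list[ElementalFormula]:
    """Candidate elemental compositions for an observed neutral mass delta.

    Exhaustively enumerates the bounded element lattice and returns every
    composition whose neutral monoisotopic mass lies within ``tol_ppm``
    of ``delta_mass`` (for ``delta_mass`` 0 an absolute window of 1e-6 Da
    is used, matching only the empty formula). Candidates are ordered by
    absolute ppm error, then lexicographically by serialized formula, so
    the output is deterministic.

    ``bounds`` maps element symbols to maximum counts; missing elements
    are excluded. An empty/None bounds map yields only what it can:
    the empty-formula match for delta 0, else nothing.
    """
    if delta_mass < 0:
        raise ValueError(f"delta_mass must be non-negative, got {delta_mass}")
    bounds = dict(bounds or {})
    for el in bounds:
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unsupported element symbol in bounds: {el!r}")
    tol_da = delta_mass * tol_ppm * 1e-6 if delta_mass > 0 else 1e-6
    elements = sorted(bounds)
    ranges: Iterable[Iterable[int]] = (range(bounds[el] + 1) for el in elements)
    hits: list[tuple[float, str, ElementalFormula]] = []
    for combo in itertools.product(*ranges):
        mass = sum(ATOMIC_MASS[el] * n for el, n in zip(elements, combo))
        if abs(mass - delta_mass) <= tol_da:
            f = ElementalFormula(dict(zip(elements, combo)))
            err = abs(mass - delta_mass) / delta_mass * 1e6 if delta_mass > 0 else 0.0
            hits.append((err, format_formula(f), f))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in hits]
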