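"""Fatty-acid shorthand parsing, molecular formulas and isotopologue m/z series.

Fatty acids are named by the common ``C<carbons>:<double bonds>`` shorthand,
optionally with a cis/trans tag and an omega (n-) position, e.g. ``C18:3n3``
or ``16:1c``.  Under negative-ion chemical ionisation of the pentafluorobenzyl
ester, the PFB group is lost in the source and the detected species is the
bare carboxylate anion [M-H]-; all m/z arithmetic here is therefore on the
free acid minus one proton.  Only straight-chain CxHyO2 acids are modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "FattyAcid",
    "MolecularFormula",
    "parse_fatty_acid_name",
    "free_acid_formula",
    "carboxylate_anion_formula",
    "isotopologue_mz_series",
    "reference_table",
]

# Nominal (integer) and monoisotopic atomic masses for the elements of a
# straight-chain fatty acid.  Monoisotopic values are CODATA/IUPAC standard.
NOMINAL_MASS = {"C": 12, "H": 1, "O": 16}
MONOISOTOPIC_MASS = {"C": 12.0, "H": 1.00782503207, "O": 15.9949146196}
ELECTRON_MASS = 0.000548579909

#: Mass difference between 13C and 12C in u — the exact isotopologue spacing.
C13_SPACING = 1.0033548378

_NAME_RE = re.compile(r"^C?(\d+):(\d+)([ct])?(?:n(\d+))?$")


@dataclass(frozen=True)
class FattyAcid:
    """A straight-chain fatty acid identified by its shorthand descriptors."""

    n_carbons: int
    n_double_bonds: int = 0
    n_position: int | None = None
    geometry: str | None = None  # "c", "t" or None

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"n_carbons must be >= 1, got {self.n_carbons}")
        if not 0 <= self.n_double_bonds < self.n_carbons:
            raise ValueError(
                f"n_double_bonds must be in [0, n_carbons), got "
                f"{self.n_double_bonds} for {self.n_carbons} carbons"
            )
        if self.geometry not in (None, "c", "t"):
            raise ValueError(f"geometry must be 'c', 't' or None, got {self.geometry!r}")

    @property
    def display_name(self) -> str:
        name = f"C{self.n_carbons}:{self.n_double_bonds}"
        if self.geometry:
            name += self.geometry
        if self.n_position is not None:
            name += f"n{self.n_position}"
        return name

    def __str__(self) -> str:
        return self.display_name


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with a formal charge (0 free acid, -1 anion)."""

    element_counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        for elem, count in self.element_counts:
            if count < 0:
                raise ValueError(f"negative count for element {elem}")

    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0) -> "MolecularFormula":
        return cls(tuple(sorted(counts.items())), charge)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def nominal_mass(self) -> int:
        return sum(NOMINAL_MASS[e] * n for e, n in self.element_counts)

    def monoisotopic_mz(self) -> float:
        """Monoisotopic m/z: neutral mass adjusted for electron gain/loss."""
        mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in self.element_counts)
        mass -= self.charge * ELECTRON_MASS
        z = abs(self.charge) or 1
        return mass / z

    def __str__(self) -> str:
        body = "".join(f"{e}{n}" for e, n in self.element_counts if n)
        if self.charge == -1:
            body += "-"
        elif self.charge:
            body += f"{self.charge:+d}"
        return body


def parse_fatty_acid_name(name: str) -> FattyAcid:
    """Parse shorthand like ``C18:3n3``, ``16:1c`` or ``C18:0``.

    The leading ``C`` is optional; a single ``c``/``t`` geometry tag and an
    ``n<int>`` omega position may follow the double-bond count.

    Raises
    ------
    ValueError
        If the string does not match the shorthand grammar; the message
        names the offending token.
    """
    stripped = name.strip()
    m = _NAME_RE.match(stripped)
    if m is None:
        # Point at the first token that breaks the grammar for a usable error.
        head = re.match(r"^C?\d+:\d+", stripped)
        offending = stripped[head.end():] if head else stripped
        raise ValueError(
            f"cannot parse fatty acid name {name!r}: unrecognised token {offending!r}"
        )
    carbons, dbonds, geometry, npos = m.groups()
    return FattyAcid(
        n_carbons=int(carbons),
        n_double_bonds=int(dbonds),
        n_position=int(npos) if npos is not None else None,
        geometry=geometry,
    )


def free_acid_formula(fa: FattyAcid) -> MolecularFormula:
    """CxHyO2 with y = 2x - 2*(double bonds); neutral species."""
    return MolecularFormula.from_dict(
        {"C": fa.n_carbons, "H": 2 * fa.n_carbons - 2 * fa.n_double_bonds, "O": 2},
        charge=0,
    )


def carboxylate_anion_formula(fa: FattyAcid) -> MolecularFormula:
    """The [M-H]- carboxylate anion observed under NCI: one H fewer, charge -1."""
    free = free_acid_formula(fa)
    counts = free.counts
    counts["H"] -= 1
    return MolecularFormula.from_dict(counts, charge=-1)


def isotopologue_mz_series(
    fa: FattyAcid, spacing: str | float = "nominal"
) -> list[tuple[int, float]]:
    """(label_count, m/z) for M+0 .. M+n of the carboxylate anion.

    Parameters
    ----------
    fa
        The fatty acid; the series has ``n_carbons + 1`` entries.
    spacing
        ``"nominal"`` (default) uses integer masses with 1 u per 13C, the
        right axis for a unit-resolution quadrupole; ``"exact"`` uses the
        monoisotopic anion m/z and the exact 13C-12C mass difference
        (1.0033548 u); a float gives a custom spacing on the exact base.
    """
    anion = carboxylate_anion_formula(fa)
    if spacing == "nominal":
        base, step = float(anion.nominal_mass()), 1.0
    elif spacing == "exact":
        base, step = anion.monoisotopic_mz(), C13_SPACING
    else:
        step = float(spacing)
        if step <= 0:
            raise ValueError(f"spacing must be positive, got {spacing}")
        base = anion.monoisotopic_mz()
    return [(k, base + k * step) for k in range(fa.n_carbons + 1)]


# Canonical names covering the common C4-C24 analytical standards (the usual
# 52-component free-fatty-acid mixes); the bundled reference CSV is generated
# from this list by ``reference_table``.
CANONICAL_NAMES: tuple[str, ...] = (
    "C4:0", "C5:0", "C6:0", "C7:0", "C8:0", "C9:0", "C10:0", "C11:0", "C12:0",
    "C13:0", "C14:0", "C14:1c", "C15:0", "C15:1c", "C16:0", "C16:1c", "C17:0",
    "C17:1c", "C18:0", "C18:1c", "C18:1t", "C18:2c", "C18:2t", "C18:3n3",
    "C18:3n6", "C19:0", "C20:0", "C20:1c", "C20:2c", "C20:3n3", "C20:3n6",
    "C20:4n6", "C20:5n3", "C21:0", "C22:0", "C22:1c", "C22:2c", "C22:4n6",
    "C22:5n3", "C22:6n3", "C23:0", "C24:0", "C24:1c",
)


def _reference_rows() -> Iterator[dict]:
    for name in CANONICAL_NAMES:
        fa = parse_fatty_acid_name(name)
        anion = carboxylate_anion_formula(fa)
        yield {
            "name": fa.display_name,
            "n_carbons": fa.n_carbons,
            "n_double_bonds": fa.n_double_bonds,
            "free_acid_formula": str(free_acid_formula(fa)),
            "anion_formula": str(anion),
            "anion_nominal_mz": anion.nominal_mass(),
            "anion_monoisotopic_mz": round(anion.monoisotopic_mz(), 5),
        }


def reference_table():
    """Reference table of canonical C4-C24 fatty acids as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(list(_reference_rows()))


def write_reference_table(path: str | Path) -> None:
    reference_table().to_csv(path, index=False)
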