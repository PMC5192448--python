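"""Natural isotope abundance tables for the elements of a fatty acid.

Each element maps to an ordered abundance vector over mass offsets
(+0, +1, +2 u).  Carbon uses [0.9893, 0.0107] (12C/13C); hydrogen and
oxygen use the standard IUPAC terrestrial abundances.  Tables are editable
via YAML so tracer purity or non-standard abundances can be configured.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["IsotopeTable", "DEFAULT_ABUNDANCES"]

DEFAULT_ABUNDANCES: dict[str, list[float]] = {
    # offset:      +0        +1        +2
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "O": [0.99757, 0.00038, 0.00205],
}


class IsotopeTable:
    """Per-element isotopic abundance vectors over integer mass offsets."""

    def __init__(self, abundances: dict[str, list[float]] | None = None):
        data = abundances if abundances is not None else DEFAULT_ABUNDANCES
        self._table: dict[str, np.ndarray] = {}
        for elem, vec in data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"abundance vector for {elem} must be 1-D, non-empty")
            if np.any(arr < 0):
                raise ValueError(f"negative abundance for element {elem}")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {elem} sum to {arr.sum():.12f}, expected 1"
                )
            self._table[elem] = arr

    def __getitem__(self, element: str) -> np.ndarray:
        try:
            return self._table[element]
        except KeyError:
            raise KeyError(
                f"no isotope abundances configured for element {element!r}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self._table

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._table)

    @classmethod
    def natural(cls) -> "IsotopeTable":
        return cls(DEFAULT_ABUNDANCES)

    @classmethod
    def monoisotopic(cls, elements: tuple[str, ...] = ("C", "H", "O")) -> "IsotopeTable":
        """Toy table with no heavy isotopes — correction matrix is identity."""
        return cls({e: [1.0] for e in elements})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IsotopeTable":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({str(k): list(map(float, v)) for k, v in data.items()})

    def to_dict(self) -> dict[str, list[float]]:
        return {e: v.tolist() for e, v in self._table.items()}
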