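"""Pool-size quantification and extraction-recovery tables.

Pool sizes come from the summed area of every isotopologue channel — the
total is invariant under labelling, so enrichment never changes the apparent
concentration — expressed as a response ratio against the deuterated
internal standard (myristic-d27, 50 uM by default; its [M-H]- anion at
nominal m/z 254 is read from its own channel and never enters the 13C MDV
arithmetic).  Concentration follows from a per-fatty-acid linear calibration
with declared linear-range bounds; ratio measurements outside the linear
response range carry large errors, so out-of-range samples are flagged,
never silently reported.

Recovery tables compare total fatty-acid concentrations across extraction
protocols as percentages relative to a reference method (classically the
chloroform-based extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import IsotopologueSeries

__all__ = [
    "ISTD_NAME",
    "ISTD_CONC_UM",
    "ISTD_ANION_NOMINAL_MZ",
    "LinearCalibration",
    "CalibrationModel",
    "PoolSize",
    "pool_size",
    "recovery_percentages",
    "round_half_up",
]

ISTD_NAME = "myristic-d27"
ISTD_CONC_UM = 50.0
#: d27-myristate [M-H]-: C14H0D27O2 minus one D -> nominal 227 + 27 = 254.
ISTD_ANION_NOMINAL_MZ = 254


@dataclass
class LinearCalibration:
    slope: float
    intercept: float
    linear_range: tuple[float, float]  # concentration bounds

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def concentration(self, response: float) -> float:
        return (response - self.intercept) / self.slope

    def in_range(self, concentration: float) -> bool:
        lo, hi = self.linear_range
        return lo <= concentration <= hi


@dataclass
class CalibrationModel:
    """Per-fatty-acid linear response calibrations (area ratio vs conc)."""

    curves: dict[str, LinearCalibration] = field(default_factory=dict)

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "CalibrationModel":
        """Fit from a long table with columns fatty_acid, concentration, response."""
        required = {"fatty_acid", "concentration", "response"}
        if not required.issubset(table.columns):
            raise ValueError(f"calibration table needs columns {sorted(required)}")
        curves = {}
        for name, grp in table.groupby("fatty_acid"):
            if len(grp) < 2:
                raise ValueError(f"need >= 2 calibration levels for {name}")
            conc = grp["concentration"].to_numpy(float)
            resp = grp["response"].to_numpy(float)
            slope, intercept = np.polyfit(conc, resp, 1)
            curves[str(name)] = LinearCalibration(
                slope=float(slope),
                intercept=float(intercept),
                linear_range=(float(conc.min()), float(conc.max())),
            )
        return cls(curves)

    def __getitem__(self, fatty_acid: str) -> LinearCalibration:
        try:
            return self.curves[fatty_acid]
        except KeyError:
            raise KeyError(
                f"no calibration available for fatty acid {fatty_acid!r}"
            ) from None


@dataclass
class PoolSize:
    fatty_acid: str
    concentration: float
    response: float
    out_of_range: bool


def pool_size(
    series: IsotopologueSeries,
    istd_area: float,
    cal: CalibrationModel,
    istd_conc: float = ISTD_CONC_UM,
) -> PoolSize:
    """Total pool concentration from the isotopologue-summed area.

    ``istd_conc`` is carried for provenance; the calibration curve is
    assumed acquired at the same internal-standard level.
    """
    if istd_area <= 0:
        raise ValueError("internal standard area must be positive")
    name = series.fatty_acid.display_name
    curve = cal[name]
    response = series.total_area() / istd_area
    conc = curve.concentration(response)
    return PoolSize(
        fatty_acid=name,
        concentration=conc,
        response=response,
        out_of_range=not curve.in_range(conc),
    )


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with halves away from zero (0.5 -> 1)."""
    x = np.asarray(x, dtype=float)
    return np.floor(x + 0.5)


def recovery_percentages(
    concentrations: pd.DataFrame,
    reference: str,
    rounding: str = "half_up",
) -> pd.DataFrame:
    """Derive "% rel to <reference>" rows from a methods x fatty-acids table.

    Parameters
    ----------
    concentrations
        Index = extraction method names, columns = fatty acids, values =
        concentrations (ug/mL).
    reference
        Method the percentages are taken relative to; its own row maps to
        100 everywhere.
    rounding
        ``"half_up"`` (integers, the presentation convention) or ``"none"``
        to keep the raw ratios.

    Returns
    -------
    DataFrame with one ``<method> % rel to <reference>`` row per
    non-reference method.
    """
    if reference not in concentrations.index:
        raise ValueError(f"reference method {reference!r} not in table")
    ref = concentrations.loc[reference]
    zero_cells = ref[ref <= 0]
    if len(zero_cells):
        raise ZeroDivisionError(
            f"reference {reference!r} has non-positive entries for "
            f"{list(zero_cells.index)}"
        )
    rows = {}
    for method in concentrations.index:
        if method == reference:
            continue
        pct = 100.0 * concentrations.loc[method] / ref
        if rounding == "half_up":
            pct = pd.Series(round_half_up(pct), index=pct.index).astype(int)
        elif rounding != "none":
            raise ValueError(f"unknown rounding convention {rounding!r}")
        rows[f"{method} % rel to {reference}"] = pct
    return pd.DataFrame(rows).T
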