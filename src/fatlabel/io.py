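"""Table schemas, run configuration and manifests.

The peak-table dialect is the contract between peak extraction and the
correction stage: CSV with header
``sample,lipid_class,fatty_acid,isotopologue,mz,area,apex_rt_min``, one row
per isotopologue, UTF-8, '.' decimal separator.  ``isotopologue`` is the
integer label count of M+i; ``lipid_class`` is one of NL, GL, PL or total
(solid-phase-extraction fractions are wet-lab provenance and carried as
labels only).  Validation is total: every malformed input is rejected with
a row/column diagnostic, and each (sample, lipid class, fatty acid) group
must contain the complete M+0..M+nC series — the correction requires the
vector to span every carbon of the parent species.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fatty_acids import FattyAcid, parse_fatty_acid_name
from .isotopes import IsotopeTable
from .peaks import IsotopologueSeries

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "LIPID_CLASSES",
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "series_to_rows",
    "write_manifest",
]

PEAK_TABLE_COLUMNS = (
    "sample",
    "lipid_class",
    "fatty_acid",
    "isotopologue",
    "mz",
    "area",
    "apex_rt_min",
)
LIPID_CLASSES = ("NL", "GL", "PL", "total")


class PeakTableError(ValueError):
    """Schema violation in a peak table, with row/column context."""


@dataclass
class RunConfig:
    """Serialisable run configuration, echoed verbatim into manifests."""

    isotope_table: dict[str, list[float]] | None = None  # None -> natural
    mz_tol: float = 0.5
    divisor: str = "n_carbons"  # "n_carbons" | "n_isotopologues"
    solver: str = "triangular"  # "triangular" | "nnls"
    carbon_natural: bool = True
    rounding: str = "half_up"
    baseline_window_s: float = 60.0
    blank_flag_frac: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def make_isotope_table(self) -> IsotopeTable:
        if self.isotope_table is None:
            return IsotopeTable.natural()
        return IsotopeTable(self.isotope_table)

    def to_dict(self) -> dict:
        return asdict(self)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read and fully validate a peak table.

    Raises
    ------
    PeakTableError
        On missing columns, unknown lipid classes, negative areas,
        non-integer isotopologue indices, or gaps in the M+0..M+nC series
        of any group (the message names the absent M+i indices).
    """
    df = pd.read_csv(path)
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise PeakTableError(f"peak table {path} missing columns {sorted(missing)}")
    bad_class = df.loc[~df["lipid_class"].isin(LIPID_CLASSES)]
    if len(bad_class):
        raise PeakTableError(
            f"row {bad_class.index[0] + 2}: unknown lipid_class "
            f"{bad_class['lipid_class'].iloc[0]!r} (expected one of {LIPID_CLASSES})"
        )
    iso = pd.to_numeric(df["isotopologue"], errors="coerce")
    if iso.isna().any() or not np.allclose(iso, iso.round()):
        row = int(iso.index[iso.isna() | (iso != iso.round())][0])
        raise PeakTableError(f"row {row + 2}: isotopologue must be an integer")
    df["isotopologue"] = iso.astype(int)
    area = pd.to_numeric(df["area"], errors="coerce")
    if area.isna().any() or (area < 0).any():
        row = int(area.index[area.isna() | (area < 0)][0])
        raise PeakTableError(f"row {row + 2}: area must be a non-negative number")
    df["area"] = area

    for (sample, lclass, fa_name), grp in df.groupby(
        ["sample", "lipid_class", "fatty_acid"]
    ):
        fa = parse_fatty_acid_name(str(fa_name))
        expected = set(range(fa.n_carbons + 1))
        present = set(grp["isotopologue"])
        gaps = sorted(expected - present)
        if gaps:
            listing = ", ".join(f"M+{i}" for i in gaps)
            raise PeakTableError(
                f"{sample}/{lclass}/{fa_name}: missing isotopologue rows {listing} "
                f"(the full M+0..M+{fa.n_carbons} series is required)"
            )
        extra = sorted(present - expected)
        if extra:
            raise PeakTableError(
                f"{sample}/{lclass}/{fa_name}: isotopologue indices {extra} "
                f"exceed the carbon count {fa.n_carbons}"
            )
    return df


def series_to_rows(series: IsotopologueSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": series.sample,
            "lipid_class": series.lipid_class,
            "fatty_acid": series.fatty_acid.display_name,
            "isotopologue": series.label_counts,
            "mz": series.mz,
            "area": series.areas,
            "apex_rt_min": series.apex_rt_min,
        }
    )


def write_peak_table(
    series_list: list[IsotopologueSeries], path: str | Path
) -> None:
    pd.concat([series_to_rows(s) for s in series_list], ignore_index=True).to_csv(
        path, index=False, columns=list(PEAK_TABLE_COLUMNS)
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    config: RunConfig,
    inputs: list[str | Path],
    extra: dict | None = None,
) -> Path:
    """Write a run manifest: config echo, input hashes, package version."""
    from . import __version__

    manifest = {
        "package": "fatlabel",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
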