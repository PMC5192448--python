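"""Chromatographic peak extraction for isotopologue series.

Heavy isotopologues elute slightly earlier than light ones (weaker London
dispersion from the smaller molecular volume), so isotopologue abundances
must be read as whole-peak areas, not apex intensities: an apex-height read
is biased by the retention-time shift, while the area integrates it out.
All channels of one fatty acid are therefore integrated over a single shared
window spanning the union of the per-channel peak extents.

Peak detection is deliberately simple and fully configurable: a moving-median
baseline, apex by maximum with parabolic sub-sample refinement, and bounds at
a small fraction of apex height or at a valley.  Instrument vendors do not
publish their integrators; these defaults are declared, conservative, and
pure functions of the input, so QC output is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .fatty_acids import FattyAcid, isotopologue_mz_series

__all__ = [
    "Chromatogram",
    "IsotopologueSeries",
    "IntegrationConfig",
    "QCReport",
    "RTShiftEstimate",
    "extract_xic",
    "integrate_isotopologue_peaks",
    "check_coelution",
    "subtract_blank",
    "rt_shift_estimate",
]


@dataclass
class Chromatogram:
    """Per-m/z intensity traces on a shared time axis (minutes)."""

    time_min: np.ndarray
    channels: dict[float, np.ndarray]
    mode: str = "scan"  # "scan" | "SIM"
    scan_rate: float = 2.0  # scans per second
    scan_range: tuple[float, float] = (100.0, 400.0)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time axis must be strictly increasing")
        for mz, trace in self.channels.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != self.time_min.shape:
                raise ValueError(f"channel {mz} length mismatch with time axis")
            if np.any(trace < 0):
                raise ValueError(f"negative intensities in channel {mz}")
            self.channels[mz] = trace

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "Chromatogram":
        """Read the portable long dialect: columns time_min, mz, intensity."""
        df = pd.read_csv(path)
        required = {"time_min", "mz", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"chromatogram CSV {path} must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        wide = df.pivot_table(
            index="time_min", columns="mz", values="intensity", aggfunc="sum"
        ).fillna(0.0)
        channels = {float(mz): wide[mz].to_numpy() for mz in wide.columns}
        return cls(time_min=wide.index.to_numpy(), channels=channels, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for mz in sorted(self.channels):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_min,
                        "mz": mz,
                        "intensity": self.channels[mz],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass
class IsotopologueSeries:
    """Integrated peak areas for every isotopologue channel of one fatty acid."""

    fatty_acid: FattyAcid
    label_counts: np.ndarray
    mz: np.ndarray
    areas: np.ndarray
    apex_rt_min: np.ndarray  # NaN where no peak was detected
    window_min: tuple[float, float] = (0.0, 0.0)
    lipid_class: str = "total"
    sample: str = ""

    def __post_init__(self) -> None:
        self.label_counts = np.asarray(self.label_counts, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.apex_rt_min = np.asarray(self.apex_rt_min, dtype=float)
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    @property
    def mdv(self) -> np.ndarray:
        return self.areas.copy()

    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class IntegrationConfig:
    mz_tol: float = 0.5  # u, matches unit resolution
    baseline_window_s: float = 60.0
    bound_frac: float = 0.001  # peak bounds at this fraction of apex
    min_points_per_peak: int = 10
    truncation_frac: float = 0.01  # edge intensity above this x apex -> truncated
    apex_min_frac: float = 1e-3  # channel counts as detected above this x max apex
    coelution_secondary_frac: float = 0.10
    coelution_min_shape_corr: float = 0.90
    blank_flag_frac: float = 0.10


@dataclass
class RTShiftEstimate:
    slope_s_per_label: float  # negative when heavy isotopologues elute earlier
    total_shift_s: float  # positive = heavy earlier; |slope| x n_carbons
    n_channels: int


@dataclass
class QCReport:
    fatty_acid: str
    coelution_flags: dict[int, str] = field(default_factory=dict)
    truncated_channels: list[int] = field(default_factory=list)
    undersampled_channels: list[int] = field(default_factory=list)
    contamination_fraction: float | None = None
    contamination_flagged: bool = False
    rt_shift: RTShiftEstimate | None = None

    def to_dict(self) -> dict:
        d = {
            "fatty_acid": self.fatty_acid,
            "coelution_flags": {str(k): v for k, v in self.coelution_flags.items()},
            "truncated_channels": list(self.truncated_channels),
            "undersampled_channels": list(self.undersampled_channels),
            "contamination_fraction": self.contamination_fraction,
            "contamination_flagged": self.contamination_flagged,
        }
        if self.rt_shift is not None:
            d["rt_shift"] = {
                "slope_s_per_label": self.rt_shift.slope_s_per_label,
                "total_shift_s": self.rt_shift.total_shift_s,
                "n_channels": self.rt_shift.n_channels,
            }
        return d


def extract_xic(chrom: Chromatogram, mz: float, tol: float = 0.5) -> np.ndarray:
    """Summed intensity of all channels within mz +/- tol."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    selected = [t for cmz, t in chrom.channels.items() if abs(cmz - mz) <= tol]
    if not selected:
        warnings.warn(
            f"no channel within {mz} +/- {tol} u; returning a zero trace",
            stacklevel=2,
        )
        return np.zeros_like(chrom.time_min)
    return np.sum(selected, axis=0)


def _baseline_subtract(trace: np.ndarray, chrom: Chromatogram, cfg: IntegrationConfig):
    window = max(3, int(round(cfg.baseline_window_s * chrom.scan_rate)) | 1)
    baseline = median_filter(trace, size=window, mode="nearest")
    return np.clip(trace - baseline, 0.0, None)


def _peak_bounds(signal: np.ndarray, apex: int, lo: int, hi: int, frac: float):
    """Walk outward from the apex to the bound fraction or the first valley."""
    threshold = frac * signal[apex]
    left = apex
    while left > lo:
        nxt = left - 1
        if signal[nxt] <= threshold or signal[nxt] > signal[left]:
            break
        left = nxt
    right = apex
    while right < hi:
        nxt = right + 1
        if signal[nxt] <= threshold or signal[nxt] > signal[right]:
            break
        right = nxt
    return left, right


def _refine_apex(time: np.ndarray, signal: np.ndarray, idx: int) -> float:
    """Parabolic sub-sample apex interpolation through three points."""
    if idx <= 0 or idx >= signal.size - 1:
        return float(time[idx])
    y0, y1, y2 = signal[idx - 1], signal[idx], signal[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a proper maximum
        return float(time[idx])
    delta = 0.5 * (y0 - y2) / denom
    dt = time[idx + 1] - time[idx] if delta > 0 else time[idx] - time[idx - 1]
    return float(time[idx] + delta * dt)


def integrate_isotopologue_peaks(
    chrom: Chromatogram,
    fa: FattyAcid,
    rt_window: tuple[float, float],
    config: IntegrationConfig | None = None,
    lipid_class: str = "total",
    sample: str = "",
) -> tuple[IsotopologueSeries, QCReport]:
    """Integrate every isotopologue channel of a fatty acid.

    The window should be padded beyond the light-isotopologue peak by at
    least the maximum expected retention-time shift, so the earliest-eluting
    heavy species is fully contained.  Areas are trapezoidal over a shared
    window (the union of the per-channel peak extents); apex retention
    times are recorded per channel.  Truncation and sampling-density
    problems are flagged in the accompanying QC report.
    """
    cfg = config or IntegrationConfig()
    series_mz = isotopologue_mz_series(fa, spacing="nominal")
    t = chrom.time_min
    lo_idx = int(np.searchsorted(t, rt_window[0], side="left"))
    hi_idx = int(np.searchsorted(t, rt_window[1], side="right")) - 1
    if hi_idx <= lo_idx:
        raise ValueError(f"rt_window {rt_window} contains no data points")

    signals, apex_idx, apex_vals = [], [], []
    for _, mz in series_mz:
        trace = extract_xic(chrom, mz, cfg.mz_tol)
        sig = _baseline_subtract(trace, chrom, cfg)
        signals.append(sig)
        rel = int(np.argmax(sig[lo_idx : hi_idx + 1]))
        apex_idx.append(lo_idx + rel)
        apex_vals.append(float(sig[lo_idx + rel]))

    max_apex = max(apex_vals) if apex_vals else 0.0
    detected = [v > cfg.apex_min_frac * max_apex and v > 0 for v in apex_vals]

    # Shared integration window: union of the detected channels' extents.
    share_lo, share_hi = hi_idx, lo_idx
    per_bounds: list[tuple[int, int] | None] = []
    for sig, idx, ok in zip(signals, apex_idx, detected):
        if not ok:
            per_bounds.append(None)
            continue
        b = _peak_bounds(sig, idx, lo_idx, hi_idx, cfg.bound_frac)
        per_bounds.append(b)
        share_lo, share_hi = min(share_lo, b[0]), max(share_hi, b[1])
    if share_hi <= share_lo:  # nothing detected anywhere
        share_lo, share_hi = lo_idx, hi_idx

    qc = QCReport(fatty_acid=fa.display_name)
    areas = np.zeros(len(series_mz))
    apex_rt = np.full(len(series_mz), np.nan)
    for k, (sig, idx, ok, b) in enumerate(
        zip(signals, apex_idx, detected, per_bounds)
    ):
        areas[k] = float(
            np.trapezoid(sig[share_lo : share_hi + 1], t[share_lo : share_hi + 1])
        )
        if not ok:
            continue
        apex_rt[k] = _refine_apex(t, sig, idx)
        edge = max(sig[share_lo], sig[share_hi])
        if edge > cfg.truncation_frac * sig[idx]:
            qc.truncated_channels.append(k)
        if b is not None and (b[1] - b[0] + 1) < cfg.min_points_per_peak:
            qc.undersampled_channels.append(k)

    series = IsotopologueSeries(
        fatty_acid=fa,
        label_counts=np.array([k for k, _ in series_mz]),
        mz=np.array([mz for _, mz in series_mz]),
        areas=areas,
        apex_rt_min=apex_rt,
        window_min=(float(t[share_lo]), float(t[share_hi])),
        lipid_class=lipid_class,
        sample=sample,
    )
    if np.isfinite(apex_rt).sum() >= 2:
        qc.rt_shift = rt_shift_estimate(series)
    return series, qc


def check_coelution(
    chrom: Chromatogram,
    series: IsotopologueSeries,
    config: IntegrationConfig | None = None,
) -> dict[int, str]:
    """Flag isotopologue channels with evidence of a co-eluting interferent.

    A channel is flagged when a secondary local maximum above a fraction
    (default 10%) of its apex lies inside the integration window, or when
    its peak shape correlates poorly (default r < 0.9) with the apex-aligned
    consensus shape of all detected channels.
    """
    cfg = config or IntegrationConfig()
    t = chrom.time_min
    lo = int(np.searchsorted(t, series.window_min[0], side="left"))
    hi = int(np.searchsorted(t, series.window_min[1], side="right")) - 1
    sigs, apexes = {}, {}
    for k, mz, rt in zip(series.label_counts, series.mz, series.apex_rt_min):
        if not np.isfinite(rt):
            continue
        sig = _baseline_subtract(extract_xic(chrom, mz, cfg.mz_tol), chrom, cfg)
        sigs[int(k)] = sig[lo : hi + 1]
        apexes[int(k)] = int(np.argmax(sig[lo : hi + 1]))

    flags: dict[int, str] = {}
    # Secondary-maximum test.
    for k, sig in sigs.items():
        apex_val = sig[apexes[k]]
        peaks, _ = find_peaks(sig, height=cfg.coelution_secondary_frac * apex_val)
        extra = [p for p in peaks if abs(p - apexes[k]) > 2]
        if extra:
            flags[k] = "secondary maximum in integration window"

    # Shape-correlation test against the area-weighted, apex-aligned consensus.
    if len(sigs) >= 3:
        width = hi - lo + 1
        aligned = {}
        for k, sig in sigs.items():
            shift = apexes[k] - width // 2
            rolled = np.roll(sig, -shift)
            peak = rolled.max()
            if peak > 0:
                aligned[k] = rolled / peak
        if len(aligned) >= 3:
            consensus = np.mean(
                [v * series.areas[k] for k, v in aligned.items()], axis=0
            )
            for k, shape in aligned.items():
                if np.std(shape) == 0 or np.std(consensus) == 0:
                    continue
                r = float(np.corrcoef(shape, consensus)[0, 1])
                if r < cfg.coelution_min_shape_corr and k not in flags:
                    flags[k] = f"peak shape correlation {r:.3f} below threshold"
    return flags


def subtract_blank(
    series: IsotopologueSeries,
    blank: IsotopologueSeries,
    flag_threshold: float = 0.10,
) -> tuple[IsotopologueSeries, dict]:
    """Subtract blank-run areas channel by channel, floored at zero.

    Ubiquitous fatty-acid contamination (16:0 and 18:0 especially) inflates
    the unlabelled channel and biases labelling low, so the M+0
    contamination fraction is reported and flagged above ``flag_threshold``.
    """
    if series.fatty_acid != blank.fatty_acid or not np.array_equal(
        series.label_counts, blank.label_counts
    ):
        raise ValueError(
            "blank series does not match sample series "
            f"({blank.fatty_acid} vs {series.fatty_acid})"
        )
    corrected = np.clip(series.areas - blank.areas, 0.0, None)
    m0 = series.areas[0]
    contamination = float(blank.areas[0] / m0) if m0 > 0 else float("inf")
    report = {
        "contamination_fraction": contamination,
        "flagged": contamination > flag_threshold,
    }
    out = IsotopologueSeries(
        fatty_acid=series.fatty_acid,
        label_counts=series.label_counts,
        mz=series.mz,
        areas=corrected,
        apex_rt_min=series.apex_rt_min,
        window_min=series.window_min,
        lipid_class=series.lipid_class,
        sample=series.sample,
    )
    return out, report


def rt_shift_estimate(series: IsotopologueSeries) -> RTShiftEstimate:
    """Least-squares slope of apex RT versus label count.

    Channels are weighted by their peak area so near-empty channels, whose
    apexes are noise, do not drive the fit.  The slope is negative when
    heavy isotopologues elute earlier; ``total_shift_s`` is the apex
    separation between M+0 and M+nC implied by the fit, positive for
    early-eluting heavy species (about 4.2 s for 18-carbon acids on a
    100 m FAME-phase column).
    """
    mask = np.isfinite(series.apex_rt_min) & (series.areas > 0)
    if mask.sum() < 2:
        warnings.warn("fewer than 2 apexes; RT shift undefined", stacklevel=2)
        return RTShiftEstimate(float("nan"), float("nan"), int(mask.sum()))
    x = series.label_counts[mask].astype(float)
    y = series.apex_rt_min[mask]
    w = np.sqrt(series.areas[mask])
    slope_min, _ = np.polyfit(x, y, 1, w=w)
    slope_s = float(slope_min * 60.0)
    n_c = int(series.label_counts.max())
    return RTShiftEstimate(
        slope_s_per_label=slope_s,
        total_shift_s=-slope_s * n_c,
        n_channels=int(mask.sum()),
    )
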