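"""Forward simulator of 13C-enriched NCI GC-MS fatty-acid data.

Generates measured-space mass distribution vectors and full chromatograms
with known ground truth, so the correction, integration and quantification
stages are testable without instrument data, and so correction accuracy can
be validated by round trip (simulate forward, correct back, compare to the
tracer distribution).

The ground-truth enrichment model is a two-pool mixture: an unlabelled pool
plus a labelled pool in which each acyl carbon is 13C with probability p.
With p near one this reproduces the bimodal unlabelled/fully-labelled
spectra characteristic of partly turned-over lipid pools growing on a 13C
carbon source, and supports reading the partially- versus fully-labelled
isotopologue ratio as de novo synthesis versus elongation.  A single-pool
binomial mode is included for simpler tests.

Chromatographic peaks are Gaussian with a constant width across
isotopologues; each heavy label shifts the apex earlier by a fixed number
of seconds (about 4.2 s across the 18 labels of an 18-carbon acid), which
makes the within-peak spectral skew — heavy-rich spectra on the leading
edge, light-rich on the tailing edge — emerge automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .correction import build_correction_matrix, natural_spectrum
from .fatty_acids import (
    FattyAcid,
    carboxylate_anion_formula,
    isotopologue_mz_series,
    parse_fatty_acid_name,
)
from .isotopes import IsotopeTable
from .peaks import Chromatogram

__all__ = [
    "EnrichmentModel",
    "FattyAcidSpec",
    "Interferent",
    "SimScenario",
    "simulate_mdv",
    "noisy_measured_mdvs",
    "simulate_chromatogram",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class EnrichmentModel:
    """Ground-truth 13C enrichment of one fatty-acid pool.

    kind="two_pool": tracer distribution (1-f) * delta(M+0) + f * Binom(nC, p*purity).
    kind="binomial": single pool, Binom(nC, p*purity); f is ignored.
    """

    kind: str = "two_pool"
    labeled_fraction: float = 0.0  # f
    p_per_carbon: float = 1.0  # p within the labelled pool
    purity: float = 1.0  # tracer isotopic purity

    def __post_init__(self) -> None:
        for name in ("labeled_fraction", "p_per_carbon", "purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kind not in ("two_pool", "binomial"):
            raise ValueError(f"unknown enrichment kind {self.kind!r}")

    @property
    def expected_labeling(self) -> float:
        """Mean fraction of carbons labelled: f*p*purity (or p*purity)."""
        p_eff = self.p_per_carbon * self.purity
        return p_eff if self.kind == "binomial" else self.labeled_fraction * p_eff

    def tracer_distribution(self, n_carbons: int) -> np.ndarray:
        p_eff = self.p_per_carbon * self.purity
        pmf = binom.pmf(np.arange(n_carbons + 1), n_carbons, p_eff)
        if self.kind == "binomial":
            return pmf
        out = self.labeled_fraction * pmf
        out[0] += 1.0 - self.labeled_fraction
        return out


def simulate_mdv(
    fa: FattyAcid, em: EnrichmentModel, table: IsotopeTable | None = None
) -> np.ndarray:
    """Exact measured-space MDV: correction matrix applied to the tracer
    distribution of the carboxylate anion.  No noise."""
    table = table or IsotopeTable.natural()
    cm = build_correction_matrix(carboxylate_anion_formula(fa), table)
    return cm.forward(em.tracer_distribution(fa.n_carbons))


def noisy_measured_mdvs(
    fa: FattyAcid,
    em: EnrichmentModel,
    n_replicates: int,
    noise_cv: float,
    rng: np.random.Generator,
    table: IsotopeTable | None = None,
) -> np.ndarray:
    """Replicate measured MDVs with multiplicative per-channel noise.

    Each channel is scaled by (1 + cv * N(0,1)), clipped at zero — the
    simple proportional-error model appropriate for well-above-noise-floor
    peak areas.  Returns an (n_replicates, nC+1) array.
    """
    clean = simulate_mdv(fa, em, table)
    factors = 1.0 + noise_cv * rng.standard_normal((n_replicates, clean.size))
    return np.clip(clean * factors, 0.0, None)


@dataclass(frozen=True)
class FattyAcidSpec:
    fatty_acid: FattyAcid
    enrichment: EnrichmentModel
    abundance: float  # total injected ion count (intensity x min units)
    apex_rt_min: float  # apex of the unlabelled isotopologue


@dataclass(frozen=True)
class Interferent:
    """A co-eluting foreign compound on a single m/z channel."""

    mz: float
    apex_rt_min: float
    sigma_s: float
    area: float


@dataclass
class SimScenario:
    fatty_acids: list[FattyAcidSpec]
    rt_shift_s_per_label: float = 4.2 / 18.0
    sigma_s: float = 2.5
    noise_cv: float = 0.0
    baseline_level: float = 0.0
    baseline_noise_sd: float = 0.0
    contamination_m0_fraction: float = 0.0  # unlabelled blank-style background
    scan_rate: float = 2.0  # scans per second
    time_start_min: float = 28.0
    time_end_min: float = 32.0
    mode: str = "scan"
    seed: int = 0
    interferents: list[Interferent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "sigma_s",
            "noise_cv",
            "baseline_level",
            "baseline_noise_sd",
            "contamination_m0_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        margin = 5 * self.sigma_s / 60.0
        for spec in self.fatty_acids:
            heavy_apex = (
                spec.apex_rt_min
                - spec.fatty_acid.n_carbons * self.rt_shift_s_per_label / 60.0
            )
            if heavy_apex - margin < self.time_start_min or (
                spec.apex_rt_min + margin > self.time_end_min
            ):
                raise ValueError(
                    f"peaks of {spec.fatty_acid} extend beyond the time axis; "
                    "widen the acquisition window"
                )


def simulate_chromatogram(
    scenario: SimScenario, table: IsotopeTable | None = None
) -> Chromatogram:
    """Render a scenario to per-channel Gaussian peaks plus noise."""
    table = table or IsotopeTable.natural()
    rng = np.random.default_rng(scenario.seed)
    dt_min = 1.0 / (scenario.scan_rate * 60.0)
    t = np.arange(scenario.time_start_min, scenario.time_end_min, dt_min)
    sigma_min = scenario.sigma_s / 60.0
    shift_min = scenario.rt_shift_s_per_label / 60.0

    channels: dict[float, np.ndarray] = {}

    def add_gaussian(mz: float, center: float, sigma: float, area: float) -> None:
        trace = channels.setdefault(float(mz), np.zeros_like(t))
        trace += (
            area / (sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        )

    for spec in scenario.fatty_acids:
        fa = spec.fatty_acid
        mdv = simulate_mdv(fa, spec.enrichment, table)
        if scenario.contamination_m0_fraction > 0:
            blank = natural_spectrum(
                carboxylate_anion_formula(fa), table, length=mdv.size
            )
            mdv = mdv + scenario.contamination_m0_fraction * blank
        for k, mz in isotopologue_mz_series(fa, spacing="nominal"):
            area = spec.abundance * mdv[k]
            if area <= 0:
                channels.setdefault(float(mz), np.zeros_like(t))
                continue
            add_gaussian(mz, spec.apex_rt_min - k * shift_min, sigma_min, area)

    for intf in scenario.interferents:
        add_gaussian(intf.mz, intf.apex_rt_min, intf.sigma_s / 60.0, intf.area)

    for mz in sorted(channels):
        trace = channels[mz]
        if scenario.noise_cv > 0:
            trace = trace * (
                1.0 + scenario.noise_cv * rng.standard_normal(trace.size)
            )
        trace = trace + scenario.baseline_level
        if scenario.baseline_noise_sd > 0:
            trace = trace + scenario.baseline_noise_sd * rng.standard_normal(
                trace.size
            )
        channels[mz] = np.clip(trace, 0.0, None)

    return Chromatogram(
        time_min=t,
        channels=channels,
        mode=scenario.mode,
        scan_rate=scenario.scan_rate,
    )


# Fixture-suite ground truth: per-carbon labelling probability in the
# labelled pool is 0.95 (near-complete labelling of de novo acyl carbons
# from a 13C inorganic-carbon source); the labelled-pool fraction is set so
# overall labelling is 0.43 at 48 h and 0.50 at 96 h.
FIXTURE_P = 0.95
FIXTURE_TARGETS = {"t48h": 0.43, "t96h": 0.50}
FIXTURE_FA = "C18:3n3"
FIXTURE_APEX_MIN = 30.0
FIXTURE_ABUNDANCE = 1.0e6


def _fixture_scenario(labeling: float, seed: int, **overrides) -> SimScenario:
    fa = parse_fatty_acid_name(FIXTURE_FA)
    em = EnrichmentModel(
        kind="two_pool",
        labeled_fraction=labeling / FIXTURE_P,
        p_per_carbon=FIXTURE_P,
    )
    spec = FattyAcidSpec(
        fatty_acid=fa,
        enrichment=em,
        abundance=FIXTURE_ABUNDANCE,
        apex_rt_min=FIXTURE_APEX_MIN,
    )
    return SimScenario(fatty_acids=[spec], seed=seed, **overrides)


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write the canonical chromatogram fixtures and their manifest.

    Fixtures: an unlabelled control, 48 h and 96 h two-pool enrichment
    scenarios (ground-truth labelling 0.43 and 0.50 for 18:3), a co-elution
    scenario with an interferent on the M+2 channel, a contamination
    scenario plus its blank run.  The manifest records every ground-truth
    parameter; with a fixed seed the file set is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fatty_acid": FIXTURE_FA, "scenarios": {}}

    def write(name: str, scenario: SimScenario, truth: dict) -> None:
        chrom = simulate_chromatogram(scenario)
        path = outdir / f"{name}.csv"
        chrom.to_csv(path)
        manifest["scenarios"][name] = {
            "file": path.name,
            "rt_shift_s_per_label": scenario.rt_shift_s_per_label,
            "sigma_s": scenario.sigma_s,
            "apex_rt_min": FIXTURE_APEX_MIN,
            "abundance": FIXTURE_ABUNDANCE,
            **truth,
        }

    write(
        "control",
        _fixture_scenario(0.0, seed),
        {"labeled_fraction": 0.0, "p_per_carbon": FIXTURE_P, "labeling": 0.0},
    )
    for offset, (name, target) in enumerate(FIXTURE_TARGETS.items(), start=1):
        write(
            name,
            _fixture_scenario(target, seed + offset),
            {
                "labeled_fraction": target / FIXTURE_P,
                "p_per_carbon": FIXTURE_P,
                "labeling": target,
            },
        )

    coel = _fixture_scenario(0.30, seed + 7)
    mz_m2 = isotopologue_mz_series(parse_fatty_acid_name(FIXTURE_FA))[2][1]
    # Interferent apex height = 50% of the M+2 peak apex.
    mdv = simulate_mdv(
        parse_fatty_acid_name(FIXTURE_FA), coel.fatty_acids[0].enrichment
    )
    interferent_area = 0.5 * FIXTURE_ABUNDANCE * mdv[2]
    coel.interferents.append(
        Interferent(
            mz=mz_m2,
            apex_rt_min=FIXTURE_APEX_MIN + 8.0 / 60.0,
            sigma_s=coel.sigma_s,
            area=interferent_area,
        )
    )
    write(
        "coelution",
        coel,
        {"labeling": 0.30, "interferent_channel": 2, "interferent_area": interferent_area},
    )

    contaminated = _fixture_scenario(
        0.30, seed + 11, contamination_m0_fraction=0.20
    )
    write("contaminated", contaminated, {"labeling": 0.30, "contamination": 0.20})
    blank_spec = FattyAcidSpec(
        fatty_acid=parse_fatty_acid_name(FIXTURE_FA),
        enrichment=EnrichmentModel(kind="two_pool", labeled_fraction=0.0),
        abundance=0.20 * FIXTURE_ABUNDANCE,
        apex_rt_min=FIXTURE_APEX_MIN,
    )
    write(
        "blank",
        SimScenario(fatty_acids=[blank_spec], seed=seed + 13),
        {"labeling": 0.0, "abundance_fraction": 0.20},
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
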