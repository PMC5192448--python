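"""Peak extraction: XIC arithmetic, integration accuracy, RT shift, QC."""

import numpy as np
import pytest
from scipy.stats import norm

from fatlabel import (
    Chromatogram,
    IntegrationConfig,
    check_coelution,
    extract_xic,
    integrate_isotopologue_peaks,
    rt_shift_estimate,
    simulate_chromatogram,
    simulate_mdv,
    subtract_blank,
)
from fatlabel.peaks import IsotopologueSeries
from fatlabel.simulate import Interferent

from conftest import shift_scenario

WINDOW = (29.5, 30.4)


def make_chrom(channels, t=None):
    t = t if t is not None else np.arange(28.0, 32.0, 1 / 120.0)
    return Chromatogram(time_min=t, channels=channels)


class TestExtractXic:
    def test_single_channel_passthrough(self):
        t = np.arange(28.0, 32.0, 1 / 120.0)
        trace = norm.pdf(t, 30.0, 0.04)
        chrom = make_chrom({277.0: trace}, t)
        assert np.array_equal(extract_xic(chrom, 277.0, 0.5), trace)

    def test_tolerance_spanning_two_channels_sums(self):
        t = np.arange(28.0, 32.0, 1 / 120.0)
        a, b = norm.pdf(t, 30.0, 0.04), norm.pdf(t, 30.1, 0.04)
        chrom = make_chrom({277.0: a, 277.6: b}, t)
        assert np.allclose(extract_xic(chrom, 277.3, 0.5), a + b)
        assert np.allclose(extract_xic(chrom, 277.0, 0.1), a)

    def test_empty_selection_warns_and_returns_zeros(self):
        chrom = make_chrom({277.0: np.zeros(480)}, np.arange(480) / 120.0 + 28)
        with pytest.warns(UserWarning, match="no channel"):
            trace = extract_xic(chrom, 350.0, 0.5)
        assert not trace.any()


class TestIntegration:
    def test_gaussian_area_closed_form(self, fa_183):
        """Recovered area of an isolated Gaussian within 0.1% of its integral."""
        t = np.arange(28.0, 32.0, 1 / 120.0)
        area = 5000.0
        channels = {277.0: area * norm.pdf(t, 30.0, 2.5 / 60.0)}
        for _, mz in [(k, 278.0 + k) for k in range(18)]:
            channels[mz] = np.zeros_like(t)
        chrom = make_chrom(channels, t)
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        assert series.areas[0] == pytest.approx(area, rel=1e-3)
        assert np.all(series.areas[1:] == 0)
        assert np.isnan(series.apex_rt_min[1:]).all()

    def test_shifted_series_areas_recovered(self, fa_183):
        """All 19 areas within 0.5% despite the 4.2 s heavy-isotopologue shift."""
        scenario = shift_scenario(fa_183)
        chrom = simulate_chromatogram(scenario)
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        truth = 1.0e6 * simulate_mdv(
            fa_183, scenario.fatty_acids[0].enrichment
        )
        mask = truth > 1e-9 * truth.max()
        assert np.allclose(series.areas[mask], truth[mask], rtol=5e-3)

    def test_area_conservation_independent_of_shift(self, fa_183):
        for shift in (0.0, 4.2 / 18.0):
            chrom = simulate_chromatogram(
                shift_scenario(fa_183, shift_s_per_label=shift)
            )
            series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
            assert series.total_area() == pytest.approx(1.0e6, rel=5e-3)

    def test_window_padding_changes_areas_only_marginally(self, fa_183):
        chrom = simulate_chromatogram(shift_scenario(fa_183))
        narrow, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        wide, _ = integrate_isotopologue_peaks(chrom, fa_183, (29.0, 31.0))
        assert np.allclose(narrow.areas, wide.areas, rtol=1e-3, atol=1e-3)

    def test_truncated_peak_flagged(self, fa_183):
        chrom = simulate_chromatogram(shift_scenario(fa_183))
        _, qc = integrate_isotopologue_peaks(chrom, fa_183, (29.93, 30.01))
        assert qc.truncated_channels

    def test_undersampled_peak_flagged(self, fa_183):
        scenario = shift_scenario(fa_183, shift_s_per_label=0.0)
        scenario.scan_rate = 0.5  # one scan every 2 s across a ~15 s peak
        chrom = simulate_chromatogram(scenario)
        _, qc = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        assert qc.undersampled_channels


class TestRTShift:
    def test_simulated_shift_recovered(self, fa_183):
        chrom = simulate_chromatogram(shift_scenario(fa_183))
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        est = rt_shift_estimate(series)
        assert est.total_shift_s == pytest.approx(4.2, abs=0.2)
        assert est.slope_s_per_label == pytest.approx(-4.2 / 18.0, abs=0.02)

    def test_zero_shift_slope_near_zero(self, fa_183):
        chrom = simulate_chromatogram(shift_scenario(fa_183, shift_s_per_label=0.0))
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        assert abs(rt_shift_estimate(series).total_shift_s) < 0.2

    def test_shift_of_0_07_min_reads_as_4_2_seconds(self, fa_183):
        """A 0.07 min apex separation over 18 labels is a 4.2 s total shift."""
        scenario = shift_scenario(fa_183, shift_s_per_label=0.07 * 60.0 / 18.0)
        chrom = simulate_chromatogram(scenario)
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        assert rt_shift_estimate(series).total_shift_s == pytest.approx(4.2, abs=0.2)

    def test_insufficient_apexes_warns(self, fa_183):
        series = IsotopologueSeries(
            fatty_acid=fa_183,
            label_counts=np.arange(19),
            mz=np.arange(277.0, 296.0),
            areas=np.zeros(19),
            apex_rt_min=np.full(19, np.nan),
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            est = rt_shift_estimate(series)
        assert np.isnan(est.total_shift_s)


class TestCoelution:
    def test_clean_series_unflagged(self, fa_183, fixture_suite):
        outdir, _ = fixture_suite
        chrom = Chromatogram.from_csv(outdir / "t96h.csv")
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, WINDOW)
        assert check_coelution(chrom, series) == {}

    def test_interferent_at_half_apex_flagged(self, fa_183, fixture_suite):
        outdir, _ = fixture_suite
        chrom = Chromatogram.from_csv(outdir / "coelution.csv")
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, (29.5, 30.5))
        flags = check_coelution(chrom, series)
        assert 2 in flags

    def test_interferent_below_threshold_not_flagged(self, fa_183):
        scenario = shift_scenario(fa_183, labeling=0.30)
        mdv = simulate_mdv(fa_183, scenario.fatty_acids[0].enrichment)
        scenario.interferents.append(
            Interferent(
                mz=279.0,
                apex_rt_min=30.0 + 8.0 / 60.0,
                sigma_s=2.5,
                area=0.05 * 1.0e6 * mdv[2],
            )
        )
        chrom = simulate_chromatogram(scenario)
        series, _ = integrate_isotopologue_peaks(chrom, fa_183, (29.5, 30.5))
        assert 2 not in check_coelution(chrom, series)

    def test_qc_is_deterministic(self, fa_183, fixture_suite):
        outdir, _ = fixture_suite
        chrom = Chromatogram.from_csv(outdir / "coelution.csv")
        runs = []
        for _ in range(2):
            series, qc = integrate_isotopologue_peaks(chrom, fa_183, (29.5, 30.5))
            qc.coelution_flags = check_coelution(chrom, series)
            runs.append(qc.to_dict())
        assert runs[0] == runs[1]


class TestBlankSubtraction:
    def _series(self, fa, areas):
        n = fa.n_carbons + 1
        return IsotopologueSeries(
            fatty_acid=fa,
            label_counts=np.arange(n),
            mz=np.arange(277.0, 277.0 + n),
            areas=np.asarray(areas, dtype=float),
            apex_rt_min=np.full(n, 30.0),
        )

    def test_zero_blank_is_identity(self, fa_183):
        sample = self._series(fa_183, np.linspace(10, 1, 19))
        blank = self._series(fa_183, np.zeros(19))
        out, report = subtract_blank(sample, blank)
        assert np.array_equal(out.areas, sample.areas)
        assert report["contamination_fraction"] == 0.0
        assert not report["flagged"]

    def test_blank_equal_to_sample_zeroes_everything(self, fa_183):
        sample = self._series(fa_183, np.linspace(10, 1, 19))
        out, report = subtract_blank(sample, sample)
        assert not out.areas.any()
        assert report["contamination_fraction"] == pytest.approx(1.0)
        assert report["flagged"]

    def test_m0_only_contamination(self, fa_183):
        areas = np.linspace(10, 1, 19)
        blank_areas = np.zeros(19)
        blank_areas[0] = 0.2 * areas[0]
        sample = self._series(fa_183, areas)
        blank = self._series(fa_183, blank_areas)
        out, report = subtract_blank(sample, blank)
        assert out.areas[0] == pytest.approx(0.8 * areas[0])
        assert np.array_equal(out.areas[1:], areas[1:])
        assert report["contamination_fraction"] == pytest.approx(0.2)
        assert report["flagged"]

    def test_mismatched_series_rejected(self, fa_183):
        from fatlabel import parse_fatty_acid_name

        other = parse_fatty_acid_name("C16:0")
        sample = self._series(fa_183, np.ones(19))
        blank = self._series(other, np.ones(17))
        with pytest.raises(ValueError, match="does not match"):
            subtract_blank(sample, blank)


def test_chromatogram_validation():
    t = np.array([1.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="increasing"):
        Chromatogram(time_min=t, channels={277.0: np.zeros(3)})
    with pytest.raises(ValueError, match="negative"):
        Chromatogram(
            time_min=np.array([1.0, 2.0]), channels={277.0: np.array([-1.0, 0.0])}
        )


def test_chromatogram_csv_round_trip(tmp_path, fa_183):
    chrom = simulate_chromatogram(shift_scenario(fa_183))
    path = tmp_path / "chrom.csv"
    chrom.to_csv(path)
    back = Chromatogram.from_csv(path)
    assert np.allclose(back.time_min, chrom.time_min)
    for mz in chrom.channels:
        assert np.allclose(back.channels[mz], chrom.channels[mz])
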