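"""SEC calibration, class integration and fraction pooling."""

import numpy as np
import pytest

from wortpep.hpsec import (CalibrationError, CalibrationStandard, Chromatogram,
                           IntegrationError, fit_calibration,
                           integrate_classes, mw_to_rt, pool_fractions,
                           read_standards, rt_to_mw)
from wortpep.synthetic import simulate_chromatogram


def std(mass, rt, name="s"):
    return CalibrationStandard(name, mass, rt)


class TestCalibration:
    def test_two_point_fit(self):
        curve = fit_calibration([std(10, 10), std(1, 20)])
        assert curve.slope == pytest.approx(-0.1)
        assert curve.intercept == pytest.approx(2.0)
        assert curve.r_squared == 1.0
        assert (curve.rt_min, curve.rt_max) == (10, 20)

    def test_collinear_r2_is_one(self):
        curve = fit_calibration([std(100, 5), std(10, 15), std(1, 25)])
        assert curve.r_squared == pytest.approx(1.0)

    def test_too_few_or_duplicate_standards(self):
        with pytest.raises(CalibrationError):
            fit_calibration([std(10, 10)])
        with pytest.raises(CalibrationError):
            fit_calibration([std(10, 10), std(1, 10)])

    def test_positive_slope_flagged(self):
        with pytest.warns(UserWarning, match="slope"):
            curve = fit_calibration([std(1, 10), std(10, 20)])
        assert curve.suspect

    def test_invalid_standards(self):
        with pytest.raises(ValueError):
            CalibrationStandard("x", -1.0, 10.0)
        with pytest.raises(ValueError):
            CalibrationStandard("x", 10.0, 50.0)  # outside the 45-min run

    def test_packaged_standards_table(self):
        from importlib import resources
        ref = resources.files("wortpep.data").joinpath(
            "standards_synthetic.tsv")
        with resources.as_file(ref) as p:
            standards = read_standards(p)
        assert len(standards) == 5
        curve = fit_calibration(standards)
        assert curve.slope < 0
        assert curve.r_squared > 0.999


class TestConversion:
    def test_known_point(self, sec_curve):
        curve = fit_calibration([std(10, 10), std(1, 20)])
        assert rt_to_mw(curve, 15) == pytest.approx(10 ** 0.5)

    def test_inverse_identity(self, sec_curve):
        rts = np.linspace(1.0, 44.0, 20)
        back = mw_to_rt(sec_curve, rt_to_mw(sec_curve, rts))
        assert np.allclose(back, rts)

    def test_monotone_decreasing(self, sec_curve):
        mw = rt_to_mw(sec_curve, np.array([5.0, 10.0, 20.0, 40.0]))
        assert np.all(np.diff(mw) < 0)

    def test_extrapolation_flag(self, sec_curve):
        _, flag = rt_to_mw(sec_curve, 44.0, with_flag=True)
        assert not flag
        _, flag = rt_to_mw(sec_curve, 46.0, with_flag=True)
        assert flag

    def test_nonfinite_rejected(self, sec_curve):
        with pytest.raises(ValueError):
            rt_to_mw(sec_curve, float("nan"))
        with pytest.raises(ValueError):
            mw_to_rt(sec_curve, -3.0)


class TestIntegration:
    def test_single_peak_single_class(self, sec_curve):
        chrom, _ = simulate_chromatogram([(1.0, 5.0, 0.5)], sec_curve,
                                         noise_sd=0.0,
                                         sampling_interval_min=0.02, seed=0)
        prof = integrate_classes(chrom, sec_curve)
        assert prof.percentages[0] == pytest.approx(100.0, abs=1e-6)
        assert sum(prof.percentages) == pytest.approx(100.0, abs=1e-9)

    def test_three_class_split_recovered_exactly(self, sec_curve):
        chrom, truth = simulate_chromatogram(
            [(1.0, 60.0, 0.5), (5.5, 30.0, 0.5), (25.0, 10.0, 0.5)],
            sec_curve, noise_sd=0.0, sampling_interval_min=0.02, seed=1)
        prof = integrate_classes(chrom, sec_curve)
        assert np.allclose(prof.percentages, truth.true_class_percentages,
                           atol=1e-6)

    def test_flat_signal_errors(self, sec_curve):
        chrom = Chromatogram("UV280", np.linspace(0, 45, 100),
                             np.zeros(100))
        with pytest.raises(IntegrationError, match="no integrable area"):
            integrate_classes(chrom, sec_curve)

    def test_out_of_range_trace_errors(self):
        curve = fit_calibration([std(10, 10), std(1, 20)])
        chrom = Chromatogram("UV280", np.linspace(30, 40, 50),
                             np.ones(50))
        with pytest.raises(IntegrationError, match="outside"):
            integrate_classes(chrom, curve)

    def test_class_labels(self, sec_curve):
        chrom, _ = simulate_chromatogram([(1.0, 5.0, 0.5)], sec_curve,
                                         noise_sd=0.0,
                                         sampling_interval_min=0.05, seed=0)
        prof = integrate_classes(chrom, sec_curve)
        assert prof.class_labels == ("<3 kDa", "3-10 kDa", "10-50 kDa",
                                     ">50 kDa")

    def test_error_shrinks_with_noise(self, sec_curve):
        """Mean class-percentage error decreases towards zero as detector
        noise shrinks."""
        peaks = [(1.0, 60.0, 0.5), (5.5, 30.0, 0.5), (25.0, 10.0, 0.5)]
        errs = []
        for noise in (0.5, 0.05, 0.0):
            per_rep = []
            for rep in range(20):
                chrom, truth = simulate_chromatogram(
                    peaks, sec_curve, noise_sd=noise,
                    sampling_interval_min=0.05, seed=100 + rep)
                prof = integrate_classes(chrom, sec_curve,
                                         clip_negative=False)
                per_rep.append(np.abs(
                    np.array(prof.percentages) -
                    np.array(truth.true_class_percentages)).max())
            errs.append(np.mean(per_rep))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4


class TestPooling:
    def test_minute_fractions_over_45_min(self, sec_curve):
        chrom, _ = simulate_chromatogram([(1.0, 5.0, 0.5)], sec_curve,
                                         noise_sd=0.0,
                                         sampling_interval_min=0.05, seed=0)
        df = pool_fractions(chrom, 1.0)
        assert len(df) == 45
        assert list(df["fraction_index"]) == list(range(1, 46))

    def test_width_five(self, sec_curve):
        chrom, _ = simulate_chromatogram([(1.0, 5.0, 0.5)], sec_curve,
                                         noise_sd=0.0,
                                         sampling_interval_min=0.05, seed=0)
        assert len(pool_fractions(chrom, 5.0)) == 9

    def test_area_conservation(self, sec_curve):
        chrom, _ = simulate_chromatogram(
            [(1.0, 60.0, 0.5), (25.0, 10.0, 0.5)], sec_curve, noise_sd=0.2,
            sampling_interval_min=0.05, seed=5)
        df = pool_fractions(chrom, 1.0)
        total = np.trapezoid(chrom.signal, chrom.times)
        assert df["area"].sum() == pytest.approx(total, rel=1e-12)

    def test_invalid_width(self, sec_curve):
        chrom = Chromatogram("RI", np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            pool_fractions(chrom, 0.0)


def test_plot_profile_writes_figure(tmp_path, sec_curve):
    from wortpep.hpsec import plot_profile
    chrom, _ = simulate_chromatogram([(5.5, 3.0, 0.4)], sec_curve,
                                     noise_sd=0.0,
                                     sampling_interval_min=0.1, seed=0)
    out = tmp_path / "trace.png"
    fig = plot_profile(chrom, sec_curve, path=out)
    assert out.exists() and out.stat().st_size > 0
    import matplotlib.pyplot as plt
    plt.close(fig)


class TestChromatogramIO:
    def test_validation(self):
        with pytest.raises(ValueError):
            Chromatogram("UV280", np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            Chromatogram("UV280", np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Chromatogram("UV280", np.array([0.0, 1.0]), np.array([1.0]))

    def test_tsv_round_trip(self, tmp_path, sec_curve):
        chrom, _ = simulate_chromatogram([(5.5, 3.0, 0.4)], sec_curve,
                                         noise_sd=0.01,
                                         sampling_interval_min=0.1, seed=2)
        path = tmp_path / "trace.tsv"
        chrom.to_tsv(path)
        back = Chromatogram.from_tsv(path)
        assert back.detector == "UV280"
        assert np.allclose(back.times, chrom.times)
        assert np.allclose(back.signal, chrom.signal, atol=1e-7)
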