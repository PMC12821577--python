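"""Spectral preprocessing: FID, baseline, alignment, binning, normalization."""

import numpy as np
import pytest

from urinmr.datatypes import BinnedMatrix, Spectrum
from urinmr.preprocess import (
    ai_binning,
    align_spectra,
    asls_baseline,
    bin_value,
    correct_baseline,
    exclude_regions,
    log_autoscale,
    mean_spectrum,
    normalize_quotient,
    process_fid,
    read_jcamp,
    read_spectra_tsv,
    uniform_binning,
    write_spectra_tsv,
)


def _lorentz(x, c, g, a):
    return a / np.pi * g / ((x - c) ** 2 + g**2)


def _fwhm_hz(spec, sf=600.0):
    hz = (spec.ppm * sf)[::-1]
    y = spec.intensity[::-1]
    i = int(np.argmax(y))
    half = y[i] / 2
    lo = i
    while y[lo] > half:
        lo -= 1
    hi = i
    while y[hi] > half:
        hi += 1
    x1 = hz[lo] + (half - y[lo]) * (hz[lo + 1] - hz[lo]) / (y[lo + 1] - y[lo])
    x2 = hz[hi - 1] + (half - y[hi - 1]) * (hz[hi] - hz[hi - 1]) / (y[hi] - y[hi - 1])
    return x2 - x1


class TestProcessFid:
    sw = 500.0

    def _fid(self, f0=100.0, r2=2.0, n=8192):
        t = np.arange(n) / self.sw
        return np.exp(2j * np.pi * f0 * t) * np.exp(-np.pi * r2 * t)

    def test_damped_cosine_gives_single_peak_at_frequency(self):
        spec = process_fid(self._fid(), lb_hz=0.0, sw_hz=self.sw, ppm_offset=0.0)
        peak_hz = spec.ppm[np.argmax(spec.intensity)] * 600.0
        assert peak_hz == pytest.approx(100.0, abs=0.2)

    def test_line_broadening_widens_peak_by_lb(self):
        s0 = process_fid(self._fid(), lb_hz=0.0, sw_hz=self.sw, ppm_offset=0.0,
                         auto_phase=False)
        s3 = process_fid(self._fid(), lb_hz=0.3, sw_hz=self.sw, ppm_offset=0.0,
                         auto_phase=False)
        assert _fwhm_hz(s0) == pytest.approx(2.0, abs=0.1)
        assert _fwhm_hz(s3) - _fwhm_hz(s0) == pytest.approx(0.3, abs=0.05)

    def test_auto_phase_recovers_dephased_fid(self):
        fid = self._fid() * np.exp(1j * 1.1)  # constant phase error
        ref = process_fid(self._fid(), lb_hz=0.0, sw_hz=self.sw, ppm_offset=0.0,
                          auto_phase=False)
        spec = process_fid(fid, lb_hz=0.0, sw_hz=self.sw, ppm_offset=0.0)
        assert spec.intensity.max() == pytest.approx(ref.intensity.max(), rel=0.02)

    def test_zero_fid_gives_zero_spectrum(self):
        assert np.allclose(process_fid(np.zeros(64), sw_hz=1000.0).intensity, 0)

    def test_non_finite_fid_rejected(self):
        bad = np.full(64, np.nan, dtype=complex)
        with pytest.raises(ValueError):
            process_fid(bad, sw_hz=1000.0)


class TestBaseline:
    x = np.linspace(9.8, 0.2, 2048)

    def test_flat_offset_removed(self):
        peak = _lorentz(self.x, 5.0, 0.01, 30)
        c1 = correct_baseline(Spectrum(self.x, peak)).intensity
        c2 = correct_baseline(Spectrum(self.x, peak + 10.0)).intensity
        assert np.abs(c1 - c2).max() < 0.01 * 10.0

    def test_zero_spectrum_unchanged(self):
        out = correct_baseline(Spectrum(self.x, np.zeros_like(self.x)))
        assert np.allclose(out.intensity, 0)

    def test_peak_heights_preserved_over_sine_hump(self):
        peaks = sum(_lorentz(self.x, c, 0.008, 20) for c in (2.0, 5.0, 8.0))
        hump = 3.0 * (1 + np.sin(2 * np.pi * self.x / 9.0))
        corrected = correct_baseline(Spectrum(self.x, peaks + hump)).intensity
        for c in (2.0, 5.0, 8.0):
            i = int(np.argmin(np.abs(self.x - c)))
            true_h = peaks[i]
            assert corrected[i] == pytest.approx(true_h, rel=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            asls_baseline(np.ones(100), smoothness=-1.0)
        with pytest.raises(ValueError):
            asls_baseline(np.ones(100), asymmetry=1.5)


class TestAlign:
    def test_identical_spectra_unchanged(self, toy_spectra):
        aligned = align_spectra([toy_spectra[0].copy(), toy_spectra[0].copy()])
        for a in aligned:
            assert np.allclose(a.intensity, toy_spectra[0].intensity)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(3)
        ppm = np.linspace(10, 0, 2048)
        base = _lorentz(ppm, 5.0, 0.02, 10) + rng.normal(0, 1e-3, ppm.size)
        k = 3  # points, within the default 0.02 ppm search window
        shifted = np.r_[base[k:], np.full(k, base[-1])]  # peak moved by +k positions
        ref = Spectrum(ppm, base, "ref")
        out = align_spectra([ref.copy(), Spectrum(ppm, shifted, "s")], reference=0)
        peak_ref = np.argmax(out[0].intensity)
        peak_aligned = np.argmax(out[1].intensity)
        assert peak_aligned == peak_ref

    def test_jittered_cohort_peak_position_sd_decreases(self, small_design):
        import dataclasses

        from urinmr import synth

        design = dataclasses.replace(small_design, shift_jitter_sd_ppm=0.004,
                                     noise_sd=0.05, baseline_amplitude=0.0)
        cohort = synth.simulate_cohort(design)
        target = design.panel["Succinate"].peaks[0].center_ppm

        def peak_sd(spectra):
            pos = []
            for s in spectra:
                window = (s.ppm < target + 0.05) & (s.ppm > target - 0.05)
                pos.append(s.ppm[window][np.argmax(s.intensity[window])])
            return np.std(pos)

        before = peak_sd(cohort.spectra)
        after = peak_sd(align_spectra(cohort.spectra))
        assert after < before

    def test_segment_shorter_than_window_rejected(self, toy_spectra):
        with pytest.raises(ValueError):
            align_spectra(toy_spectra, max_shift_ppm=1.0, segment_ppm=0.5)


class TestAiBinning:
    def test_two_singlets_split_once_in_valley(self, toy_spectra):
        bm = ai_binning(toy_spectra, noise_region=(9.0, 10.0))
        assert bm.n_bins == 2
        boundary = bm.bin_edges[0, 1]
        assert 3.5 < boundary < 6.5

    def test_pure_noise_never_splits(self):
        ppm = np.linspace(10, 0, 512)
        for seed in range(100):
            r = np.random.default_rng(seed)
            specs = [Spectrum(ppm, r.normal(0, 0.01, ppm.size), f"n{i}") for i in range(4)]
            assert ai_binning(specs, noise_region=(9.0, 10.0)).n_bins == 1

    def test_bins_partition_axis(self, toy_spectra):
        bm = ai_binning(toy_spectra, noise_region=(9.0, 10.0))
        edges = bm.bin_edges
        assert edges[0, 0] == toy_spectra[0].ppm[0]
        assert edges[-1, 1] == toy_spectra[0].ppm[-1]
        for k in range(len(edges) - 1):
            assert edges[k, 1] >= edges[k + 1, 0] - 0.05  # contiguous

    def test_recursive_matches_exhaustive_oracle(self):
        """On short axes the recursion must reproduce a brute-force search
        that evaluates every split point independently."""
        from urinmr.preprocess.binning import _split_bin, noise_sigma

        def brute(mat, s, e, r, sigma, safety, min_pts):
            from urinmr.preprocess.binning import noise_threshold

            if e - s + 1 < 2 * min_pts:
                return [(s, e)]
            parent = bin_value(mat, s, e, r)
            best, best_j = -np.inf, None
            for j in range(s + min_pts - 1, e - min_pts):
                bl = bin_value(mat, s, j, r)
                br = bin_value(mat, j + 1, e, r)
                if bl + br > best:
                    best, best_j = bl + br, j
            if best_j is None:
                return [(s, e)]
            bl = bin_value(mat, s, best_j, r)
            br = bin_value(mat, best_j + 1, e, r)
            ok = (
                bl + br > parent
                and bl > noise_threshold(mat.shape[0], best_j - s + 1, sigma, r, safety)
                and br > noise_threshold(mat.shape[0], e - best_j, sigma, r, safety)
            )
            if not ok:
                return [(s, e)]
            return brute(mat, s, best_j, r, sigma, safety, min_pts) + brute(
                mat, best_j + 1, e, r, sigma, safety, min_pts
            )

        for seed in range(20):
            r = np.random.default_rng(seed)
            x = np.linspace(0, 1, 64)
            mat = np.vstack(
                [
                    _lorentz(x, 0.3, 0.02, 1) + _lorentz(x, 0.7, 0.02, r.uniform(0.5, 2))
                    + r.normal(0, 0.05, 64)
                    for _ in range(3)
                ]
            )
            sigma = noise_sigma(mat[:, :10])
            out: list = []
            _split_bin(mat, 0, 63, 0.5, sigma, 4.0, 4, out)
            assert sorted(out) == sorted(brute(mat, 0, 63, 0.5, sigma, 4.0, 4))

    def test_noise_region_outside_axis_rejected(self, toy_spectra):
        with pytest.raises(ValueError):
            ai_binning(toy_spectra, noise_region=(20.0, 21.0))


class TestExcludeRegions:
    def test_empty_region_list_is_identity(self, simple_matrix):
        assert exclude_regions(simple_matrix, []) is simple_matrix

    def test_full_cover_raises_or_empties(self, simple_matrix):
        with pytest.raises(ValueError):
            exclude_regions(simple_matrix, [(0.0, 5.0)])
        out = exclude_regions(simple_matrix, [(0.0, 5.0)], on_empty="allow")
        assert out.n_bins == 0

    def test_default_regions_drop_matching_bins(self, simple_matrix):
        out = exclude_regions(simple_matrix, [(2.5, 3.5)])
        # bins (4,3), (3,2) both intersect (2.5, 3.5)
        assert out.n_bins == 3
        assert (2.5, 3.5) in out.excluded_regions

    def test_spectra_points_removed(self, toy_spectra):
        out = exclude_regions(toy_spectra, [(4.5, 5.5)])
        assert all(((s.ppm < 4.5) | (s.ppm > 5.5)).all() for s in out)


class TestNormalizeQuotient:
    def test_pure_dilution_exact(self, simple_matrix):
        out = normalize_quotient(simple_matrix)
        assert np.allclose(out.values, out.values[0])
        factors = out.metadata["pqn_factors"]
        assert np.allclose(factors / factors[0], [1.0, 2.0, 0.5, 1.5])

    def test_self_reference_quotient_is_one(self, simple_matrix):
        out = normalize_quotient(simple_matrix, reference=0)
        assert out.metadata["pqn_factors"][0] == pytest.approx(1.0)

    def test_dilution_recovery_under_noise(self, binned_default):
        bm = exclude_regions(binned_default, [(9.3, 10.0)])
        out = normalize_quotient(bm)
        r = np.corrcoef(out.metadata["pqn_factors"], bm.metadata["dilution"])[0, 1]
        assert r > 0.95

    def test_renormalizing_is_near_idempotent(self, binned_default):
        """Second-pass quotient medians sit at ~1 (the reference profile
        itself shifts slightly after normalization, so exactness is not
        attainable in general)."""
        once = normalize_quotient(binned_default)
        twice = normalize_quotient(once)
        assert np.allclose(twice.metadata["pqn_factors"], 1.0, atol=0.05)
        # a pure-dilution matrix IS exactly idempotent
        row = binned_default.values[:1]
        pure = BinnedMatrix(
            np.vstack([row, 2 * row, 0.5 * row]), binned_default.bin_edges, ["a", "b", "c"]
        )
        f2 = normalize_quotient(normalize_quotient(pure)).metadata["pqn_factors"]
        assert np.allclose(f2, 1.0, atol=1e-12)

    def test_all_zero_sample_rejected(self, simple_matrix):
        bad = simple_matrix.with_values(simple_matrix.values.copy())
        bad.values[1] = 0.0
        with pytest.raises(ValueError):
            normalize_quotient(bad)


class TestLogAutoscale:
    def test_columns_standardised(self, binned_default):
        out = log_autoscale(binned_default)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        sd = out.values.std(axis=0, ddof=1)
        assert np.abs(sd[sd > 0] - 1).max() < 1e-10

    def test_constant_column_policy(self, simple_matrix):
        m = simple_matrix.with_values(simple_matrix.values.copy())
        m.values[:, 2] = 7.0
        out = log_autoscale(m)
        assert np.allclose(out.values[:, 2], 0.0)
        with pytest.raises(ValueError):
            log_autoscale(m, constant_policy="error")

    def test_non_positive_after_offset_rejected(self, simple_matrix):
        m = simple_matrix.with_values(simple_matrix.values.copy())
        m.values[0, 0] = -5.0
        with pytest.raises(ValueError):
            log_autoscale(m, offset=1.0)


class TestMeanSpectrum:
    def test_single_sample_group_is_itself(self, toy_spectra):
        out = mean_spectrum(toy_spectra[:1], ["g"])
        assert np.allclose(out["g"].intensity, toy_spectra[0].intensity)

    def test_opposite_spectra_cancel(self, toy_spectra):
        a = toy_spectra[0]
        b = a.copy(intensity=-a.intensity)
        out = mean_spectrum([a, b])
        assert np.allclose(out.intensity, 0)

    def test_group_means_differ_in_planted_direction(self, small_cohort):
        out = mean_spectrum(small_cohort.spectra, small_cohort.labels)
        panel = small_cohort.design.panel
        # leucine is worker-elevated: its peak region should be higher in workers
        peak = panel["Leucine"].peaks[0].center_ppm
        window = (out["worker"].ppm > peak - 0.02) & (out["worker"].ppm < peak + 0.02)
        assert out["worker"].intensity[window].sum() > out["resident"].intensity[window].sum()


class TestSpectraIO:
    def test_tsv_roundtrip(self, toy_spectra, tmp_path):
        write_spectra_tsv(toy_spectra, tmp_path / "s.tsv")
        back = read_spectra_tsv(tmp_path / "s.tsv")
        assert [s.sample_id for s in back] == [s.sample_id for s in toy_spectra]
        assert np.allclose(back[0].intensity, toy_spectra[0].intensity)

    def test_jcamp_reader(self, tmp_path):
        y = [0.0, 1.0, 4.0, 1.0, 0.0]
        lines = [
            "##TITLE=demo",
            "##JCAMP-DX=4.24",
            "##XUNITS=PPM",
            "##FIRSTX=5.0",
            "##LASTX=1.0",
            "##NPOINTS=5",
            "##XFACTOR=1.0",
            "##YFACTOR=0.5",
            "##XYDATA=(X++(Y..Y))",
            "5.0 0 2 8 2 0",
            "##END=",
        ]
        path = tmp_path / "demo.jdx"
        path.write_text("\n".join(lines))
        spec = read_jcamp(path)
        assert len(spec) == 5
        assert np.allclose(sorted(spec.intensity), sorted(y))
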