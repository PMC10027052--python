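import numpy as np
import pytest

from timecellbench.containers import DfbfTensor
from timecellbench.event_library import active_mask, detect_events
from timecellbench.synthesis import (DatasetConfig, ReferenceQInputs,
                                     add_background_events, add_noise,
                                     build_benchmark_suite,
                                     compute_reference_q, dataset_reference_q,
                                     fwhm_to_sigma, generate_dataset,
                                     sample_imprecision)

from conftest import clean_config


class TestSampleImprecision:
    def test_zero_fwhm_gives_zeros(self):
        rng = np.random.default_rng(0)
        assert np.all(sample_imprecision("uniform", 0, 50, rng) == 0)
        assert np.all(sample_imprecision("none", 10, 50, rng) == 0)

    def test_uniform_bounds(self):
        rng = np.random.default_rng(1)
        offs = sample_imprecision("uniform", 10, 5000, rng)
        assert offs.min() >= -5 and offs.max() <= 5

    def test_normal_sd_matches_fwhm_conversion(self):
        rng = np.random.default_rng(2)
        offs = sample_imprecision("normal", 10, 200_000, rng)
        # FWHM / (2 sqrt(2 ln 2)) = 4.2466 frames
        assert fwhm_to_sigma(10) == pytest.approx(4.2466, abs=1e-3)
        assert offs.std() == pytest.approx(fwhm_to_sigma(10), abs=0.05)

    def test_unknown_type_errors(self):
        with pytest.raises(ValueError, match="imprecision"):
            sample_imprecision("triangular", 5, 10, np.random.default_rng(0))


class TestAddNoise:
    def test_zero_noise_identity(self):
        sig = DfbfTensor(np.random.default_rng(0).uniform(0, 1, (2, 3, 50)))
        out = add_noise(sig, 0.0, np.random.default_rng(1))
        assert out is sig

    def test_noise_sd_scales_with_percent_and_peak(self):
        rng = np.random.default_rng(3)
        values = np.zeros((2, 40, 246))
        values[0, :, 100] = 1.0   # unit-peak cell
        values[1, :, 100] = 2.0   # doubled peak
        out = add_noise(DfbfTensor(values), 10.0, rng)
        resid = out.values - values
        sd0 = resid[0].std()
        sd1 = resid[1].std()
        assert sd0 == pytest.approx(0.10, abs=0.005)
        assert sd1 / sd0 == pytest.approx(2.0, abs=0.1)


class TestBackground:
    def test_lambda_zero_noop(self, template_lib):
        values = np.zeros((2, 5, 246))
        out = add_background_events(values, template_lib, 0.0, [0, 1],
                                    np.random.default_rng(0))
        assert not out.any()

    def test_no_cells_noop(self, template_lib):
        values = np.zeros((2, 5, 246))
        out = add_background_events(values, template_lib, 2.0, [],
                                    np.random.default_rng(0))
        assert not out.any()

    def test_poisson_mean_count(self, template_lib):
        # lambda=2 with 60 trials -> ~120 inserted events per cell
        rng = np.random.default_rng(4)
        n_cells, n_trials = 40, 60
        values = np.zeros((n_cells, n_trials, 246))
        add_background_events(values, template_lib, 2.0, list(range(n_cells)), rng)
        mean_area = np.mean([e.trace.sum() for e in template_lib.events])
        est_per_cell = values.sum(axis=(1, 2)) / mean_area
        # truncation at trial end biases slightly low
        assert est_per_cell.mean() == pytest.approx(120, rel=0.08)


class TestGenerateDataset:
    def test_zero_time_cells_all_silent(self, template_lib):
        cfg = clean_config(time_cell_percent=0.0, seed=1)
        ds = generate_dataset(cfg, template_lib)
        assert not ds.truth.is_time_cell.any()
        assert not ds.truth.hit_trial_mask.any()
        assert np.all(ds.dfbf.values == 0)

    def test_no_imprecision_peaks_equal_nominal(self, template_lib):
        ds = generate_dataset(clean_config(seed=2), template_lib)
        for c in np.flatnonzero(ds.truth.is_time_cell):
            peaks = ds.truth.assigned_peak_frame[c][ds.truth.hit_trial_mask[c]]
            assert np.unique(peaks).size == 1

    def test_clean_full_htr_event_per_trial(self, template_lib):
        """Noiseless, bg-free, HTR 100% fixed: the detector recovers
        exactly one event in every trial of every time cell."""
        ds = generate_dataset(clean_config(seed=3), template_lib)
        for c in range(ds.config.n_cells):
            n_ev = sum(len(detect_events(ds.dfbf.values[c, t]))
                       for t in range(ds.config.n_trials))
            if ds.truth.is_time_cell[c]:
                assert n_ev == ds.config.n_trials
                mask = active_mask(ds.dfbf.values[c])
                frac = mask.any(axis=1).mean()
                assert frac == pytest.approx(ds.truth.realized_htr[c])
            else:
                assert n_ev == 0

    def test_determinism_bit_identical(self, template_lib):
        cfg = clean_config(seed=42, noise_type="gaussian", noise_percent=20.0,
                           bg_for_time_cells=True, bg_for_other_cells=True,
                           bg_mean=1.0)
        a = generate_dataset(cfg, template_lib)
        b = generate_dataset(cfg, template_lib)
        assert np.array_equal(a.dfbf.values, b.dfbf.values)
        assert a.watermark == b.watermark

    def test_watermark_present(self, clean_dataset):
        assert clean_dataset.watermark.startswith("SYNTHETIC-TIMECELL-BENCH")

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(start_frame=200, end_frame=100)


class TestReferenceQ:
    def test_perfect_cell_scores_one(self):
        q = compute_reference_q(ReferenceQInputs(
            htr=1.0, mnp=0.0, eaf=1.0, ew=np.full(5, 20), imp=np.zeros(5),
            stim_win=186))
        assert q == pytest.approx(1.0)

    def test_zero_htr_scores_zero(self):
        q = compute_reference_q(ReferenceQInputs(
            htr=0.0, mnp=0.0, eaf=1.0, ew=np.array([20]), imp=np.array([0]),
            stim_win=186))
        assert q == 0.0

    def test_half_htr_half_noise(self):
        # 0.5 * exp(-0.5) = 0.30327
        q = compute_reference_q(ReferenceQInputs(
            htr=0.5, mnp=50.0, eaf=1.0, ew=np.full(4, 20), imp=np.zeros(4),
            stim_win=186))
        assert q == pytest.approx(0.5 * np.exp(-0.5), abs=1e-12)

    def test_empty_widths_error(self):
        with pytest.raises(ValueError, match="width"):
            compute_reference_q(ReferenceQInputs(
                htr=0.5, mnp=0.0, eaf=1.0, ew=np.array([]), imp=np.array([]),
                stim_win=186))

    def test_q_bounded_by_htr(self, template_lib):
        cfg = clean_config(seed=7, noise_type="gaussian", noise_percent=30.0,
                           imprecision_type="normal", imprecision_fwhm=6.0,
                           max_hit_trial_percent=60.0,
                           hit_trial_assignment="random")
        ds = generate_dataset(cfg, template_lib)
        q = dataset_reference_q(ds)
        assert np.all(q >= 0) and np.all(q <= 1)
        assert np.all(q <= ds.truth.realized_htr + 1e-12)
        assert not q[~ds.truth.is_time_cell].any()

    def test_mean_q_decreases_with_noise(self, template_lib):
        means = []
        for noise in (10.0, 40.0, 70.0):
            vals = []
            for seed in range(10):
                cfg = clean_config(seed=seed, noise_type="gaussian",
                                   noise_percent=noise)
                vals.append(dataset_reference_q(
                    generate_dataset(cfg, template_lib)).mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestBenchmarkSuite:
    def test_full_scale_enumeration(self):
        configs = build_benchmark_suite(scale=1.0)
        assert len(configs) == 567
        assert sum(c.n_cells for c in configs) == 76_545
        assert len({c.seed for c in configs}) == len(configs)

    def test_desk_scale_overrides(self):
        configs = build_benchmark_suite(scale=0.2, n_cells=45, n_trials=30,
                                        n_shuffles=1)
        assert len(configs) == 126
        assert all(c.n_cells == 45 and c.n_trials == 30 for c in configs)
        assert all("scaled" in c.label for c in configs)

    def test_regime_composition(self):
        configs = build_benchmark_suite(scale=1.0)
        unphys = [c for c in configs if c.label.startswith("unphys")]
        canon = [c for c in configs if c.label.startswith("canonical")]
        phys = [c for c in configs if c.label.startswith("phys:")]
        assert (len(unphys), len(canon), len(phys)) == (297, 120, 150)
        assert all(c.bg_mean > 0 for c in phys)
        assert all(c.bg_mean == 0 for c in unphys + canon)
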