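import numpy as np
import pytest
from scipy import stats

from latency_readout import retina, tuning
from latency_readout.spikeio import Dataset


class TestSamplePopulation:
    def test_seeded_reproducibility(self):
        cfg = retina.PopulationConfig(n_cells=20, seed=3)
        p1 = retina.sample_population(cfg)
        p2 = retina.sample_population(cfg)
        assert p1 == p2

    def test_phase_offsets_uniform(self):
        cfg = retina.PopulationConfig(n_cells=1000, seed=0)
        pop = retina.sample_population(cfg)
        phi0 = np.array([c.phase_offset_deg for c in pop])
        _, p = stats.kstest(phi0 / 360.0, "uniform")
        assert p > 0.05

    def test_latency_count_parameters_independent(self):
        cfg = retina.PopulationConfig(n_cells=1000, seed=1)
        pop = retina.sample_population(cfg)
        b_lat = np.array([c.latency_baseline for c in pop])
        b_cnt = np.array([c.count_baseline for c in pop])
        assert abs(np.corrcoef(b_lat, b_cnt)[0, 1]) < 0.1

    def test_latencies_stay_positive(self):
        cfg = retina.PopulationConfig(n_cells=300, seed=2)
        for c in retina.sample_population(cfg):
            assert c.latency_baseline > c.latency_amplitude > 0


class TestSimulateTrial:
    def test_noiseless_latency_on_cosine_curve(self):
        cfg = retina.PopulationConfig(
            n_cells=4, seed=0, jitter_shared_sd=0.0, jitter_private_sd=0.0,
            count_noise_sd=0.0,
        )
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=2)
        for cell_idx, cell in enumerate(pop):
            responses = [
                (retina.phase_deg(t.phase_index), t.trains[cell_idx].times[0])
                for t in data.trials
            ]
            fit = tuning.fit_cosine(responses)
            assert fit.baseline == pytest.approx(cell.latency_baseline, abs=1e-9)
            assert fit.amplitude == pytest.approx(cell.latency_amplitude, abs=1e-9)
            assert fit.r2_single == pytest.approx(1.0, abs=1e-12)

    def test_latency_count_antiphase(self):
        cfg = retina.PopulationConfig(
            n_cells=6, seed=4, jitter_shared_sd=0.0, jitter_private_sd=0.0,
            count_noise_sd=0.0,
        )
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=2)
        for i in range(len(pop)):
            lat, cnt = [], []
            for t in data.trials:
                phi = retina.phase_deg(t.phase_index)
                lat.append((phi, t.trains[i].times[0]))
                cnt.append((phi, len(t.trains[i].times)))
            f_lat = tuning.fit_cosine(lat)
            f_cnt = tuning.fit_cosine(cnt)
            diff = (f_cnt.phase_offset_deg - f_lat.phase_offset_deg) % 360.0
            assert abs(diff - 180.0) < 15.0

    def test_shared_jitter_correlation(self):
        cfg = retina.PopulationConfig(
            n_cells=2, seed=5, jitter_shared_sd=2.0, jitter_private_sd=2.0
        )
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=200)
        _, mean_r = tuning.pair_latency_correlation(data, 0, 1)
        assert mean_r == pytest.approx(0.5, abs=0.1)

    def test_contrast_shift_moves_baseline_only(self):
        cfg = retina.PopulationConfig(
            n_cells=4, seed=6, jitter_shared_sd=0.0, jitter_private_sd=0.0,
            count_noise_sd=0.0,
            contrast_shift_ms={50.0: -20.0, 100.0: 0.0},
        )
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=1)
        for i in range(len(pop)):
            fits = {}
            for level in (50.0, 100.0):
                resp = [
                    (retina.phase_deg(t.phase_index), t.trains[i].times[0])
                    for t in data.trials
                    if t.contrast == level
                ]
                fits[level] = tuning.fit_cosine(resp)
            assert fits[50.0].baseline - fits[100.0].baseline == pytest.approx(
                -20.0, abs=1e-9
            )
            assert fits[50.0].amplitude == pytest.approx(
                fits[100.0].amplitude, abs=1e-9
            )
            assert fits[50.0].phase_offset_deg == pytest.approx(
                fits[100.0].phase_offset_deg, abs=1e-9
            )

    def test_failures_more_frequent_at_low_contrast(self):
        cfg = retina.PopulationConfig(
            n_cells=5, seed=7,
            contrast_shift_ms={10.0: 30.0, 100.0: 0.0},
            failure_rate={10.0: 0.3, 100.0: 0.0},
        )
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=60)
        def failure_frac(level):
            trials = [t for t in data.trials if t.contrast == level]
            empty = sum(len(tr.times) == 0 for t in trials for tr in t.trains)
            return empty / (len(trials) * 5)
        assert failure_frac(100.0) <= 0.02  # only window-overrun failures
        assert failure_frac(10.0) == pytest.approx(0.3, abs=0.06)

    def test_burst_structure_within_window(self):
        cfg = retina.PopulationConfig(n_cells=3, seed=8, count_noise_sd=0.0)
        pop = retina.sample_population(cfg)
        data = retina.simulate_dataset(pop, cfg, trials_per_condition=5)
        for t in data.trials:
            for tr, cell in zip(t.trains, pop):
                if len(tr.times) >= 2:
                    isis = np.diff(tr.times)
                    assert np.allclose(isis, cell.burst_isi)
                if tr.times:
                    assert tr.times[-1] <= data.window_ms


class TestDarkFraction:
    def test_point_receptive_field_inside_dark_bar(self):
        # dark bars at phase 0 cover u in [0, 0.5)
        D = retina.dark_fraction((0.25, 0.0), 1e-4, 0.0)
        assert D == pytest.approx(1.0, abs=1e-9)

    def test_polarity_inversion_complement(self, rng):
        for _ in range(10):
            center = tuple(rng.uniform(-1.5, 1.5, 2))
            phi = float(rng.uniform(0, 360))
            psi = float(rng.uniform(-90, 90))
            D1 = retina.dark_fraction(center, 0.12, phi, psi)
            D2 = retina.dark_fraction(center, 0.12, phi + 180.0, psi)
            assert D1 + D2 == pytest.approx(1.0, abs=1e-9)

    def test_wide_field_averages_to_half(self):
        D = retina.dark_fraction((0.3, -0.2), 50.0, 123.0, 30.0)
        assert D == pytest.approx(0.5, abs=1e-6)

    def test_orientation_mod_180_invariance(self, rng):
        for _ in range(10):
            center = tuple(rng.uniform(-1.5, 1.5, 2))
            phi = float(rng.uniform(0, 360))
            psi = float(rng.uniform(-89, 89))
            assert retina.dark_fraction(center, 0.12, phi, psi) == pytest.approx(
                retina.dark_fraction(center, 0.12, phi, psi + 180.0), abs=1e-12
            )

    def test_continuity_in_phase(self):
        Ds = [retina.dark_fraction((0.4, 0.1), 0.12, phi, 20.0) for phi in
              np.linspace(0, 360, 721)]
        assert np.max(np.abs(np.diff(Ds))) < 0.02

    def test_grid_matches_scalar(self, rng):
        centers = rng.uniform(-1, 1, (6, 2))
        phis = rng.uniform(0, 360, 4)
        psis = rng.uniform(-90, 90, 4)
        M = retina.dark_fraction_grid(centers, 0.12, phis, psis)
        for s in range(4):
            for c in range(6):
                assert M[s, c] == pytest.approx(
                    retina.dark_fraction(tuple(centers[c]), 0.12, phis[s], psis[s]),
                    abs=1e-12,
                )


class TestLatencyLaw:
    @pytest.mark.parametrize(
        "D,expected",
        [(0.0, 105.0), (1.0, 55.0), (0.5, 80.0)],
    )
    def test_endpoints_and_midpoint(self, D, expected):
        assert retina.latency_from_dark_fraction(D, 80.0, 25.0) == pytest.approx(
            expected
        )

    def test_monotone_decreasing_in_coverage(self):
        Ds = np.linspace(0, 1, 50)
        lats = [retina.latency_from_dark_fraction(D, 80.0, 25.0) for D in Ds]
        assert np.all(np.diff(lats) < 0)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            retina.latency_from_dark_fraction(1.2, 80.0, 25.0)


class TestHexSchematic:
    def test_pattern_counts(self):
        ds, targets = retina.hex_schematic((1, 1, 1, 0, 0, 0, 0))
        assert len(ds) == 128
        assert targets.sum() == 2
        assert (~targets).sum() == 126

    def test_polarity_inversion_is_involution(self):
        ds, _ = retina.hex_schematic((1, 0, 1, 0, 1, 0, 1), delta_t=30.0, t_early=20.0)
        def bits_of(trial):
            return tuple(int(tr.times[0] == 20.0) for tr in trial.trains)
        for trial in ds.trials[:16]:
            b = bits_of(trial)
            inv = tuple(1 - x for x in b)
            invinv = tuple(1 - x for x in inv)
            assert invinv == b

    def test_each_cell_fires_exactly_once_early_or_late(self):
        ds, _ = retina.hex_schematic((1, 1, 0, 0, 1, 0, 1), delta_t=25.0, t_early=10.0)
        for trial in ds.trials:
            for tr in trial.trains:
                assert len(tr.times) == 1
                assert tr.times[0] in (10.0, 35.0)

    def test_invalid_preferred_rejected(self):
        with pytest.raises(ValueError):
            retina.hex_schematic((1, 0, 1))
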