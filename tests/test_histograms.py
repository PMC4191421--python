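"""Histograms: normalization, subtraction conservation, scoring, level fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import gqfret as g
from conftest import fret_traces_of, single_state_config
from gqfret.exceptions import ConfigurationError


def hist_from_values(values, weights_percent=None, bin_width=0.025):
    """Build a FretHistogram directly from E values (one frame each)."""
    traces = [g.FretTrace(i, np.array([v]), 1) for i, v in enumerate(values)]
    return g.build_histogram(traces, frames_per_molecule=1, bin_width=bin_width)


class TestBuildHistogram:
    def test_single_molecule_single_level_fills_one_bin(self):
        ft = g.FretTrace(0, np.full(30, 0.5), 30)
        hist = g.build_histogram([ft])
        assert hist.counts_percent.max() == pytest.approx(100.0)
        assert (hist.counts_percent > 0).sum() == 1

    def test_two_molecules_split_fifty_fifty(self):
        fts = [g.FretTrace(0, np.full(30, 0.2), 30), g.FretTrace(1, np.full(30, 0.8), 30)]
        hist = g.build_histogram(fts)
        occupied = hist.counts_percent[hist.counts_percent > 0]
        assert np.allclose(occupied, [50.0, 50.0])
        assert hist.n_molecules == 2

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 1000),
        n=st.integers(1, 40),
        frames=st.integers(1, 30),
    )
    def test_normalization_to_100_is_exact(self, seed, n, frames):
        rng = np.random.default_rng(seed)
        fts = [
            g.FretTrace(i, rng.normal(0.5, 0.3, 30), rng.integers(1, 31))
            for i in range(n)
        ]
        hist = g.build_histogram(fts, frames_per_molecule=frames)
        assert hist.counts_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_frames_per_molecule_caps_pooling(self):
        e = np.concatenate([np.full(10, 0.2), np.full(20, 0.8)])
        ft = g.FretTrace(0, e, 30)
        hist = g.build_histogram([ft], frames_per_molecule=10)
        assert g.threshold_population(hist, 0.5) == pytest.approx(100.0)

    def test_generator_folded_mixture_peaks_near_configured_centers(self):
        cfg = single_state_config(
            g.CANONICAL_STATES[g.StateName.folded_conf1], n_molecules=150, seed=2
        )
        hist = g.build_histogram(fret_traces_of(cfg))
        mode = hist.bin_centers[np.argmax(hist.counts_percent)]
        assert abs(mode - 0.64) <= 2 * hist.bin_width

    def test_no_traces_is_an_error(self):
        with pytest.raises(ConfigurationError):
            g.build_histogram([])


class TestSubtraction:
    def test_identical_histograms_give_zero_difference(self):
        hist = hist_from_values(np.linspace(0.1, 0.9, 50))
        diff = g.subtract_reference(hist, hist)
        assert np.allclose(diff.delta_percent, 0.0)
        assert g.positive_area(diff) == 0.0

    def test_conservation_of_positive_and_negative_lobes(self):
        rng = np.random.default_rng(1)
        sample = hist_from_values(rng.normal(0.3, 0.08, 400))
        reference = hist_from_values(rng.normal(0.7, 0.07, 300))
        diff = g.subtract_reference(sample, reference)
        assert diff.delta_percent.sum() == pytest.approx(0.0, abs=1e-9)
        pos = diff.delta_percent[diff.delta_percent > 0].sum()
        neg = -diff.delta_percent[diff.delta_percent < 0].sum()
        assert pos == pytest.approx(neg, abs=1e-9)

    def test_thirty_percent_mass_shift_scores_thirty(self):
        # 30% of molecules move from a high-FRET bin to a low-FRET bin
        reference = hist_from_values([0.7] * 10)
        sample = hist_from_values([0.7] * 7 + [0.3] * 3)
        diff = g.subtract_reference(sample, reference)
        assert g.positive_area(diff) == pytest.approx(30.0, abs=1e-9)

    def test_mismatched_binning_is_an_error(self):
        h1 = hist_from_values([0.5], bin_width=0.025)
        h2 = hist_from_values([0.5], bin_width=0.05)
        with pytest.raises(ConfigurationError):
            g.subtract_reference(h1, h2)

    def test_half_saturation_positive_area_through_pipeline(self, ntfree_occupancy):
        # at x = K_eq the configured low-class occupancy is alpha/2 = 24.5%;
        # the subtraction score recovers it up to the Gaussian-overlap loss
        cfg = g.SimulationConfig(
            condition=g.Condition(protein=g.Protein.BLM),
            occupancy=ntfree_occupancy,
            n_molecules=300,
            seed=9,
        )
        datasets = g.simulate_titration(cfg, [0.0, 305.0], n_fields=2)
        series, _ = g.titration_series_from_datasets(datasets)
        assert series.y[1] == pytest.approx(24.5, abs=4.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_positive_area_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        edges = -0.2 + 0.025 * np.arange(57)
        delta = rng.normal(0, 1, 56)
        delta -= delta.mean()  # conservation
        diff = g.DifferenceHistogram(edges, delta)
        total = 0.0
        for value in delta:  # independent scalar loop
            if value > 0:
                total += value
        assert g.positive_area(diff) == pytest.approx(total, abs=1e-12)


class TestThresholdPopulation:
    def test_below_first_occupied_bin_is_zero(self):
        hist = hist_from_values([0.5] * 10)
        assert g.threshold_population(hist, 0.2) == 0.0

    def test_upper_range_recovers_full_normalization(self):
        hist = hist_from_values(np.random.default_rng(0).uniform(0, 1, 200))
        assert g.threshold_population(hist, 1.2) == pytest.approx(100.0, abs=1e-9)

    def test_straddling_bin_contributes_pro_rata(self):
        # all mass in bin [0.50, 0.525); threshold mid-bin takes half
        hist = hist_from_values([0.51] * 8)
        left = hist.bin_edges[np.argmax(hist.counts_percent)]
        assert g.threshold_population(hist, left + 0.0125) == pytest.approx(50.0)

    def test_configured_low_class_mass_recovered(self, ntfree_occupancy):
        # ~24.5% of molecules in the 0.20/0.40 states at half saturation
        cfg = g.SimulationConfig(
            condition=g.Condition(protein=g.Protein.BLM),
            occupancy=ntfree_occupancy,
            n_molecules=400,
            seed=4,
        )
        hist = g.pooled_histogram(
            [g.simulate_dataset(cfg)], g.ProcessingOptions(), g.HistogramOptions()
        )
        cfg305 = g.SimulationConfig(
            condition=g.Condition(protein=g.Protein.BLM, protein_conc=305.0),
            occupancy=ntfree_occupancy,
            n_molecules=400,
            seed=4,
        )
        hist = g.pooled_histogram(
            [g.simulate_dataset(cfg305)], g.ProcessingOptions(), g.HistogramOptions()
        )
        # integrate below the midpoint between the low classes and folded states
        assert g.threshold_population(hist, 0.50) == pytest.approx(24.5, abs=4.0)


class TestGaussianFit:
    def test_exact_rendered_gaussian_recovered_to_high_precision(self):
        edges = -0.2 + 0.025 * np.arange(57)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = 100 * 0.025 * norm.pdf(centers, 0.42, 0.05)
        counts *= 100.0 / counts.sum()
        hist = g.FretHistogram(edges, counts, n_molecules=1)
        (comp,) = g.fit_gaussians(hist, 1)
        assert comp.center == pytest.approx(0.42, abs=1e-6)
        assert comp.sigma == pytest.approx(0.05, abs=1e-4)

    def test_two_conformer_folded_distribution_recovers_both_centers(self, blm_condition):
        occ = g.OccupancySpec(
            g.IsothermParams(49.0, 305.0),
            g.folded_states_potassium(),
            g.default_low_states(),
        )
        cfg = g.SimulationConfig(
            condition=g.Condition(),
            occupancy=occ,
            n_molecules=400,
            contaminant_fraction=0.0,
            seed=6,
        )
        hist = g.build_histogram(fret_traces_of(cfg))
        lo, hi = g.fit_gaussians(hist, 2)
        assert lo.center == pytest.approx(0.64, abs=0.03)
        assert hi.center == pytest.approx(0.78, abs=0.03)

    def test_unfolded_state_center_and_width(self):
        cfg = single_state_config(
            g.CANONICAL_STATES[g.StateName.unfolded], n_molecules=300, seed=8
        )
        hist = g.build_histogram(fret_traces_of(cfg))
        (comp,) = g.fit_gaussians(hist, 1)
        assert comp.center == pytest.approx(0.40, abs=0.01)
        # observed width = state width (0.06) broadened by intensity noise
        assert 0.05 <= comp.sigma <= 0.09

    def test_too_few_occupied_bins_rejected(self):
        hist = hist_from_values([0.5] * 10)
        with pytest.raises(ConfigurationError):
            g.fit_gaussians(hist, 2)


class TestCsvRoundTrip:
    def test_histogram_csv_round_trip(self, tmp_path, blm_condition):
        rng = np.random.default_rng(3)
        fts = [g.FretTrace(i, rng.normal(0.6, 0.1, 20), 20) for i in range(30)]
        hist = g.build_histogram(fts, condition=blm_condition)
        g.write_histogram(hist, tmp_path / "h.csv")
        back = g.read_histogram(tmp_path / "h.csv")
        assert np.allclose(back.bin_edges, hist.bin_edges)
        assert np.allclose(back.counts_percent, hist.counts_percent)
        assert back.n_molecules == 30
        assert back.condition == blm_condition
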