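"""Trace I/O, background subtraction, single-molecule filter and E_FRET."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gqfret as g
from gqfret.exceptions import ManifestError, TraceParseError


class TestRoundTrip:
    def test_write_then_read_is_lossless(self, small_config, tmp_path):
        ds = g.simulate_dataset(small_config)
        ds.provenance["custom_key"] = "survives"
        g.write_traces(ds, tmp_path / "d0")
        back = g.read_traces(tmp_path / "d0")
        assert back.condition == ds.condition
        assert back.provenance["custom_key"] == "survives"
        assert back.ground_truth["isotherm"]["k_eq"] == 305.0
        assert len(back.traces) == len(ds.traces)
        for a, b in zip(ds.traces, back.traces):
            assert np.array_equal(a.i_donor, b.i_donor)
            assert np.array_equal(a.i_acceptor, b.i_acceptor)
            assert a.category == b.category
            assert a.bleach_frame_d == b.bleach_frame_d

    def test_empty_table_is_a_parse_error(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "traces.csv").write_text("")
        (d / "manifest.json").write_text("{}")
        with pytest.raises(TraceParseError, match="empty"):
            g.read_traces(d)

    def test_non_numeric_cell_names_molecule_and_line(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "traces.csv").write_text(
            "molecule_id,frame,i_donor,i_acceptor\n0,0,100,50\n0,1,oops,50\n"
        )
        (d / "manifest.json").write_text("{}")
        with pytest.raises(TraceParseError, match="molecule 0 at line 3"):
            g.read_traces(d)

    def test_manifest_missing_condition_lists_required_keys(self, small_config, tmp_path):
        ds = g.simulate_dataset(small_config)
        g.write_traces(ds, tmp_path / "d0")
        manifest = json.loads((tmp_path / "d0" / "manifest.json").read_text())
        del manifest["condition"]
        (tmp_path / "d0" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ManifestError, match="protein_conc_nM"):
            g.read_traces(tmp_path / "d0")


class TestBackgroundSubtraction:
    def test_constant_zero_background_is_identity(self, small_config):
        t = g.simulate_trace(small_config, 0)
        out = g.subtract_background(t, "constant", background=(0.0, 0.0))
        assert np.array_equal(out.i_donor, t.i_donor)

    def test_constant_matches_generator_backgrounds(self, small_config):
        cfg = dataclasses.replace(
            small_config, donor_bleach_rate=0.0, acceptor_bleach_rate=0.0
        )
        t = g.simulate_trace(cfg, 1)
        out = g.subtract_background(
            t, "constant", background=(cfg.background_d, cfg.background_a)
        )
        # corrected total should fluctuate around the molecule brightness
        expected = t.total.mean() - cfg.background_d - cfg.background_a
        assert out.total.mean() == pytest.approx(expected, abs=1e-9)

    def test_post_bleach_estimates_true_backgrounds(self):
        rng = np.random.default_rng(0)
        n, bleach, noise = 1000, 500, 5.0
        i_d = np.where(np.arange(n) < bleach, 300.0, 0.0) + 20.0
        i_a = np.where(np.arange(n) < bleach, 200.0, 0.0) + 15.0
        t = g.Trace(0, i_d + rng.normal(0, noise, n), i_a + rng.normal(0, noise, n))
        out = g.subtract_background(t, "post_bleach")
        n_post = n - bleach
        tol = 3 * noise / np.sqrt(n_post)
        assert abs(out.i_donor[bleach:].mean()) < tol
        assert abs(out.i_acceptor[bleach:].mean()) < tol

    def test_post_bleach_without_step_falls_back_with_warning(self, caplog):
        t = g.Trace(5, np.full(100, 300.0), np.full(100, 200.0))
        with caplog.at_level("WARNING"):
            out = g.subtract_background(t, "post_bleach", background=(10.0, 10.0))
        assert "no bleach step" in caplog.text
        assert out.i_donor[0] == 290.0


class TestComputeFret:
    def test_equal_channels_give_half(self):
        t = g.Trace(0, np.full(10, 120.0), np.full(10, 120.0))
        ft = g.compute_fret(t)
        assert np.allclose(ft.e, 0.5)

    def test_zero_acceptor_gives_zero(self):
        t = g.Trace(0, np.full(10, 240.0), np.zeros(10))
        assert np.allclose(g.compute_fret(t).e, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_common_channel_scaling(self, scale):
        rng = np.random.default_rng(4)
        i_d = rng.uniform(50, 400, 20)
        i_a = rng.uniform(50, 400, 20)
        e1 = g.compute_fret(g.Trace(0, i_d, i_a)).e
        e2 = g.compute_fret(g.Trace(0, i_d * scale, i_a * scale)).e
        assert np.allclose(e1, e2, atol=1e-12)

    def test_usable_frames_end_at_donor_bleach(self):
        i_d = np.where(np.arange(100) < 60, 300.0, 1.0)
        i_a = np.where(np.arange(100) < 60, 200.0, 1.0)
        ft = g.compute_fret(g.Trace(0, i_d, i_a))
        assert ft.usable_frames == 60

    def test_negative_total_marks_frame_not_nan(self):
        i_d = np.full(10, 100.0)
        i_a = np.full(10, 100.0)
        i_d[3] = -150.0
        i_a[3] = -150.0
        ft = g.compute_fret(g.Trace(0, i_d, i_a))
        assert np.isfinite(ft.e).all()
        assert ft.usable_frames == 3


class TestFilter:
    def make_dataset(self, contaminant_fraction, n, seed=17):
        occ = g.OccupancySpec(
            g.IsothermParams(49.0, 305.0),
            g.folded_states_potassium(),
            g.default_low_states(),
        )
        cfg = g.SimulationConfig(
            condition=g.Condition(protein=g.Protein.BLM, protein_conc=305.0),
            occupancy=occ,
            n_molecules=n,
            contaminant_fraction=contaminant_fraction,
            seed=seed,
        )
        ds = g.simulate_dataset(cfg)
        corrected = [
            g.subtract_background(
                t, "constant", background=(cfg.background_d, cfg.background_a)
            )
            for t in ds.traces
        ]
        return g.TraceDataset(corrected, ds.condition, ds.ground_truth, ds.provenance)

    def test_confusion_matrix_against_ground_truth(self):
        ds = self.make_dataset(contaminant_fraction=0.2, n=500)
        accepted, report = g.filter_single_molecules(ds)
        truth = {t.molecule_id: t.category for t in ds.traces}
        n_singles = sum(1 for c in truth.values() if c == "single")
        n_contam = len(truth) - n_singles
        kept_singles = sum(1 for t in accepted.traces if truth[t.molecule_id] == "single")
        kept_contam = sum(1 for t in accepted.traces if truth[t.molecule_id] != "single")
        assert kept_singles / n_singles >= 0.85
        assert kept_contam / n_contam <= 0.05
        assert report.n_accepted == len(accepted.traces)

    def test_accepted_and_rejected_partition_the_input(self):
        ds = self.make_dataset(contaminant_fraction=0.2, n=200)
        accepted, report = g.filter_single_molecules(ds)
        accepted_ids = {t.molecule_id for t in accepted.traces}
        rejected_ids = set(report.rejected_ids)
        assert accepted_ids | rejected_ids == {t.molecule_id for t in ds.traces}
        assert not accepted_ids & rejected_ids

    def test_filtering_is_deterministic(self):
        ds = self.make_dataset(contaminant_fraction=0.2, n=200)
        a1, r1 = g.filter_single_molecules(ds)
        a2, r2 = g.filter_single_molecules(ds)
        assert [t.molecule_id for t in a1.traces] == [t.molecule_id for t in a2.traces]
        assert r1.rejected_by_reason == r2.rejected_by_reason

    def test_clean_dataset_is_mostly_accepted_with_no_contaminants_kept(self):
        # brightness spread (lognormal, CV 0.2) puts a tail of true singles
        # outside the intensity band, so acceptance is high but not total
        ds = self.make_dataset(contaminant_fraction=0.0, n=400)
        accepted, report = g.filter_single_molecules(ds)
        assert report.n_accepted / report.n_input >= 0.85
        # the rare rejections are brightness/bleach screening, not state-driven
        assert report.rejected_by_reason.get("no_acceptor", 0) <= 0.01 * report.n_input

    def test_aggregates_rejected_for_intensity(self, small_config):
        cfg = dataclasses.replace(small_config, n_molecules=50)
        ds = g.simulate_dataset(cfg)
        agg = g.simulate_contaminant(dataclasses.replace(cfg, seed=99), 0)
        while agg.category != "aggregate":
            agg = g.simulate_contaminant(
                dataclasses.replace(cfg, seed=99), agg.molecule_id + 1,
            )
            agg = dataclasses.replace(agg, molecule_id=agg.molecule_id)
        agg = dataclasses.replace(agg, molecule_id=1000)
        full = g.TraceDataset([*ds.traces, agg], ds.condition)
        _, report = g.filter_single_molecules(full)
        assert report.rejected_ids.get(1000) == "intensity_band"

    def test_donor_only_rejected_for_missing_acceptor(self, small_config):
        cfg = dataclasses.replace(small_config, n_molecules=50)
        ds = g.simulate_dataset(cfg)
        dono = None
        for m in range(20):
            c = g.simulate_contaminant(dataclasses.replace(cfg, seed=55), m)
            if c.category == "donor_only":
                dono = dataclasses.replace(c, molecule_id=1000)
                break
        assert dono is not None
        corrected = [
            g.subtract_background(
                t, "constant", background=(cfg.background_d, cfg.background_a)
            )
            for t in [*ds.traces, dono]
        ]
        full = g.TraceDataset(corrected, ds.condition)
        _, report = g.filter_single_molecules(full)
        assert report.rejected_ids.get(1000) == "no_acceptor"

    def test_empty_dataset_returns_empty_with_warning(self, caplog, blm_condition):
        ds = g.TraceDataset([], blm_condition)
        with caplog.at_level("WARNING"):
            accepted, report = g.filter_single_molecules(ds)
        assert accepted.n_molecules == 0
        assert report.n_input == 0
        assert "empty" in caplog.text

    def test_noiseless_unfolded_traces_keep_configured_level(self):
        from conftest import single_state_config

        state = g.FretState(g.StateName.unfolded, 0.40, 1e-9)
        cfg = single_state_config(
            state, n_molecules=3, noise_sigma=1e-9, intensity_cv=0.0,
            background_d=0.0, background_a=0.0,
            donor_bleach_rate=0.0, acceptor_bleach_rate=0.0,
        )
        ds = g.simulate_dataset(cfg)
        for t in ds.traces:
            ft = g.compute_fret(t)
            assert np.allclose(ft.e[: ft.usable_frames], 0.40, atol=1e-6)
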