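from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import cardiofuse as cf
from cardiofuse.synthetic_data import _severe_drift

from conftest import run_pipeline


class TestSimulateEmbryo:
    def test_deterministic_given_seed_and_id(self):
        cfg = cf.SimulationConfig(seed=1)
        a = cf.simulate_embryo(cfg, "e1")
        b = cf.simulate_embryo(cfg, "e1")
        pd.testing.assert_frame_equal(a.data, b.data)
        c = cf.simulate_embryo(cfg, "e2")
        assert not a.data[["x", "y"]].equals(c.data[["x", "y"]])

    def test_complete_tracks_and_one_reference(self, noiseless_config):
        tt = cf.simulate_embryo(noiseless_config, "e1")
        _, report = cf.filter_complete_tracks(tt)
        assert report["dropped"].sum() == 0
        ref = tt.data[tt.data["cell_class"] == "reference"]
        assert ref["track_id"].nunique() == 1
        assert len(ref) == noiseless_config.n_timepoints

    def test_zero_noise_drift_integrates_exactly(self, noiseless_config):
        # 0.5 μm/min for 120 min -> 60 μm medial, per cell, exactly
        kin = run_pipeline(cf.simulate_embryo(noiseless_config, "e1"))
        np.testing.assert_allclose(kin["velocity_ml"], 0.5, rtol=1e-12)
        np.testing.assert_allclose(kin["displacement"], 60.0, rtol=1e-12)

    def test_imaging_drift_cancelled_by_correction(self, noiseless_config):
        cfg = replace(noiseless_config, medial_drift=0.0, imaging_drift=(1.0, 0.0))
        raw = cf.simulate_embryo(cfg, "e1")
        # raw tracks translate at the imaging drift rate
        one = raw.cells[raw.cells["track_id"] == raw.cells["track_id"].iloc[0]]
        np.testing.assert_allclose(np.diff(one["x"]), cfg.dt * 1.0)
        corrected = cf.align_sides(cf.drift_correct(raw))
        assert np.allclose(
            corrected.data.groupby("track_id")[["x", "y"]].std(ddof=0), 0.0,
            atol=1e-9,
        )

    def test_reference_retracts_posteriorly(self):
        cfg = cf.SimulationConfig(reference_retraction=0.5, imaging_drift=(0, 0))
        tt = cf.simulate_embryo(cfg, "e1")
        ref = tt.data[tt.data["cell_class"] == "reference"].sort_values("t_index")
        np.testing.assert_allclose(np.diff(ref["y"]), -0.5 * cfg.dt)

    def test_coherent_movement_preserves_rank_order(self):
        cfg = cf.SimulationConfig(
            cells_per_side=8, coherent_fraction=1.0, noise_sigma=0.4,
            z_noise_sigma=0.0, seed=3,
        )
        tt = cf.simulate_embryo(cfg, "e1")
        left = tt.cells[tt.cells["side"] == "left"]
        wide = left.pivot(index="t_index", columns="track_id", values="x")
        ranks = wide.rank(axis=1)
        assert (ranks.nunique(axis=0) == 1).all()  # no neighbor exchange

    @pytest.mark.parametrize("bad", [dict(dt=0.0), dict(n_timepoints=1),
                                     dict(coherent_fraction=1.5),
                                     dict(noise_sigma=-0.1)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(cf.ConfigurationError):
            cf.SimulationConfig(**bad).validate()

    def test_config_dict_roundtrip(self):
        cfg = cf.SimulationConfig(seed=9, cells_per_side=(10, 12))
        assert cf.SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestPresets:
    def test_wt_preset_counts(self):
        _, preset = cf.make_preset("wt")
        assert len(preset.embryos) == 8
        assert preset.total_cells == 168
        assert all(e.medial_drift > 0 for e in preset.embryos)
        assert preset.cell_weighted_mean_drift() == pytest.approx(0.19)

    def test_mutant_preset_counts_and_split(self):
        _, preset = cf.make_preset("ref_mutant")
        assert len(preset.embryos) == 6
        assert preset.total_cells == 137
        phenotypes = [e.phenotype for e in preset.embryos]
        assert phenotypes.count("mild") == 2
        assert phenotypes.count("severe") == 4
        assert all(
            e.medial_drift <= 0 for e in preset.embryos if e.phenotype == "severe"
        )

    def test_severe_drift_closed_form(self):
        # hand calibration: (46*0.19 + 91*d) / 137 = 0.016
        d = (137 * 0.016 - 46 * 0.19) / 91
        assert _severe_drift() == pytest.approx(d, rel=1e-12)
        _, preset = cf.make_preset("ref_mutant")
        assert preset.cell_weighted_mean_drift() == pytest.approx(0.016, rel=1e-9)

    def test_cells_per_embryo_in_tracked_range(self):
        for name in ("wt", "ref_mutant"):
            _, preset = cf.make_preset(name)
            for e in preset.embryos:
                assert 20 <= e.n_cells <= 30

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            cf.make_preset("nope")


class TestSimulateCohort:
    def test_track_counts(self):
        wt = cf.simulate_cohort("wt", seed=1)
        assert wt.n_tracks == 168
        assert wt.data[wt.data["cell_class"] == "reference"]["embryo_id"].nunique() == 8
        mut = cf.simulate_cohort("ref_mutant", seed=1)
        assert mut.n_tracks == 137

    def test_cohort_reproducible_from_seed(self):
        a = cf.simulate_cohort("wt", seed=5)
        b = cf.simulate_cohort("wt", seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_noise_cohort_mean_equals_target_exactly(self):
        for name, target in (("wt", 0.19), ("ref_mutant", 0.016)):
            cfg, preset = cf.make_preset(name)
            cfg = replace(cfg, noise_sigma=0.0, z_noise_sigma=0.0)
            kin = run_pipeline(cf.simulate_cohort(preset, cfg, seed=2))
            assert kin["velocity_ml"].mean() == pytest.approx(target, abs=1e-12)

    @pytest.mark.parametrize("name, target", [("wt", 0.19), ("ref_mutant", 0.016)])
    def test_stochastic_recovery_within_3_se(self, name, target):
        cfg, preset = cf.make_preset(name)
        means = []
        for seed in range(5):
            kin = run_pipeline(cf.simulate_cohort(preset, cfg, seed=seed))
            means.append(kin["velocity_ml"].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - target) <= 3 * se
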