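"""Synthetic generator, experiment arithmetic and dataset splitting."""

import numpy as np
import pytest

import dynmst
from dynmst import (CouplingGraph, SynthConfig, chain_graph, experiment_counts,
                    generate_dataset, load_epochs, save_epochs, split_dataset,
                    star_graph)
from dynmst.synth import validation_study_config


def tiny_config(**kw):
    base = dict(n_subjects=2, trials_per_condition_per_subject=3, n_channels=4,
                band_plan={"alpha": (8.0, 12.0)}, conditions=("face", "ketch"),
                seed=1)
    base.update(kw)
    return SynthConfig(**base)


class TestCouplingGraph:
    def test_rejects_self_edges_duplicates_zero_lag(self):
        with pytest.raises(ValueError):
            CouplingGraph(3, ((0, 0, 1.0, 1.0),))
        with pytest.raises(ValueError):
            CouplingGraph(3, ((0, 1, 1.0, 1.0), (1, 0, 0.5, 1.0)))
        with pytest.raises(ValueError):
            CouplingGraph(3, ((0, 1, 0.0, 1.0),))
        with pytest.raises(ValueError):
            CouplingGraph(3, ((0, 1, 1.0, 1.5),))

    def test_star_and_chain_builders(self):
        s = star_graph(5, hub=2)
        assert len(s.edges) == 4
        assert all(i == 2 for i, _, _, _ in s.edges)
        c = chain_graph(5)
        assert [(i, j) for i, j, _, _ in c.edges] == \
            [(0, 1), (1, 2), (2, 3), (3, 4)]


class TestSynthConfig:
    def test_epoch_span_must_straddle_onset(self):
        with pytest.raises(ValueError):
            tiny_config(epoch_span=(100.0, 800.0))

    def test_plan_window_outside_analysis_span_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(coupling_plan={
                ("face", "alpha", 6): star_graph(4)})

    def test_plan_graph_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(coupling_plan={("face", "alpha", 2): star_graph(5)})

    def test_plan_band_must_exist(self):
        with pytest.raises(ValueError):
            tiny_config(coupling_plan={("face", "theta", 2): star_graph(4)})


class TestGenerateDataset:
    def test_shape_bookkeeping(self):
        ep = generate_dataset(tiny_config())
        assert ep.data.shape == (12, 4, 1000)
        assert ep.time_zero_index == 200
        assert sorted(set(ep.condition)) == ["face", "ketch"]
        assert np.sum(ep.condition == "face") == 6
        assert len(set(ep.subject)) == 2

    def test_same_seed_bit_identical(self):
        a = generate_dataset(tiny_config())
        b = generate_dataset(tiny_config())
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = generate_dataset(tiny_config())
        b = generate_dataset(tiny_config(seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_planted_lag_expressed_in_window(self):
        # strong star coupling: hub-spoke phase difference inside the
        # planted window concentrates at the requested quarter-cycle lag
        from dynmst.connectivity import instantaneous_phase
        cfg = tiny_config(
            n_channels=4, trials_per_condition_per_subject=10,
            band_plan={"gamma": (31.0, 46.0)}, conditions=("face",),
            coupling_plan={("face", "gamma", 2):
                           star_graph(4, hub=0, lag=np.pi / 2,
                                      alternate=False)},
            coupling_strength=1.0, noise_sd=0.0, edge_phase_jitter=0.0)
        ep = generate_dataset(cfg)
        ph = instantaneous_phase(ep.data)
        d = np.angle(np.exp(1j * (ph[:, 0, 310:390] - ph[:, 1, 310:390])))
        assert np.abs(np.median(d) - np.pi / 2) < 0.2

    def test_labels_use_standard_montage(self):
        ep = generate_dataset(tiny_config())
        assert ep.channel_labels == ["Fp1", "Fz", "F3", "F7"]

    def test_validation_study_config_plan(self):
        cfg = validation_study_config(trials_per_condition=5, seed=3)
        assert set(b for _, b, _ in cfg.coupling_plan) == {"beta", "gamma"}
        assert set(w for _, _, w in cfg.coupling_plan) == {2, 3}
        ep = generate_dataset(cfg)
        assert ep.n_trials == 15


class TestExperimentCounts:
    @pytest.mark.parametrize("args,expected", [
        ((28, 48, 6), 8064),
        ((1, 1, 1), 1),
        ((1, 16, 18), 288),
    ])
    def test_products(self, args, expected):
        assert experiment_counts(*args) == expected

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            experiment_counts(0, 48, 6)


class TestSplitDataset:
    @staticmethod
    def label_epochs(n_per, conditions=("face", "ketch", "scrambled")):
        n = n_per * len(conditions)
        return dynmst.EpochSet(
            data=np.zeros((n, 2, 10)), sample_rate=1000.0, time_zero_index=2,
            channel_labels=["a", "b"],
            condition=np.repeat(conditions, n_per),
            subject=np.repeat("S01", n))

    def test_seventy_thirty_split_counts(self):
        ep = self.label_epochs(7665)
        first, second = split_dataset(ep, 0.7, seed=0)
        for cond in ("face", "ketch", "scrambled"):
            assert np.sum(first.condition == cond) == 5366
            assert np.sum(second.condition == cond) == 2299

    def test_half_split_disjoint_exhaustive(self):
        ep = self.label_epochs(10, conditions=("a", "b"))
        ep.subject = np.arange(20).astype(str)  # unique trial tags
        first, second = split_dataset(ep, 0.5, seed=1)
        assert np.sum(first.condition == "a") == 5
        assert np.sum(second.condition == "a") == 5
        assert set(first.subject) | set(second.subject) == set(ep.subject)
        assert set(first.subject) & set(second.subject) == set()

    def test_reproducible_under_seed(self):
        ep = self.label_epochs(20)
        a1, _ = split_dataset(ep, 0.7, seed=9)
        a2, _ = split_dataset(ep, 0.7, seed=9)
        np.testing.assert_array_equal(a1.condition, a2.condition)

    def test_tiny_condition_rejected(self):
        ep = self.label_epochs(1)
        with pytest.raises(ValueError):
            split_dataset(ep, 0.5, seed=0)

    def test_fraction_bounds(self):
        ep = self.label_epochs(10)
        with pytest.raises(ValueError):
            split_dataset(ep, 1.0, seed=0)


class TestEpochArchive:
    def test_roundtrip(self, tmp_path, rng):
        ep = generate_dataset(tiny_config())
        save_epochs(ep, tmp_path / "arch")
        back = load_epochs(tmp_path / "arch")
        np.testing.assert_array_equal(back.data, ep.data)
        np.testing.assert_array_equal(back.condition, ep.condition)
        assert back.channel_labels == ep.channel_labels
        assert back.sample_rate == ep.sample_rate
        assert (tmp_path / "arch" / "manifest.csv").exists()

    def test_epochset_invariants(self):
        with pytest.raises(ValueError):
            dynmst.EpochSet(data=np.full((1, 2, 10), np.nan), sample_rate=1e3,
                            time_zero_index=2, channel_labels=["a", "b"],
                            condition=np.array(["x"]),
                            subject=np.array(["s"]))
        with pytest.raises(ValueError):
            dynmst.EpochSet(data=np.zeros((1, 2, 10)), sample_rate=1e3,
                            time_zero_index=99, channel_labels=["a", "b"],
                            condition=np.array(["x"]),
                            subject=np.array(["s"]))
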