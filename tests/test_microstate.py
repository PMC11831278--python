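"""GFP, peak extraction, modified k-means, back-fitting, canonical
labeling, and the 17 per-epoch parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microband as mb
from microband.containers import Epoch
from microband.microstate import (MicrostateModel, assign_canonical_labels,
                                  backfit, compute_gfp, compute_parameters,
                                  epoch_features, exhaustive_kmeans_gev,
                                  extract_peak_maps, find_gfp_peaks,
                                  modified_kmeans)


def _unit(v):
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    return v / np.linalg.norm(v)


class TestGfp:
    def test_closed_forms(self):
        assert compute_gfp(np.array([[1.0], [-1.0], [1.0], [-1.0]]))[0] == \
            pytest.approx(1.0)
        assert compute_gfp(np.array([[2.0], [0.0], [0.0], [-2.0]]))[0] == \
            pytest.approx(np.sqrt(2.0))

    def test_zero_map(self):
        assert compute_gfp(np.zeros((5, 3)))[1] == 0.0


class TestGfpPeaks:
    def test_enumerated_example(self):
        assert find_gfp_peaks(np.array([0, 1, 0, 2, 0.0])).tolist() == [1, 3]

    def test_plateau_takes_first_sample(self):
        assert find_gfp_peaks(np.array([0, 1, 1, 0.0])).tolist() == [1]

    def test_monotone_has_no_peaks(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_endpoints_excluded(self):
        assert find_gfp_peaks(np.array([5, 1, 4.0])).size == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_gfp_peaks(np.array([1.0, 2.0]))


class TestExtractPeakMaps:
    def test_per_subject_cap(self):
        rng = np.random.default_rng(0)
        eps = [Epoch(data=rng.normal(size=(4, 500)), fs=250.0, band="all",
                     subject=s, group="HC", condition="resting", trial=0,
                     ch_names=("a", "b", "c", "d"))
               for s in ("S01", "S02")]
        full = extract_peak_maps(eps, cap_per_subject=10 ** 6, seed=0)
        capped = extract_peak_maps(eps, cap_per_subject=50, seed=0)
        assert full.shape[0] > 100
        assert capped.shape[0] == 100
        assert capped.shape[1] == 4

    def test_maps_are_average_referenced(self):
        rng = np.random.default_rng(1)
        ep = Epoch(data=rng.normal(size=(4, 300)) + 5.0, fs=250.0,
                   band="all", subject="S01", group="HC",
                   condition="resting", trial=0, ch_names=("a", "b", "c", "d"))
        maps = extract_peak_maps([ep])
        assert np.abs(maps.mean(axis=1)).max() < 1e-12


class TestModifiedKmeans:
    def test_two_polarity_pairs_perfect_gev(self):
        u = _unit([1, 0, -1, 0, 0])
        w = _unit([0, 1, 0, -1, 0])
        maps = np.stack([u, -u, w, -w, u, w]) * \
            np.array([1, 2, 3, 1, 2, 1.0])[:, None]
        model = modified_kmeans(maps, k=2, n_restarts=5, seed=0)
        assert model.training_gev == pytest.approx(1.0, abs=1e-12)
        # recovered templates span {u, w} up to sign
        cos = np.abs(model.templates @ np.stack([u, w]).T)
        assert np.allclose(np.sort(cos.max(axis=1)), [1.0, 1.0], atol=1e-9)

    def test_k_equals_n_maps_perfect_gev(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(3, 6))
        maps -= maps.mean(axis=1, keepdims=True)
        model = modified_kmeans(maps, k=3, n_restarts=20, seed=1)
        assert model.training_gev == pytest.approx(1.0, abs=1e-9)

    def test_matches_small_oracle(self):
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(7, 4))
        maps -= maps.mean(axis=1, keepdims=True)
        best = exhaustive_kmeans_gev(maps, k=2)
        model = modified_kmeans(maps, k=2, n_restarts=20, seed=3)
        assert model.training_gev >= best - 1e-9
        assert model.training_gev <= best + 1e-9

    def test_gev_history_monotone(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(size=(200, 8))
        maps -= maps.mean(axis=1, keepdims=True)
        model = modified_kmeans(maps, k=4, n_restarts=3, seed=2)
        hist = np.asarray(model.gev_history)
        assert np.all(np.diff(hist) >= -1e-12)

    def test_templates_centered_unit_norm(self):
        rng = np.random.default_rng(11)
        maps = rng.normal(size=(100, 6))
        maps -= maps.mean(axis=1, keepdims=True)
        model = modified_kmeans(maps, k=4, n_restarts=3, seed=0)
        assert np.abs(model.templates.mean(axis=1)).max() < 1e-9
        assert np.abs(np.linalg.norm(model.templates, axis=1) - 1).max() \
            < 1e-12

    def test_seeded_determinism(self):
        rng = np.random.default_rng(13)
        maps = rng.normal(size=(150, 6))
        maps -= maps.mean(axis=1, keepdims=True)
        a = modified_kmeans(maps, k=4, n_restarts=5, seed=8)
        b = modified_kmeans(maps, k=4, n_restarts=5, seed=8)
        assert np.array_equal(a.templates, b.templates)
        assert a.training_gev == b.training_gev


class TestBackfit:
    def _model(self):
        t = np.stack([_unit([1, 0, -1, 0]), _unit([0, 1, 0, -1]),
                      _unit([1, -1, 1, -1]), _unit([3, 1, -1, -3])])
        return MicrostateModel(templates=t, training_gev=1.0,
                               labels=("A", "B", "C", "D"))

    def test_templates_fit_themselves(self):
        model = self._model()
        seg = backfit(model.templates.T.copy(), model)
        assert seg.labels.tolist() == [0, 1, 2, 3]
        assert np.allclose(seg.fit_corr, 1.0)
        assert np.all(seg.polarity == 1)

    def test_polarity_invariance(self):
        model = self._model()
        data = np.column_stack([model.templates[0], -model.templates[0]])
        seg = backfit(data, model)
        assert seg.labels.tolist() == [0, 0]
        assert seg.polarity.tolist() == [1, -1]

    def test_zero_sample_inherits_previous_label(self):
        model = self._model()
        data = np.column_stack([model.templates[1],
                                np.zeros(4), model.templates[2]])
        seg = backfit(data, model)
        assert seg.labels.tolist() == [1, 1, 2]
        assert seg.fit_corr[1] == 0.0

    def test_leading_zero_backfilled(self):
        model = self._model()
        data = np.column_stack([np.zeros(4), model.templates[3]])
        seg = backfit(data, model)
        assert seg.labels.tolist() == [3, 3]

    def test_min_duration_smoothing_removes_short_run(self):
        model = self._model()
        cols = [model.templates[0]] * 5 + [model.templates[1]] + \
            [model.templates[0]] * 5
        seg = backfit(np.column_stack(cols), model, smooth_min_samples=2)
        assert np.all(seg.labels == 0)

    def test_smooth_ms_requires_fs(self):
        model = self._model()
        with pytest.raises(ValueError):
            backfit(model.templates.T.copy(), model, smooth_min_ms=30.0)


class TestCanonicalLabels:
    def test_recovers_shuffled_signed_templates(self, templates31):
        rng = np.random.default_rng(3)
        perm = rng.permutation(4)
        signs = np.array([1, -1, -1, 1.0])
        shuffled = templates31.maps[perm] * signs[:, None]
        model = MicrostateModel(templates=shuffled, training_gev=0.9)
        out = assign_canonical_labels(model, templates31)
        assert out.labels == ("A", "B", "C", "D")
        cos = np.abs(np.einsum("ij,ij->i", out.templates, templates31.maps))
        assert np.all(cos > 1 - 1e-9)

    def test_perturbed_templates_still_matched(self, templates31):
        rng = np.random.default_rng(4)
        noisy = templates31.maps[::-1] + 0.1 * rng.normal(size=(4, 31))
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        model = MicrostateModel(templates=noisy, training_gev=0.9)
        out = assign_canonical_labels(model, templates31)
        cos = np.abs(out.templates @ templates31.maps.T)
        # each reordered template is closest to its own canonical map
        assert np.array_equal(np.argmax(cos, axis=1), np.arange(4))

    def test_requires_four_templates(self, templates31):
        model = MicrostateModel(templates=templates31.maps[:3],
                                training_gev=0.9)
        with pytest.raises(ValueError):
            assign_canonical_labels(model, templates31)


class TestParameters:
    def test_hand_enumerated_example(self):
        """labels A,A,A,B,A,A at 250 Hz: coverage_A = 5/6,
        duration_A = 10 ms, occurrence_A = 83.33/s."""
        labels = np.array([0, 0, 0, 1, 0, 0])
        fit = np.ones(6)
        gfp = np.ones(6)
        p = compute_parameters(labels, fit, gfp, fs=250.0)
        assert p["coverage_A"] == pytest.approx(5 / 6)
        assert p["duration_A"] == pytest.approx(10.0)
        assert p["occurrence_A"] == pytest.approx(2 / (6 / 250))
        assert p["coverage_B"] == pytest.approx(1 / 6)
        assert p["duration_B"] == pytest.approx(4.0)
        assert p["duration_C"] == 0.0
        assert p["occurrence_C"] == 0.0

    def test_identity_holds_exactly(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            labels = rng.integers(0, 4, 500)
            fit = rng.uniform(0, 1, 500)
            gfp = rng.uniform(0, 2, 500)
            p = compute_parameters(labels, fit, gfp, fs=250.0)
            for cls in "ABCD":
                lhs = p[f"coverage_{cls}"]
                rhs = p[f"occurrence_{cls}"] * p[f"duration_{cls}"] / 1000.0
                assert abs(lhs - rhs) < 1e-12

    def test_seventeen_values(self):
        p = compute_parameters(np.zeros(10, dtype=int), np.ones(10),
                               np.ones(10), fs=250.0)
        assert len(p) == 17
        assert p["gev_total"] == pytest.approx(
            p["gev_A"] + p["gev_B"] + p["gev_C"] + p["gev_D"])

    def test_gev_total_bounded_by_one(self):
        rng = np.random.default_rng(19)
        labels = rng.integers(0, 4, 300)
        fit = rng.uniform(0, 1, 300)
        gfp = rng.uniform(0, 2, 300)
        p = compute_parameters(labels, fit, gfp, fs=250.0)
        assert 0.0 <= p["gev_total"] <= 1.0

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=200),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_identity_property(self, label_list, seed):
        """coverage = occurrence x duration / 1000 for arbitrary label
        sequences and positive GFP/fit values."""
        labels = np.asarray(label_list)
        rng = np.random.default_rng(seed)
        fit = rng.uniform(0, 1, labels.size)
        gfp = rng.uniform(0, 2, labels.size)
        p = compute_parameters(labels, fit, gfp, fs=250.0)
        for cls in "ABCD":
            lhs = p[f"coverage_{cls}"]
            rhs = p[f"occurrence_{cls}"] * p[f"duration_{cls}"] / 1000.0
            assert abs(lhs - rhs) < 1e-12
        assert abs(sum(p[f"coverage_{c}"] for c in "ABCD") - 1.0) < 1e-12

    def test_zero_gfp_denominator(self):
        p = compute_parameters(np.zeros(5, dtype=int), np.ones(5),
                               np.zeros(5), fs=250.0)
        assert p["gev_total"] == 0.0


class TestEpochFeatures:
    def test_sign_and_permutation_invariance(self, templates31, true_model):
        """Flipping template polarity or epoch sign leaves every
        parameter unchanged; permuting templates permutes class names."""
        spec = mb.DynamicsSpec(snr=5.0)
        lab = mb.sample_state_sequence(spec, 2.0, 250.0, 31)
        v = mb.synthesize_epoch(lab, templates31, spec, 250.0, 32)
        ep = Epoch(data=v, fs=250.0, band="all", subject="s", group="HC",
                   condition="resting", trial=0,
                   ch_names=tuple(f"c{i}" for i in range(31)))
        base = epoch_features(ep, true_model)

        flipped = MicrostateModel(templates=-true_model.templates,
                                  training_gev=1.0,
                                  labels=true_model.labels)
        assert epoch_features(ep, flipped) == pytest.approx(base)

        neg = ep.copy_with(data=-ep.data)
        assert epoch_features(neg, true_model) == pytest.approx(base)

        perm = [2, 3, 0, 1]
        permuted = MicrostateModel(
            templates=true_model.templates[perm], training_gev=1.0,
            labels=("A", "B", "C", "D"))
        swapped = epoch_features(ep, permuted)
        assert swapped["coverage_A"] == pytest.approx(base["coverage_C"])
        assert swapped["duration_D"] == pytest.approx(base["duration_B"])
        assert swapped["gev_total"] == pytest.approx(base["gev_total"])

    def test_metadata_and_count(self, templates31, true_model):
        ep = Epoch(data=np.random.default_rng(0).normal(size=(31, 100)),
                   fs=250.0, band="alpha", subject="MUD03", group="MUD",
                   condition="drug", trial=7,
                   ch_names=tuple(f"c{i}" for i in range(31)))
        row = epoch_features(ep, true_model)
        assert row["subject"] == "MUD03" and row["band"] == "alpha"
        assert row["trial"] == 7
        assert len(row) == 5 + 17


class TestModelIo:
    def test_json_round_trip(self, tmp_path, layout31, templates31):
        model = MicrostateModel(templates=templates31.maps,
                                training_gev=0.77,
                                labels=("A", "B", "C", "D"),
                                ch_names=tuple(layout31.names))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MicrostateModel.from_json(path)
        assert np.allclose(back.templates, model.templates)
        assert back.training_gev == pytest.approx(0.77)
        assert back.labels == model.labels
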