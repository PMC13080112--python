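"""Generator unit and property tests: templates, label statistics, rendering,
cohort assembly."""

import numpy as np
import pytest

from mstate_mci.montage import canonical_maps, spherical_montage
from mstate_mci.synth import (
    GroupSpec,
    default_group_specs,
    embedded_stationary,
    expected_occupancy,
    make_cohort,
    make_templates,
    render_eeg,
    sample_moca,
    simulate_feature_table,
    simulate_label_sequence,
    _uniform_rows,
)
from tests.conftest import make_spec


class TestMontage:
    def test_positions_on_unit_sphere_with_unique_names(self, montage62):
        norms = np.linalg.norm(montage62.positions, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert len(set(montage62.channel_names)) == 62

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            spherical_montage(3)

    def test_canonical_maps_are_car_unit_norm_and_distinct(self, montage62):
        maps = canonical_maps(montage62.positions)
        assert np.allclose(maps.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-9)
        corr = maps @ maps.T
        off = np.abs(corr - np.diag(np.diag(corr)))
        assert off.max() < 0.8


class TestTemplates:
    def test_car_consistent_and_unit_norm(self, montage62):
        t = make_templates(montage62, k=4, seed=1)
        assert t.shape == (4, 62)
        assert np.allclose(t.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, montage62):
        a = make_templates(montage62, k=4, seed=1)
        b = make_templates(montage62, k=4, seed=1)
        assert np.array_equal(a, b)

    def test_different_seeds_give_different_maps(self, montage62):
        a = make_templates(montage62, k=4, seed=1)
        b = make_templates(montage62, k=4, seed=2)
        for m in range(4):
            assert abs(float(a[m] @ b[m])) < 1.0 - 1e-6

    def test_pairwise_correlation_bounded(self, montage62):
        for seed in range(5):
            t = make_templates(montage62, k=4, seed=seed)
            corr = t @ t.T
            off = np.abs(corr - np.diag(np.diag(corr)))
            assert off.max() < 0.8

    def test_more_templates_than_channels_rejected(self, montage16):
        with pytest.raises(ValueError):
            make_templates(montage16, k=17, seed=0)


class TestLabelSequences:
    def test_support_restricted_to_reachable_states(self):
        # A <-> B only
        P = np.zeros((4, 4))
        P[0, 1] = 1.0
        P[1, 0] = 1.0
        P[2, 0] = 1.0
        P[3, 0] = 1.0
        spec = GroupSpec(
            group_label="HC",
            n_subjects=1,
            transition_matrix=P,
            mean_durations_ms=np.full(4, 20.0),
        )
        labels = simulate_label_sequence(spec, 10.0, 250.0, seed=0)
        # the embedded stationary start already lives on {A, B}
        assert set(np.unique(labels)) <= {0, 1}

    def test_deterministic_given_seed(self, hc_spec):
        a = simulate_label_sequence(hc_spec, 5.0, 250.0, seed=7)
        b = simulate_label_sequence(hc_spec, 5.0, 250.0, seed=7)
        assert np.array_equal(a, b)

    def test_mean_run_length_matches_generator(self):
        spec = make_spec(durations=(20.0, 20.0, 20.0, 20.0), subject_cv=0.0)
        labels = simulate_label_sequence(spec, 600.0, 250.0, seed=3)
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        runs_a = (ends - starts)[labels[starts] == 0] / 250.0 * 1000.0
        assert runs_a.mean() == pytest.approx(20.0, abs=2.0)

    def test_degenerate_transition_row_rejected(self):
        P = _uniform_rows()
        P[2] = 0.0
        with pytest.raises(ValueError):
            GroupSpec(
                group_label="HC",
                n_subjects=1,
                transition_matrix=P,
                mean_durations_ms=np.full(4, 20.0),
            )

    def test_transition_frequencies_converge_to_spec(self, mci_spec):
        labels = simulate_label_sequence(mci_spec, 3600.0, 250.0, seed=5)
        change = np.flatnonzero(np.diff(labels)) + 1
        runs = labels[np.concatenate([[0], change])]
        counts = np.zeros((4, 4))
        for a, b in zip(runs[:-1], runs[1:]):
            counts[a, b] += 1
        tp = counts / counts.sum(axis=1, keepdims=True)
        # subject-level jitter is part of the draw; compare to the jittered spec
        assert np.abs(tp - mci_spec.transition_matrix).max() < 0.03 + 0.05

    def test_occupancy_matches_stationary_prediction(self):
        spec = make_spec(into=[1, 1, 1, 0.6], subject_cv=0.0)
        labels = simulate_label_sequence(spec, 3600.0, 250.0, seed=11)
        occ = np.bincount(labels, minlength=4) / labels.size
        target = expected_occupancy(spec.transition_matrix, spec.mean_durations_ms)
        assert np.abs(occ - target).max() < 0.03

    def test_stationary_vector_sums_to_one(self, mci_spec):
        pi = embedded_stationary(mci_spec.transition_matrix)
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi >= 0)


class TestRendering:
    def test_deterministic_given_seed(self, hc_spec, montage16):
        t = make_templates(montage16, k=4, seed=0)
        labels = simulate_label_sequence(hc_spec, 2.0, 250.0, seed=0)
        a = render_eeg(labels, t, snr=5.0, fs=250.0, seed=9)
        b = render_eeg(labels, t, snr=5.0, fs=250.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_output_is_average_referenced(self, hc_spec, montage16):
        t = make_templates(montage16, k=4, seed=0)
        labels = simulate_label_sequence(hc_spec, 2.0, 250.0, seed=0)
        rec = render_eeg(labels, t, snr=5.0, fs=250.0, seed=1)
        assert np.allclose(rec.data.mean(axis=0), 0.0, atol=1e-9)

    def test_noise_scaled_to_requested_snr(self, hc_spec, montage16):
        t = make_templates(montage16, k=4, seed=0)
        labels = simulate_label_sequence(hc_spec, 20.0, 250.0, seed=0)
        clean = render_eeg(labels, t, snr=np.inf, fs=250.0, seed=2)
        noisy = render_eeg(labels, t, snr=5.0, fs=250.0, seed=2)
        noise = noisy.data - clean.data
        ratio = np.sqrt(np.mean(clean.data**2)) / np.sqrt(np.mean(noise**2))
        assert ratio == pytest.approx(5.0, rel=1e-6)

    def test_noiseless_backfit_reproduces_labels_exactly(self, hc_spec, montage16):
        from mstate_mci.microstate import MicrostateModel, backfit

        t = make_templates(montage16, k=4, seed=0)
        labels = simulate_label_sequence(hc_spec, 4.0, 250.0, seed=0)
        rec = render_eeg(labels, t, snr=np.inf, fs=250.0, seed=3)
        model = MicrostateModel(
            templates=t, class_labels=("A", "B", "C", "D"), gev=1.0, n_restarts=1
        )
        recovered, flags = backfit(rec, model)
        assert np.array_equal(recovered, labels)
        assert not flags.any()


class TestCohort:
    def test_default_cohort_sizes(self):
        cohort = make_cohort(seed=0, paradigms=("rest",), rest_duration_s=20.0)
        assert cohort.n_subjects == 63
        groups = [s.group for s in cohort.subjects]
        assert groups.count("MCI") == 32 and groups.count("HC") == 31

    def test_single_subject_per_group(self, hc_spec, mci_spec, montage16):
        cohort = make_cohort(
            hc=hc_spec, mci=mci_spec, montage=montage16, seed=0,
            rest_duration_s=4.0, n_incongruent=5, n_congruent=5,
        )
        assert cohort.n_subjects == 8  # n_subjects from the specs (4 + 4)
        _, rest, task, events = next(cohort.iter_recordings())
        assert rest.paradigm == "rest" and task.paradigm == "task"
        assert (events["condition"] == "incongruent").sum() == 5

    def test_moca_group_means(self, hc_spec, rng):
        draws = sample_moca(hc_spec, 1000, rng)
        assert draws.mean() == pytest.approx(hc_spec.moca_mean, abs=0.5)
        assert np.all((draws >= 0) & (draws <= 30))

    def test_cohort_reproducible_from_seed(self, hc_spec, mci_spec, montage16):
        a = make_cohort(hc=hc_spec, mci=mci_spec, montage=montage16, seed=4,
                        rest_duration_s=4.0, n_incongruent=3, n_congruent=3)
        b = make_cohort(hc=hc_spec, mci=mci_spec, montage=montage16, seed=4,
                        rest_duration_s=4.0, n_incongruent=3, n_congruent=3)
        sid = a.subjects[0].subject_id
        assert np.array_equal(
            a.ground_truth.label_sequences[(sid, "rest")],
            b.ground_truth.label_sequences[(sid, "rest")],
        )
        assert np.array_equal(a.rest_recording(sid).data, b.rest_recording(sid).data)

    def test_task_recording_time_locked_and_eventful(self, hc_spec, mci_spec, montage16):
        cohort = make_cohort(hc=hc_spec, mci=mci_spec, montage=montage16, seed=2,
                             rest_duration_s=4.0, n_incongruent=4, n_congruent=4)
        sid = cohort.subjects[0].subject_id
        rec, events = cohort.task_recording(sid)
        assert len(events) == 8
        assert rec.n_samples == 8 * int(1.2 * 250)


class TestFeatureTableShortcut:
    def test_shape_and_determinism(self, hc_spec, mci_spec):
        a = simulate_feature_table(hc_spec, mci_spec, n_segments=3, segment_s=5.0, seed=1)
        b = simulate_feature_table(hc_spec, mci_spec, n_segments=3, segment_s=5.0, seed=1)
        assert a.shape == b.shape and a.equals(b)
        assert len(a) == (4 + 4) * 3
        feature_cols = [c for c in a.columns if c not in ("subject_id", "segment_id", "group")]
        assert len(feature_cols) == 26
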