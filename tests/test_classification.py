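"""Spectral flatness, event detection, type criteria, cohort summaries."""

import numpy as np
import pytest
from scipy.signal import welch

from wingstroke.classification import (ClassificationThresholds, OccurrenceTable,
                                       classify_component, classify_decomposition,
                                       compare_pca, detect_events, repeatability,
                                       subsample_batches, tally_occurrence,
                                       welch_spectrum, wiener_entropy)
from wingstroke.dependence import shuffle_null

from conftest import summed_activation


def _context(n=2500, seed=0, P=8):
    """Neutral classification context: flat vectors, uncorrelated series."""
    r = np.random.default_rng(seed)
    baseline = np.cos(2 * np.pi * np.arange(2 * P) / P) * 70
    return dict(period=5e-3 + 1e-5 * r.standard_normal(n),
                ratio=1.5 + 0.01 * r.standard_normal(n),
                scaled_vector=np.full(2 * P, 1 / np.sqrt(2 * P)),
                mixing_column=np.ones(2 * P),
                baseline=baseline,
                points_per_wing=P)


class TestWienerEntropy:
    def test_white_noise_flat(self):
        r = np.random.default_rng(0)
        assert wiener_entropy(r.standard_normal(2500)) > 0.9

    def test_sinusoid_peaked(self):
        z = np.sin(2 * np.pi * 0.05 * np.arange(2500))
        assert wiener_entropy(z) < 0.1

    def test_ar1_matches_theoretical_spectrum_oracle(self):
        """Empirical flatness of an AR(1) tracks the closed-form spectrum."""
        a = 0.9
        # oracle: evaluate the theoretical AR(1) density on the Welch bins
        f = np.fft.rfftfreq(256)[1:]
        S = 1.0 / (1 - 2 * a * np.cos(2 * np.pi * f) + a * a)
        oracle = np.exp(np.mean(np.log(S))) / np.mean(S)
        vals = []
        for s in range(3):
            r = np.random.default_rng(s)
            z = np.empty(4096)
            acc = 0.0
            innov = r.standard_normal(4096)
            for i in range(4096):
                acc = a * acc + innov[i]
                z[i] = acc
            vals.append(wiener_entropy(z))
        assert abs(np.mean(vals) - oracle) < 0.05

    def test_invariant_to_amplitude_scaling(self):
        r = np.random.default_rng(1)
        z = np.cumsum(r.standard_normal(2500))
        assert abs(wiener_entropy(z) - wiener_entropy(z * 1234.5)) < 1e-12

    def test_constant_series_flagged_zero(self):
        assert welch_spectrum(np.ones(2500)).wiener_entropy == 0.0

    def test_bounded_between_zero_and_one(self):
        for s in range(5):
            r = np.random.default_rng(s)
            z = np.cumsum(r.standard_normal(1000))
            assert 0.0 <= wiener_entropy(z) <= 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            wiener_entropy(np.zeros(100))


class TestDetectEvents:
    def test_plain_noise_has_no_events(self):
        r = np.random.default_rng(2)
        assert detect_events(r.standard_normal(2500)) == []

    def test_injected_event_onset_and_duration(self):
        # plateaued event with short raised-cosine ramps, like the generator's
        r = np.random.default_rng(3)
        z = r.standard_normal(2500)
        env = np.ones(60)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, 6) / 6))
        env[:5], env[-5:] = ramp, ramp[::-1]
        z[500:560] += 8 * env
        events = detect_events(z)
        assert len(events) == 1
        onset, dur, pol = events[0]
        assert abs(onset - 500) <= 10
        assert 40 <= dur <= 100
        assert pol == 1

    def test_two_separated_events_detected_separately(self):
        r = np.random.default_rng(4)
        z = r.standard_normal(2500)
        for c in (400, 600):
            z[c:c + 50] -= 8 * np.hanning(50)
        events = detect_events(z)
        assert len(events) == 2
        assert all(pol == -1 for _, _, pol in events)

    def test_nearby_runs_merged(self):
        r = np.random.default_rng(5)
        z = r.standard_normal(1000)
        z[300:330] += 9
        z[332:360] += 9
        assert len(detect_events(z)) == 1


class TestClassifyComponent:
    def test_shuffled_noise_labelled_noise(self):
        r = np.random.default_rng(6)
        lab = classify_component(r.standard_normal(2500), **_context())
        assert lab.primary == "noise"
        assert lab.labels == ("noise",)

    def test_period_two_alternation_labelled_vi(self):
        r = np.random.default_rng(7)
        z = 0.3 * r.standard_normal(2500)
        for onset in (500, 1500):
            z[onset:onset + 120] += 3 * (-1.0) ** np.arange(120)
        lab = classify_component(z, **_context())
        assert lab.primary == "VI"

    def test_slow_periodic_modulation_labelled_vii(self):
        r = np.random.default_rng(8)
        z = np.sin(2 * np.pi * np.arange(2500) / 50) + 0.3 * r.standard_normal(2500)
        lab = classify_component(z, **_context())
        assert lab.primary == "VII"

    def test_dorsal_difference_vector_labelled_iv(self):
        r = np.random.default_rng(9)
        ctx = _context()
        v = np.zeros(16)
        v[0], v[8] = 0.7, -0.7
        v[3] = 0.1
        ctx["scaled_vector"] = v / np.linalg.norm(v)
        z = np.empty(2500)
        acc = 0.0
        innov = r.standard_normal(2500)
        for i in range(2500):
            acc = 0.7 * acc + innov[i]
            z[i] = acc
        lab = classify_component(z, **ctx)
        assert "IV" in lab.labels

    def test_missing_context_rejected(self):
        ctx = _context()
        ctx["period"] = None
        with pytest.raises(ValueError):
            classify_component(np.zeros(2500), **ctx)

    def test_classification_deterministic(self, two_pattern_run,
                                          two_pattern_decomposition):
        l1 = classify_decomposition(two_pattern_decomposition,
                                    two_pattern_run.segment.signals,
                                    two_pattern_run.features)
        l2 = classify_decomposition(two_pattern_decomposition,
                                    two_pattern_run.segment.signals,
                                    two_pattern_run.features)
        assert [a.primary for a in l1] == [b.primary for b in l2]

    def test_noise_label_exclusive_of_types(self, two_pattern_run,
                                            two_pattern_decomposition):
        labels = classify_decomposition(two_pattern_decomposition,
                                        two_pattern_run.segment.signals,
                                        two_pattern_run.features)
        for lab in labels:
            if "noise" in lab.labels:
                assert lab.labels == ("noise",)
            assert (lab.wiener_entropy > 0.9) == (lab.primary == "noise")

    def test_injected_types_recovered(self, two_pattern_run,
                                      two_pattern_decomposition):
        dec = two_pattern_decomposition
        labels = classify_decomposition(dec, two_pattern_run.segment.signals,
                                        two_pattern_run.features)
        for ptype in ("I", "II"):
            gt = summed_activation(two_pattern_run, ptype)
            best = int(np.argmax([abs(np.corrcoef(dec.Z[i], gt)[0, 1])
                                  for i in range(16)]))
            assert labels[best].primary == ptype


class TestOccurrence:
    def _grid(self, counts, n_flies=10):
        labels = {}
        for f in range(n_flies):
            present = {t for t, c in counts.items() if f < c}
            labels[f"fly{f}"] = [present]
        return labels

    def test_three_of_ten_is_frequent(self):
        table = tally_occurrence(self._grid({"I": 3}))
        assert table.frequent[table.types.index("I")]

    def test_absent_type_not_frequent(self):
        table = tally_occurrence(self._grid({"I": 3}))
        assert not table.frequent[table.types.index("II")]

    def test_two_of_eight_is_frequent_under_quarter_rule(self):
        table = tally_occurrence(self._grid({"III": 2}, n_flies=8))
        assert table.frequent[table.types.index("III")]
        table7 = tally_occurrence(self._grid({"III": 1}, n_flies=8))
        assert not table7.frequent[table7.types.index("III")]


class TestSubsampleBatches:
    def test_identical_flies_give_constant_count(self):
        labels = {f"fly{f}": [{"I", "II"}] for f in range(10)}
        table = tally_occurrence(labels)
        out = subsample_batches(table, [5, 10], n_draws=200, seed=0)
        assert np.all(out[5] == 2) and np.all(out[10] == 2)

    def test_empty_grid_gives_zero_counts(self):
        labels = {f"fly{f}": [set()] for f in range(10)}
        table = tally_occurrence(labels)
        out = subsample_batches(table, [6], n_draws=100, seed=0)
        assert np.all(out[6] == 0)

    def test_modal_count_matches_exhaustive_enumeration_on_toy_grid(self):
        """Small grid: bootstrap mode equals the exact enumeration mode."""
        rng = np.random.default_rng(5)
        presence = rng.random((4, 7)) < 0.6
        table = OccurrenceTable(flies=[f"f{i}" for i in range(4)],
                                types=tuple("ABCDEFG"), presence=presence,
                                counts=presence.sum(axis=0),
                                frequent=presence.sum(axis=0) >= 1)
        size = 2
        # exhaustive enumeration over all 4^2 ordered draws
        counts = []
        need = OccurrenceTable.required(size)
        for i in range(4):
            for j in range(4):
                counts.append(int((presence[[i, j]].sum(axis=0) >= need).sum()))
        exact_mode = np.bincount(counts).argmax()
        boot = subsample_batches(table, [size], n_draws=4000, seed=1)[size]
        assert np.bincount(boot).argmax() == exact_mode


class TestRepeatability:
    def test_identical_segments_share_all_types(self):
        out = repeatability({"fly": [{"I", "II"}, {"I", "II"}]})
        assert out["fly"] == (2.0, 2, 2)

    def test_disjoint_segments_share_none(self):
        out = repeatability({"fly": [{"I"}, {"II"}]})
        assert out["fly"] == (0.0, 0, 0)

    def test_three_segment_toy(self):
        out = repeatability({"fly": [{"I", "II"}, {"II", "III"}, {"I", "III"}]})
        assert out["fly"] == (1.0, 1, 1)


class TestComparePCA:
    def test_components_uncorrelated(self, two_pattern_run):
        pcs, _ = compare_pca(two_pattern_run.segment.signals)
        C = np.corrcoef(pcs)
        off = C[~np.eye(16, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_pca_leaves_more_dependence_than_ldc(self, two_pattern_run,
                                                 two_pattern_decomposition):
        """The decorrelated-only transform keeps more significant MI pairs
        than the MI-minimizing one."""
        from wingstroke.dependence import pairwise_mi_matrix
        pcs, pca_mi = compare_pca(two_pattern_run.segment.signals)
        ldc_mi = pairwise_mi_matrix(two_pattern_decomposition)
        null = shuffle_null(two_pattern_decomposition, 600, seed=9)
        frac_pca = np.mean(pca_mi.offdiagonal() > null.threshold)
        frac_ldc = np.mean(ldc_mi.offdiagonal() > null.threshold)
        assert frac_pca >= frac_ldc
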