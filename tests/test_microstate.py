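"""GFP, clustering, template ordering, backfitting and metrics."""

import itertools

import numpy as np
import pytest

from msretest import (
    MicrostateSequence,
    MicrostateTemplates,
    ParameterError,
    Recording,
    TopographySet,
    aahc,
    backfit,
    canonical_templates,
    gfp_curve,
    gfp_peaks,
    make_templates,
    metrics,
    order_templates,
    spatial_corr,
    standard_positions,
    two_level_templates,
)


def _rec_from_maps(maps, seg_samples, rate=250.0, amp=10.0, noise=0.0, rng=None):
    """Piecewise-constant topography recording: maps[i] held for
    seg_samples[i] samples, amplitude-modulated so the GFP curve has
    strict local maxima at every other sample."""
    cols = []
    for i, ns in enumerate(seg_samples):
        cols.append(np.tile(maps[i % len(maps)][:, None], (1, ns)))
    data = np.concatenate(cols, axis=1)
    n = data.shape[1]
    envelope = amp * (2.0 + np.sin(2 * np.pi * (rate / 4) * np.arange(n) / rate
                                   + 0.3))
    data = data * envelope[None, :]
    if noise and rng is not None:
        data = data + rng.normal(0, noise, size=data.shape)
    names, _ = standard_positions(data.shape[0])
    return Recording(data=data, rate=rate, ch_names=names)


class TestGfp:
    def test_equal_channels_give_zero(self):
        rec = Recording(data=np.ones((4, 10)), rate=100.0,
                        ch_names=list("abcd"))
        np.testing.assert_allclose(gfp_curve(rec), 0.0, atol=1e-12)

    def test_two_channel_closed_form(self):
        rec = Recording(data=np.array([[1.0], [-1.0]]), rate=100.0,
                        ch_names=["a", "b"])
        assert gfp_curve(rec)[0] == pytest.approx(1.0)

    def test_homogeneous_scaling(self, rng):
        data = rng.normal(size=(5, 50))
        rec = Recording(data=data, rate=100.0, ch_names=list("abcde"))
        rec3 = Recording(data=-3 * data, rate=100.0, ch_names=list("abcde"))
        np.testing.assert_allclose(gfp_curve(rec3), 3 * gfp_curve(rec), atol=1e-12)


class TestGfpPeaks:
    def test_rectified_sine_peak_positions(self):
        rate = 250.0
        t = np.arange(int(rate * 2)) / rate
        envelope = np.abs(np.sin(2 * np.pi * 10 * t))
        data = np.vstack([envelope, -envelope])
        rec = Recording(data=data, rate=rate, ch_names=["a", "b"])
        # |sin| extrema at odd multiples of a quarter 10 Hz cycle
        peaks_expected = [k * rate / 10 / 4 for k in range(1, 80, 2)]
        topos = gfp_peaks(rec)
        g = gfp_curve(rec)
        found = np.where((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:]))[0] + 1
        for p in found:
            assert min(abs(p - e) for e in peaks_expected) <= 1

    def test_monotone_gfp_errors(self):
        data = np.vstack([np.arange(100.0), -np.arange(100.0)])
        rec = Recording(data=data, rate=100.0, ch_names=["a", "b"])
        with pytest.raises(ParameterError, match="peaks"):
            gfp_peaks(rec)

    def test_peak_maps_match_generating_templates(self, synth_recording):
        rec, truth = synth_recording
        topos = gfp_peaks(rec)
        g = gfp_curve(rec)
        peak_idx = np.where((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:]))[0] + 1
        ok = 0
        for m, i in zip(topos.maps, peak_idx):
            true_map = truth.template_maps[truth.state_labels[i]]
            if spatial_corr(m, true_map) > 0.9:
                ok += 1
        assert ok / topos.n_maps >= 0.9


class TestAahc:
    def test_perfectly_separable_recovery(self, rng):
        protos = make_templates(16, 4, seed=1)
        maps = np.repeat(protos, 10, axis=0)
        topos = TopographySet(maps=maps, gfp=np.ones(len(maps)))
        tmpl = aahc(topos, 4)
        for p in protos:
            assert max(spatial_corr(p, m) for m in tmpl.maps) > 0.999

    def test_polarity_invariance(self, rng):
        protos = make_templates(16, 4, seed=2)
        maps = np.repeat(protos, 8, axis=0) + 0.05 * rng.normal(size=(32, 16))
        flip = rng.choice([-1.0, 1.0], size=len(maps))
        a = aahc(TopographySet(maps=maps, gfp=np.ones(len(maps))), 4)
        b = aahc(TopographySet(maps=maps * flip[:, None], gfp=np.ones(len(maps))), 4)
        for ma, mb in zip(a.maps, b.maps):
            assert spatial_corr(ma, mb) > 0.999

    def test_small_instance_near_optimal_gev(self, rng):
        """M = 8 maps, C = 4 channels, k = 2: the AAHC partition's GEV is
        within 5% of the best 2-partition found by exhaustive search."""
        protos = rng.normal(size=(2, 4))
        maps = np.repeat(protos, 4, axis=0) + 0.4 * rng.normal(size=(8, 4))
        maps *= rng.choice([-1.0, 1.0], size=8)[:, None]
        maps -= maps.mean(axis=1, keepdims=True)
        gfp = maps.std(axis=1)
        topos = TopographySet(maps=maps, gfp=gfp)

        def gev_of_partition(groups):
            total = 0.0
            for g in groups:
                if not g:
                    continue
                sub = maps[list(g)]
                u = sub / np.linalg.norm(sub, axis=1, keepdims=True)
                S = u.T @ u
                vals, vecs = np.linalg.eigh(S)
                p = vecs[:, -1]
                corr = u @ p
                total += np.sum((gfp[list(g)] * np.abs(corr)) ** 2)
            return total / np.sum(gfp ** 2)

        best = 0.0
        for assignment in itertools.product([0, 1], repeat=8):
            if len(set(assignment)) < 2:
                continue
            groups = [[i for i in range(8) if assignment[i] == s] for s in (0, 1)]
            best = max(best, gev_of_partition(groups))

        tmpl = aahc(topos, 2)
        # recompute GEV of the AAHC clustering by reassigning maps
        corr = np.abs((maps / np.linalg.norm(maps, axis=1, keepdims=True))
                      @ (tmpl.maps / np.linalg.norm(tmpl.maps, axis=1, keepdims=True)).T)
        assign = np.argmax(corr, axis=1)
        groups = [[i for i in range(8) if assign[i] == s] for s in (0, 1)]
        got = gev_of_partition(groups)
        assert got >= 0.95 * best

    def test_too_few_maps_error(self, rng):
        topos = TopographySet(maps=rng.normal(size=(3, 8)), gfp=np.ones(3))
        with pytest.raises(ParameterError):
            aahc(topos, 4)


class TestTwoLevel:
    def test_shared_generators_recovered(self, rng):
        protos = make_templates(16, 4, seed=3)
        subjects = []
        for s in range(4):
            maps = np.repeat(protos, 12, axis=0) + 0.1 * rng.normal(size=(48, 16))
            subjects.append(TopographySet(maps=maps, gfp=np.ones(48)))
        result = two_level_templates(subjects, k_subject_range=[4], k_group_range=[4])
        group = result[4]
        for p in protos:
            assert max(spatial_corr(p, m) for m in group.maps) > 0.99

    def test_single_subject_passthrough(self, rng):
        protos = make_templates(16, 4, seed=4)
        maps = np.repeat(protos, 10, axis=0)
        topos = TopographySet(maps=maps, gfp=np.ones(40))
        subj = aahc(topos, 4)
        group = two_level_templates([topos], k_subject_range=[4], k_group_range=[4])[4]
        for m in subj.maps:
            assert max(spatial_corr(m, g) for g in group.maps) > 0.999

    def test_excess_group_k_still_recovers_generators(self, rng):
        protos = make_templates(16, 4, seed=5)
        subjects = []
        for s in range(4):
            maps = np.repeat(protos, 12, axis=0) + 0.1 * rng.normal(size=(48, 16))
            subjects.append(TopographySet(maps=maps, gfp=np.ones(48)))
        group = two_level_templates(subjects, k_subject_range=[4], k_group_range=[5])[5]
        assert group.k == 5
        hits = sum(max(spatial_corr(p, m) for m in group.maps) > 0.95 for p in protos)
        assert hits == 4


class TestOrderTemplates:
    def test_shuffled_identity_recovered(self):
        canon = canonical_templates(standard_positions(16)[1])
        perm = [2, 0, 3, 1]
        shuffled = MicrostateTemplates(maps=canon.maps[perm], labels=list("WXYZ"))
        ordered = order_templates(shuffled, canon)
        assert ordered.labels == ["A", "B", "C", "D"]
        for lab, m in zip(ordered.labels, ordered.maps):
            ref = canon.maps[canon.labels.index(lab)]
            assert spatial_corr(m, ref) > 0.999

    def test_sign_flips_ignored(self):
        canon = canonical_templates(standard_positions(16)[1])
        flipped = MicrostateTemplates(maps=canon.maps * np.array([-1, 1, -1, 1])[:, None],
                                      labels=list("WXYZ"))
        ordered = order_templates(flipped, canon)
        assert ordered.labels == ["A", "B", "C", "D"]

    def test_hungarian_matches_brute_force(self, rng):
        canon = canonical_templates(standard_positions(16)[1])
        tmpl = MicrostateTemplates(maps=make_templates(16, 4, seed=6),
                                   labels=list("WXYZ"))
        corr = np.array([[spatial_corr(a, b) for b in canon.maps] for a in tmpl.maps])
        best_perm, best_sum = None, -1
        for perm in itertools.permutations(range(4)):
            s = sum(corr[i, perm[i]] for i in range(4))
            if s > best_sum:
                best_sum, best_perm = s, perm
        ordered = order_templates(tmpl, canon)
        expected = {i: canon.labels[best_perm[i]] for i in range(4)}
        got = {}
        for lab, m in zip(ordered.labels, ordered.maps):
            for i in range(4):
                if np.allclose(m, tmpl.maps[i]):
                    got[i] = lab
        assert got == expected


class TestSpatialCorr:
    def test_self_is_one(self, rng):
        m = rng.normal(size=16)
        assert spatial_corr(m, m) == pytest.approx(1.0)

    def test_negation_ignored(self, rng):
        m = rng.normal(size=16)
        assert spatial_corr(m, -m) == pytest.approx(1.0)
        assert spatial_corr(m, -m, ignore_polarity=False) == pytest.approx(-1.0)

    def test_orthogonal_maps_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert spatial_corr(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ParameterError):
            spatial_corr(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestBackfit:
    def test_noise_free_boundary_exact(self):
        maps = make_templates(16, 4, seed=7)
        # B for 100 ms then A for 100 ms at 250 Hz
        rec = _rec_from_maps([maps[1], maps[0]], [25, 25])
        tmpl = MicrostateTemplates(maps=maps, labels=list("ABCD"))
        seq = backfit(rec, tmpl, smooth_window_ms=0)
        assert np.all(seq.labels[:24] == 1)
        assert np.all(seq.labels[26:] == 0)

    def test_polarity_flip_invariant(self, synth_recording):
        rec, truth = synth_recording
        tmpl = MicrostateTemplates(maps=truth.template_maps, labels=list("ABCD"))
        seq = backfit(rec, tmpl)
        flipped = rec.with_data(-rec.data, "flip")
        seq2 = backfit(flipped, tmpl)
        np.testing.assert_array_equal(seq.labels, seq2.labels)

    def test_short_spurious_segment_absorbed(self):
        maps = make_templates(16, 4, seed=8)
        # long A, 8 ms of B, long A again (8 ms = 2 samples at 250 Hz)
        rec = _rec_from_maps([maps[0], maps[1], maps[0]], [50, 2, 50])
        tmpl = MicrostateTemplates(maps=maps, labels=list("ABCD"))
        seq = backfit(rec, tmpl, smooth_window_ms=20, penalty=1.0)
        assert np.all(seq.labels == 0)

    def test_metrics_recover_generative_coverage(self, synth_recording):
        rec, truth = synth_recording
        tmpl = MicrostateTemplates(maps=truth.template_maps, labels=list("ABCD"))
        seq = backfit(rec, tmpl)
        m = metrics(seq)
        true_cov = np.array([np.mean(truth.state_labels == k) * 100 for k in range(4)])
        np.testing.assert_allclose(m.coverage_pct, true_cov, atol=10.0)


class TestMetrics:
    def test_worked_example(self):
        """A 25-sample sequence A*5 B*10 A*5 C*5 at 250 Hz has closed-form
        duration/occurrence/coverage/transition values."""
        labels = np.array([0] * 5 + [1] * 10 + [0] * 5 + [2] * 5)
        seq = MicrostateSequence(labels=labels, rate=250.0,
                                 gfp=np.ones(25), fit=np.ones(25), k=3)
        m = metrics(seq, labels=list("ABC"))
        assert m.duration_ms[0] == pytest.approx(20.0)
        assert m.duration_ms[1] == pytest.approx(40.0)
        assert m.duration_ms[2] == pytest.approx(20.0)
        assert m.occurrence_hz[0] == pytest.approx(20.0)
        assert m.coverage_pct.tolist() == pytest.approx([40.0, 40.0, 20.0])
        assert m.transition[0, 1] == pytest.approx(0.5)
        assert m.transition[0, 2] == pytest.approx(0.5)
        assert m.transition[1, 0] == pytest.approx(1.0)

    def test_single_label_sequence(self):
        seq = MicrostateSequence(labels=np.zeros(100, dtype=int), rate=250.0,
                                 gfp=np.ones(100), fit=np.ones(100), k=4)
        m = metrics(seq)
        assert m.coverage_pct[0] == pytest.approx(100.0)
        np.testing.assert_allclose(m.transition, 0.0)

    def test_four_templates_give_three_transitions_each(self, synth_recording):
        rec, truth = synth_recording
        tmpl = MicrostateTemplates(maps=truth.template_maps, labels=list("ABCD"))
        m = metrics(backfit(rec, tmpl))
        for k in range(4):
            off_diag = np.delete(m.transition[k], k)
            assert len(off_diag) == 3
            assert np.sum(off_diag) == pytest.approx(1.0)

    def test_coverage_sums_to_100_and_consistency(self, synth_recording):
        rec, truth = synth_recording
        tmpl = MicrostateTemplates(maps=truth.template_maps, labels=list("ABCD"))
        m = metrics(backfit(rec, tmpl))
        assert np.sum(m.coverage_pct) == pytest.approx(100.0, abs=1e-6)
        # coverage fraction = duration * occurrence per type (fully assigned)
        np.testing.assert_allclose(m.coverage_pct / 100.0,
                                   m.duration_ms / 1000.0 * m.occurrence_hz,
                                   rtol=1e-6)

    def test_whole_recording_sign_flip_changes_no_metric(self, synth_recording):
        rec, truth = synth_recording
        tmpl = MicrostateTemplates(maps=truth.template_maps, labels=list("ABCD"))
        m1 = metrics(backfit(rec, tmpl))
        m2 = metrics(backfit(rec.with_data(-rec.data, "flip"), tmpl))
        np.testing.assert_allclose(m1.duration_ms, m2.duration_ms)
        np.testing.assert_allclose(m1.transition, m2.transition)
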