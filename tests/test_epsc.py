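"""Tests for sEPSC detection, raw matching, PAM clustering and labeling."""

import numpy as np
import pandas as pd
import pytest

from fibsinet.epsc import (
    epsc_feature_matrix,
    detect_epscs,
    label_clusters,
    lowpass_filter,
    match_filtered_to_raw,
    pam_cluster,
    select_k_silhouette,
)
from fibsinet.fibsi import Trace


def sine_trace(freq, fs=2000.0, dur=2.0, amp=1.0):
    t = np.arange(0.0, dur, 1.0 / fs)
    return Trace("s", t, amp * np.sin(2 * np.pi * freq * t), modality="current")


class TestLowpass:
    def test_constant_trace_unchanged(self):
        t = np.arange(0.0, 1.0, 5e-4)
        tr = Trace("c", t, np.full_like(t, 7.0), modality="current")
        assert np.allclose(lowpass_filter(tr, 200.0).y, 7.0, atol=1e-9)

    def test_stopband_attenuation_over_20_db(self):
        out = lowpass_filter(sine_trace(900.0), 200.0)
        mid = out.y[500:-500]
        assert np.abs(mid).max() < 0.1  # > 20 dB down

    def test_passband_within_one_percent(self):
        out = lowpass_filter(sine_trace(1.0), 200.0)
        assert np.abs(out.y).max() == pytest.approx(1.0, rel=0.01)

    def test_zero_phase_keeps_peak_time(self):
        fs = 2000.0
        t = np.arange(0.0, 1.0, 1.0 / fs)
        y = np.exp(-0.5 * ((t - 0.5) / 0.01) ** 2)
        out = lowpass_filter(Trace("g", t, y, modality="current"), 200.0)
        assert abs(t[np.argmax(out.y)] - 0.5) < 2.0 / fs

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(sine_trace(10.0), 1000.0)


class TestDetectEpscs:
    def test_pure_noise_below_epsilon_is_empty(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 10.0, 5e-4)
        tr = Trace("n", t, rng.normal(0, 2.0, len(t)), modality="current")
        out = detect_epscs(lowpass_filter(tr))
        assert len(out) == 0

    def test_single_planted_event_peak_within_2_ms(self):
        from fibsinet.synthetic import biexp_kernel

        rng = np.random.default_rng(1)
        fs = 2000.0
        t = np.arange(0.0, 30.0, 1.0 / fs)
        y = rng.normal(0, 2.0, len(t))
        j = int(12.0 * fs)
        kern = biexp_kernel(np.arange(200) / fs, 1e-3, 7.5e-3)
        y[j:j + 200] -= 50.0 * kern
        out = detect_epscs(lowpass_filter(Trace("e", t, y, modality="current")))
        assert len(out) == 1
        t_peak_true = 12.0 + 1e-3 * 7.5 / 6.5 * np.log(7.5)
        assert abs(out.t_peak.iloc[0] - t_peak_true) < 2e-3

    def test_poisson_train_count_within_3_sigma(self, epsc_recording):
        params, trace, truth = epsc_recording
        out = detect_epscs(lowpass_filter(trace))
        n = len(truth.events)
        assert abs(len(out) - n) < 3 * np.sqrt(n)

    def test_calcium_modality_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError):
            detect_epscs(Trace("c", t, np.zeros(100), modality="calcium"))

    def test_iei_peak_to_peak(self, epsc_recording):
        _, trace, _ = epsc_recording
        out = detect_epscs(lowpass_filter(trace))
        assert np.isnan(out.iei_ms.iloc[0])
        got = out.iei_ms.iloc[1:].to_numpy()
        expect = np.diff(out.t_peak.to_numpy()) * 1000.0
        assert np.allclose(got, expect)


class TestMatchFilteredToRaw:
    def test_raw_equals_filtered_matches_all(self, epsc_recording):
        _, trace, _ = epsc_recording
        filt = lowpass_filter(trace)
        ev = detect_epscs(filt)
        out = match_filtered_to_raw(ev, trace)
        assert out.matched.mean() > 0.95

    def test_matched_amplitudes_recover_planted_within_noise(self, epsc_recording):
        _, trace, truth = epsc_recording
        ev = match_filtered_to_raw(detect_epscs(lowpass_filter(trace)), trace)
        tt = truth.events.event_time_s.to_numpy()
        amp = truth.events.amplitude.to_numpy()
        det = ev.t_peak.to_numpy()
        j = np.abs(det[:, None] - tt[None, :]).argmin(axis=1)
        ok = np.abs(det - tt[j]) < 0.01
        err = ev.amplitude_pA.to_numpy()[ok] - amp[j][ok]
        assert abs(np.median(err)) < 5.0

    def test_competing_events_earlier_wins(self):
        # two filtered "events" pointing at the same raw peak
        fs = 2000.0
        t = np.arange(0.0, 2.0, 1.0 / fs)
        y = np.zeros_like(t)
        y[2000] = -50.0
        raw = Trace("r", t, y, modality="current")
        ev = pd.DataFrame({"t_peak": [0.9995, 1.0005],
                           "amplitude_pA": [10.0, 11.0], "matched": True})
        from fibsinet.fibsi import ReferencePolyline

        ref = ReferencePolyline(np.array([0.0, 2.0]), np.zeros(2))
        out = match_filtered_to_raw(ev, raw, tolerance_ms=5.0, reference=ref)
        assert bool(out.matched.iloc[0]) is True
        assert bool(out.matched.iloc[1]) is False
        assert out.amplitude_pA.iloc[0] == pytest.approx(50.0)
        assert out.amplitude_pA.iloc[1] == 11.0  # filtered amplitude retained


class TestPam:
    def test_two_point_masses_split_perfectly(self):
        X = np.vstack([np.tile([0.0, 0.0, 0.0], (10, 1)),
                       np.tile([100.0, 50.0, 10.0], (10, 1))])
        m = pam_cluster(X, 2)
        assert len(set(m.assignments[:10])) == 1
        assert len(set(m.assignments[10:])) == 1
        assert m.assignments[0] != m.assignments[10]
        assert m.avg_silhouette == pytest.approx(1.0)

    def test_exhaustive_optimum_in_1d(self):
        # PAM is a local search: every solution must be a single-swap local
        # optimum, and on small 1-D problems it should almost always reach
        # the exhaustive-search global optimum.
        from itertools import combinations

        rng = np.random.default_rng(2)
        global_hits = 0
        for _ in range(10):
            X = rng.uniform(0, 100, size=(12, 1))
            m = pam_cluster(X, 2)
            D = np.abs(X[:, 0][:, None] - X[:, 0][None, :])
            best = min(D[:, list(pair)].min(axis=1).sum()
                       for pair in combinations(range(12), 2))
            global_hits += abs(m.objective - best) < 1e-9
            meds = list(m.medoid_indices)
            for mi in range(2):
                for c in range(12):
                    if c in meds:
                        continue
                    trial = meds.copy()
                    trial[mi] = c
                    assert D[:, trial].min(axis=1).sum() >= m.objective - 1e-9
        assert global_hits >= 8

    def test_matches_reference_r_implementation(self, tmp_path):
        # independent oracle: cluster::pam (default settings, manhattan)
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal([20, 15, 150], [4, 3, 30], (30, 3)),
                       rng.normal([2000, 15, 150], [400, 3, 30], (30, 3)),
                       rng.normal([200, 80, 800], [40, 16, 160], (30, 3))])
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = (
            'x <- as.matrix(read.csv("{}", header=FALSE));'
            'p <- cluster::pam(x, 3, metric="manhattan");'
            'cat(p$objective["swap"] * nrow(x), "\\n");'
            'cat(p$clustering, "\\n")'
        ).format(tmp_path / "X.csv")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.splitlines()
        r_objective = float(out[0].strip())
        r_assign = np.array(out[1].split(), dtype=int)
        m = pam_cluster(X, 3)
        assert m.objective == pytest.approx(r_objective, rel=1e-6)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(r_assign, m.assignments) == pytest.approx(1.0)

    def test_k_equals_n_zero_objective(self):
        X = np.arange(12.0).reshape(6, 2)
        m = pam_cluster(X, 6)
        assert m.objective == 0.0

    def test_objective_never_increases_under_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        m1 = pam_cluster(X, 3)
        perm = rng.permutation(40)
        m2 = pam_cluster(X[perm], 3)
        assert m1.objective == pytest.approx(m2.objective)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((3, 2)), 5)


class TestSelectK:
    def planted(self, rng, centers, n=40):
        return np.vstack([rng.normal(c, np.abs(np.asarray(c)) * 0.05 + 0.5,
                                     size=(n, len(c))) for c in centers])

    def test_three_separated_components_select_k3(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = self.planted(rng, [[20, 15, 150], [2000, 15, 150], [200, 80, 800]])
            hits += select_k_silhouette(X).k == 3
        assert hits >= 9

    def test_two_components_select_k2(self):
        rng = np.random.default_rng(11)
        X = self.planted(rng, [[20, 15, 150], [2000, 15, 150]])
        assert select_k_silhouette(X).k == 2

    def test_silhouette_bounded(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        m = select_k_silhouette(X)
        assert all(-1.0 <= v <= 1.0 for v in m.silhouette_profile.values())

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError):
            select_k_silhouette(np.zeros((20, 3)))


class TestLabelClusters:
    def model_for(self, X, k):
        return pam_cluster(X, k)

    def test_three_cluster_naming_rule(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal([15, 10, 50], 0.5, (10, 3)),
                       rng.normal([900, 12, 60], 0.5, (10, 3)),
                       rng.normal([40, 80, 500], 0.5, (10, 3))])
        m = label_clusters(self.model_for(X, 3), X)
        by_label = {v: m.medoid_indices[k] for k, v in m.labels.items()}
        assert set(by_label) == {"small;short", "small;long", "large"}
        assert by_label["large"] >= 20
        assert by_label["small;short"] < 10
        assert 10 <= by_label["small;long"] < 20

    def test_k2_labels_small_and_large(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal([100, 10, 80], 0.5, (10, 3)),
                       rng.normal([100, 80, 700], 0.5, (10, 3))])
        m = label_clusters(self.model_for(X, 2), X)
        assert set(m.labels.values()) == {"small", "large"}

    def test_close_amplitudes_demote_large_to_medium(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal([20, 50, 400], 0.5, (10, 3)),
                       rng.normal([900, 60, 500], 0.5, (10, 3))])
        m = label_clusters(self.model_for(X, 2), X)
        assert "medium" in m.labels.values()

    def test_planted_component_labels_recovered_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        from fibsinet.pipeline import epsc_pipeline
        from fibsinet.synthetic import EpscParams, generate_epsc_recording

        aris = []
        for seed in (3, 4):
            trace, truth = generate_epsc_recording(EpscParams(seed=seed))
            ev, model = epsc_pipeline(trace)
            X, idx = epsc_feature_matrix(ev)
            det = ev.loc[idx, "t_peak"].to_numpy()
            tt = truth.events.event_time_s.to_numpy()
            j = np.abs(det[:, None] - tt[None, :]).argmin(axis=1)
            ok = np.abs(det - tt[j]) < 0.01
            truth_lab = truth.events.cluster_id.to_numpy()[j][ok]
            aris.append(adjusted_rand_score(truth_lab, model.assignments[ok]))
        assert min(aris) >= 0.9

    def test_clustering_is_per_cell_independent(self, epsc_recording):
        # clustering a cell twice with other data present/absent is identical
        _, trace, _ = epsc_recording
        from fibsinet.pipeline import epsc_pipeline

        ev1, m1 = epsc_pipeline(trace)
        ev2, m2 = epsc_pipeline(trace)
        assert m1.k == m2.k
        assert np.array_equal(m1.assignments, m2.assignments)
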