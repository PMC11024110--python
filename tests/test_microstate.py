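import numpy as np
import pytest

from aad.microstate import (GFPSeries, backfit, compute_gev, compute_gfp,
                            find_gfp_peaks, fit_prototypes,
                            microstate_features, scan_n_states)
from aad.synthetic import make_templates

from conftest import make_window


class TestGFP:
    @pytest.mark.parametrize("topography,expected", [
        ([2.0, 2.0, 2.0], 0.0),
        ([1.0, -1.0], 1.0),
        ([2.0, 0.0, -2.0, 0.0], np.sqrt(2.0)),
    ])
    def test_hand_computed_topographies(self, topography, expected):
        w = make_window(np.array(topography)[:, None].repeat(4, axis=1))
        np.testing.assert_allclose(compute_gfp(w).values, expected, atol=1e-15)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 50))
        got = compute_gfp(make_window(data)).values
        for t in range(50):
            x = data[:, t]
            naive = np.sqrt(np.sum((x - x.mean()) ** 2) / len(x))
            assert abs(got[t] - naive) <= 1e-12 * max(naive, 1.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            compute_gfp(make_window(np.ones((1, 10))))


class TestPeaks:
    def test_simple_maxima(self):
        gfp = GFPSeries(values=np.array([0.0, 1, 0, 2, 0]), sfreq=1000.0)
        np.testing.assert_array_equal(find_gfp_peaks(gfp, 1.0), [1, 3])

    def test_monotone_has_none(self):
        gfp = GFPSeries(values=np.arange(10.0), sfreq=1000.0)
        assert len(find_gfp_peaks(gfp)) == 0

    def test_matches_bruteforce_neighbor_scan(self):
        rng = np.random.default_rng(5)
        v = np.abs(np.sin(np.linspace(0, 20, 500)) + 0.3 * rng.standard_normal(500))
        gfp = GFPSeries(values=v, sfreq=1000.0)
        got = find_gfp_peaks(gfp, min_distance_ms=1.0)
        brute = [i for i in range(1, 499) if v[i] > v[i - 1] and v[i] > v[i + 1]]
        np.testing.assert_array_equal(got, brute)

    def test_endpoints_never_returned(self):
        gfp = GFPSeries(values=np.array([5.0, 1, 2, 1, 5]), sfreq=1000.0)
        peaks = find_gfp_peaks(gfp)
        assert 0 not in peaks and 4 not in peaks


def _planted_peak_maps(K=4, n_channels=8, n_per=30, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    templates = make_templates(K, n_channels, seed=seed)
    idx = np.tile(np.arange(K), n_per)
    signs = rng.choice([-1.0, 1.0], size=len(idx))
    maps = templates[idx] * signs[:, None] * rng.uniform(1, 3, len(idx))[:, None]
    if noise:
        maps = maps + noise * rng.standard_normal(maps.shape)
    return maps, templates, idx


class TestFitPrototypes:
    @pytest.mark.parametrize("method", ["KMEANS", "AAHC", "PCA", "ICA"])
    def test_unit_norm_and_shape(self, method):
        maps, _, _ = _planted_peak_maps(noise=0.2)
        protos = fit_prototypes(maps, 4, method=method, n_init=3, seed=0)
        assert protos.maps.shape == (4, 8)
        np.testing.assert_allclose(np.linalg.norm(protos.maps, axis=1), 1.0,
                                   atol=1e-9)

    def test_noiseless_recovery_up_to_sign_and_permutation(self):
        maps, templates, _ = _planted_peak_maps(noise=0.0)
        protos = fit_prototypes(maps, 4, "KMEANS", n_init=5, seed=1)
        # every template matched by exactly one prototype with |corr| ~ 1
        sim = np.abs(templates @ protos.maps.T)
        assert (sim.max(axis=1) > 1 - 1e-9).all()
        assert len(set(sim.argmax(axis=1))) == 4
        assert protos.gev_total > 1 - 1e-9

    def test_k1_is_dominant_eigvec(self):
        maps, _, _ = _planted_peak_maps(noise=0.3, seed=2)
        protos = fit_prototypes(maps, 1, "KMEANS", n_init=2, seed=0)
        centered = maps - maps.mean(axis=1, keepdims=True)
        norm = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        _, vecs = np.linalg.eigh(norm.T @ norm)
        lead = vecs[:, -1]
        assert abs(abs(protos.maps[0] @ lead) - 1) < 1e-9

    def test_deterministic_given_seed(self):
        maps, _, _ = _planted_peak_maps(noise=0.2)
        a = fit_prototypes(maps, 4, "KMEANS", n_init=3, seed=9)
        b = fit_prototypes(maps, 4, "KMEANS", n_init=3, seed=9)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_bad_K_rejected(self):
        maps, _, _ = _planted_peak_maps()
        with pytest.raises(ValueError):
            fit_prototypes(maps, 0, "KMEANS")
        with pytest.raises(ValueError):
            fit_prototypes(maps, len(maps) + 1, "KMEANS")


class TestBackfitAndGEV:
    def test_exact_prototype_gets_label_and_polarity(self):
        templates = make_templates(3, 8, seed=0)
        protos = fit_prototypes(templates * 2.0, 3, "KMEANS", n_init=2, seed=0)
        # find which prototype corresponds to template 2
        sim = np.abs(templates @ protos.maps.T)
        k = int(sim[2].argmax())
        seg = backfit(templates[2][:, None] * 5.0, protos, sfreq=100.0)
        assert seg.labels[0] == k
        sign = np.sign(templates[2] @ protos.maps[k])
        assert seg.polarity[0] == sign
        seg_neg = backfit(-templates[2][:, None], protos, sfreq=100.0)
        assert seg_neg.labels[0] == k
        assert seg_neg.polarity[0] == -sign

    def test_global_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 40))
        protos = fit_prototypes(rng.standard_normal((20, 8)), 4, "KMEANS",
                                n_init=2, seed=0)
        a = backfit(data, protos, sfreq=100.0)
        b = backfit(-data, protos, sfreq=100.0)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.polarity, -b.polarity)

    def test_gev_one_for_scaled_prototypes(self):
        protos = fit_prototypes(make_templates(4, 8, seed=1), 4, "KMEANS",
                                n_init=2, seed=0)
        rng = np.random.default_rng(0)
        idx = rng.integers(4, size=60)
        scale = rng.uniform(0.5, 4.0, 60)
        data = (protos.maps[idx] * scale[:, None]).T
        seg = backfit(data, protos, sfreq=100.0)
        assert compute_gev(data, protos, seg) == pytest.approx(1.0, abs=1e-12)

    def test_gev_zero_for_orthogonal_assignment(self):
        basis = make_templates(4, 8, seed=2)
        protos = fit_prototypes(basis[:2] * 3.0, 2, "KMEANS", n_init=2, seed=0)
        # data built from the *other* two orthogonal maps
        data = basis[2:].T @ np.ones((2, 30)) * 0  # start at zero
        rng = np.random.default_rng(1)
        coef = rng.standard_normal((2, 30))
        data = basis[2:].T @ coef
        seg = backfit(data, protos, sfreq=100.0)
        assert compute_gev(data, protos, seg) == pytest.approx(0.0, abs=1e-18)

    def test_gev_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((8, 50))
        protos = fit_prototypes(rng.standard_normal((30, 8)), 4, "KMEANS",
                                n_init=2, seed=0)
        seg = backfit(data, protos, sfreq=100.0)
        num = den = 0.0
        for t in range(50):
            x = data[:, t]
            gfp = x.std()
            m = protos.maps[seg.labels[t]]
            c = np.corrcoef(x, m)[0, 1]
            num += gfp ** 2 * c ** 2
            den += gfp ** 2
        assert compute_gev(data, protos, seg) == pytest.approx(num / den, rel=1e-10)

    def test_all_zero_window_rejected(self):
        protos = fit_prototypes(make_templates(2, 4, seed=0), 2, "KMEANS",
                                n_init=2, seed=0)
        seg = backfit(np.zeros((4, 10)) + 1e-30, protos, sfreq=100.0)
        with pytest.raises(ValueError):
            compute_gev(np.zeros((4, 10)), protos, seg)

    def test_planted_sequence_recovered_at_snr10(self, small_recording):
        rec, truth, spec = small_recording
        protos = fit_prototypes(truth["templates"], spec.K, "KMEANS",
                                n_init=2, seed=0)
        seg = backfit(rec.data, protos, sfreq=rec.sfreq)
        from scipy.optimize import linear_sum_assignment

        conf = np.zeros((spec.K, spec.K))
        for a, b in zip(truth["state_labels"], seg.labels):
            conf[a, b] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(seg.labels) >= 0.95


class TestScan:
    def test_single_cell_table(self):
        maps, _, _ = _planted_peak_maps(noise=0.1)
        res = scan_n_states(maps, maps.T, sfreq=100.0, K_range=[2],
                            methods=("KMEANS",), n_init=2, n_reruns=2, seed=0)
        assert set(res["gev"]["KMEANS"]) == {2}
        assert res["best_K"]["KMEANS"] == 2

    def test_planted_K_reaches_high_gev(self):
        maps, _, _ = _planted_peak_maps(n_per=40, noise=0.05, seed=4)
        res = scan_n_states(maps, maps.T, sfreq=100.0, K_range=range(2, 7),
                            methods=("KMEANS",), n_init=3, n_reruns=3, seed=0)
        gev = res["gev"]["KMEANS"]
        assert gev[4] >= 0.95
        # marginal gain collapses after the planted K
        assert gev[4] - gev[3] > 5 * max(gev[5] - gev[4], 1e-12)


class TestFeatures:
    def _seg(self, labels, sfreq=10.0):
        labels = np.asarray(labels)
        from aad.microstate import MicrostateSegmentation

        return MicrostateSegmentation(labels=labels,
                                      polarity=np.ones_like(labels), sfreq=sfreq)

    def test_two_block_window(self):
        seg = self._seg([0] * 5 + [1] * 5)
        gfp = GFPSeries(values=np.ones(10), sfreq=10.0)
        f = microstate_features(seg, gfp)
        assert f.coverage[0] == pytest.approx(0.5)
        assert f.occurrence[0] == pytest.approx(1.0)
        assert f.duration[0] == pytest.approx(500.0)

    def test_alternating_window(self):
        seg = self._seg([0, 1] * 5)
        gfp = GFPSeries(values=np.ones(10), sfreq=10.0)
        f = microstate_features(seg, gfp)
        assert f.occurrence[0] == pytest.approx(5.0)
        assert f.duration[0] == pytest.approx(100.0)
        assert f.coverage[0] == pytest.approx(0.5)

    def test_absent_state_zeroed(self):
        seg = self._seg([0, 0, 0, 0])
        gfp = GFPSeries(values=np.ones(4), sfreq=10.0)
        f = microstate_features(seg, gfp, K=3)
        assert f.coverage[2] == 0 and f.occurrence[2] == 0 and f.duration[2] == 0

    def test_coverage_occurrence_duration_consistency(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 4, size=200)
        seg = self._seg(labels, sfreq=100.0)
        gfp = GFPSeries(values=rng.uniform(1, 2, 200), sfreq=100.0)
        f = microstate_features(seg, gfp)
        assert f.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        # run-length enumeration oracle
        runs = {}
        start = 0
        for i in range(1, 201):
            if i == 200 or labels[i] != labels[start]:
                runs.setdefault(labels[start], []).append(i - start)
                start = i
        for k, lens in runs.items():
            assert f.occurrence[k] == pytest.approx(len(lens) / 2.0)
            assert f.duration[k] == pytest.approx(np.mean(lens) * 10.0)
            assert f.coverage[k] == pytest.approx(sum(lens) / 200)
            # coverage == occurrence * duration / 1000 (all runs interior or not)
            assert f.coverage[k] == pytest.approx(
                f.occurrence[k] * f.duration[k] / 1000.0)
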