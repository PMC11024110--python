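import numpy as np
import pytest

from aad.rqa import (EmbeddingConfig, RecurrencePlot, auto_epsilon,
                     diagonal_histogram, embed, recurrence_matrix,
                     recurrence_times, rqa_features, rqa_from_series,
                     vertical_histogram)

# ---------------------------------------------------------------------------
# independent brute-force oracle: O(N^3)-ish explicit enumeration


def oracle_matrix(series, m, tau, eps):
    pts = [series[i:i + (m - 1) * tau + 1:tau] for i in
           range(len(series) - (m - 1) * tau)]
    n = len(pts)
    R = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            d = max(abs(a - b) for a, b in zip(pts[i], pts[j]))
            R[i, j] = 1 if eps - d >= 0 else 0
    return R


def oracle_features(R, l_min=2, v_min=2, theiler=0):
    n = len(R)
    rr = R.sum() / n ** 2

    def runs(bits):
        out, run = [], 0
        for b in bits:
            run = run + 1 if b else (out.append(run) if run else None) or 0
        if run:
            out.append(run)
        return out

    diag_lines = []
    for off in range(-(n - 1), n):
        if abs(off) <= theiler:
            continue
        line = [R[i, i + off] for i in range(max(0, -off), min(n, n - off))]
        diag_lines.extend(runs(line))
    vert_lines = []
    for j in range(n):
        vert_lines.extend(runs(R[:, j]))

    total = sum(diag_lines)
    long = [l for l in diag_lines if l >= l_min]
    det = sum(long) / total if total and long else 0.0
    l_mean = sum(long) / len(long) if long else 0.0
    l_max = max(diag_lines) if diag_lines else 0.0
    if long:
        from collections import Counter

        c = Counter(long)
        p = np.array(list(c.values())) / len(long)
        entr = float(-(p * np.log(p)).sum())
    else:
        entr = 0.0
    vlong = [v for v in vert_lines if v >= v_min]
    tt = sum(vlong) / len(vlong) if vlong else 0.0
    v_max = max(vert_lines) if vert_lines else 0.0

    times = []
    for j in range(n):
        rows = [i for i in range(n) if R[i, j]]
        starts = [r for k, r in enumerate(rows) if k == 0 or rows[k - 1] != r - 1]
        times.extend(np.diff(starts))
    if times and max(times) > 1:
        from collections import Counter

        c = Counter(times)
        p = np.array(list(c.values())) / len(times)
        rpde = float(-(p * np.log(p)).sum() / np.log(max(times)))
    else:
        rpde = 0.0
    return dict(RR=rr, DET=det, L_MEAN=l_mean, L_MAX=float(l_max), ENTR=entr,
                TT=tt, V_MAX=float(v_max), RPDE=rpde)


# ---------------------------------------------------------------------------


class TestEmbed:
    def test_m1_identity(self):
        s = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(embed(s, 1, 1).ravel(), s)

    def test_m2_pairs(self):
        out = embed(np.array([1.0, 2, 3, 4]), 2, 1)
        np.testing.assert_array_equal(out, [[1, 2], [2, 3], [3, 4]])

    def test_length_formula(self):
        assert embed(np.arange(10.0), 3, 2).shape == (6, 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed(np.arange(4.0), 3, 2)


class TestRecurrenceMatrix:
    def test_constant_series_all_ones(self):
        rp = recurrence_matrix(embed(np.full(4, 5.0)), EmbeddingConfig(epsilon=0.1))
        assert rp.matrix.sum() == 16

    def test_parity_series(self):
        rp = recurrence_matrix(embed(np.array([0.0, 10, 0, 10])),
                               EmbeddingConfig(epsilon=1.0))
        i, j = np.meshgrid(range(4), range(4), indexing="ij")
        np.testing.assert_array_equal(rp.matrix, ((i - j) % 2 == 0).astype(int))
        assert rp.matrix.sum() / 16 == 0.5

    def test_threshold_boundary_counts(self):
        # distance exactly epsilon is recurrent (Heaviside(0) = 1)
        rp = recurrence_matrix(embed(np.array([0.0, 1.0])), EmbeddingConfig(epsilon=1.0))
        assert rp.matrix.all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(30)
        for m, tau in [(1, 1), (2, 1), (3, 2)]:
            rp = recurrence_matrix(embed(s, m, tau),
                                   EmbeddingConfig(m=m, tau=tau, epsilon=0.5))
            np.testing.assert_array_equal(rp.matrix, oracle_matrix(s, m, tau, 0.5))

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        rp = recurrence_matrix(embed(rng.standard_normal(25)),
                               EmbeddingConfig(epsilon=0.3))
        np.testing.assert_array_equal(rp.matrix, rp.matrix.T)
        assert np.diagonal(rp.matrix).all()


class TestHistograms:
    def test_all_ones_diagonal_histogram(self):
        rp = RecurrencePlot(matrix=np.ones((10, 10), dtype=np.uint8),
                            config=EmbeddingConfig())
        hist = diagonal_histogram(rp)
        assert dict(hist) == {l: 2 for l in range(1, 10)}

    def test_parity_matrix_off_loi_lines(self):
        rp = recurrence_matrix(embed(np.array([0.0, 10, 0, 10])),
                               EmbeddingConfig(epsilon=1.0))
        hist = diagonal_histogram(rp)
        # odd offsets mix parities (all zero); offsets +-2 carry one
        # length-2 line each; offsets +-3 are odd again
        assert dict(hist) == {2: 2}

    def test_empty_matrix(self):
        rp = RecurrencePlot(matrix=np.eye(5, dtype=np.uint8),
                            config=EmbeddingConfig())
        assert len(diagonal_histogram(rp)) == 0

    def test_vertical_all_ones(self):
        rp = RecurrencePlot(matrix=np.ones((4, 4), dtype=np.uint8),
                            config=EmbeddingConfig())
        assert dict(vertical_histogram(rp)) == {4: 4}

    def test_vertical_identity(self):
        rp = RecurrencePlot(matrix=np.eye(4, dtype=np.uint8),
                            config=EmbeddingConfig())
        assert dict(vertical_histogram(rp)) == {1: 4}

    def test_line_count_sums(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(35)
        rp = recurrence_matrix(embed(s), EmbeddingConfig(epsilon=0.8))
        dh = diagonal_histogram(rp)
        off_band = rp.matrix.sum() - np.diagonal(rp.matrix).sum()
        assert sum(l * c for l, c in dh.items()) == off_band
        vh = vertical_histogram(rp)
        assert sum(v * c for v, c in vh.items()) == rp.matrix.sum()


class TestRecurrenceTimes:
    def test_period_two(self):
        rp = recurrence_matrix(embed(np.array([0.0, 10, 0, 10, 0, 10])),
                               EmbeddingConfig(epsilon=1.0))
        hist = recurrence_times(rp)
        assert set(hist) == {2}

    def test_constant_series_no_gaps(self):
        rp = recurrence_matrix(embed(np.full(6, 1.0)), EmbeddingConfig(epsilon=0.1))
        assert len(recurrence_times(rp)) == 0


class TestFeaturesAgainstOracle:
    def test_parity_fixture(self):
        f = rqa_from_series(np.array([0.0, 10, 0, 10]),
                            EmbeddingConfig(epsilon=1.0), eps_strategy=None)
        assert f.rr == 0.5
        assert f.det == 1.0
        assert f.l_max == 2
        assert f.entr == 0.0

    def test_constant_fixture(self):
        f = rqa_from_series(np.full(10, 3.0), EmbeddingConfig(epsilon=0.1),
                            eps_strategy=None)
        assert f.rr == 1.0
        assert f.v_max == 10
        assert f.tt == 10
        assert f.l_max == 9
        assert f.rpde == 0.0

    def test_long_period_two_rpde_zero(self):
        f = rqa_from_series(np.tile([0.0, 10.0], 20),
                            EmbeddingConfig(epsilon=1.0), eps_strategy=None)
        assert f.rpde == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_random_series_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 41))
        s = rng.standard_normal(n)
        m = int(rng.integers(1, 4))
        tau = int(rng.integers(1, 3))
        if len(s) - (m - 1) * tau < 5:
            m, tau = 1, 1
        eps = float(rng.uniform(0.2, 1.5))
        cfg = EmbeddingConfig(m=m, tau=tau, epsilon=eps)
        got = rqa_features(recurrence_matrix(embed(s, m, tau), cfg)).as_dict()
        want = oracle_features(oracle_matrix(s, m, tau, eps))
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12), k

    def test_rr_monotone_in_epsilon(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(40)
        rrs = [rqa_from_series(s, EmbeddingConfig(epsilon=e), eps_strategy=None).rr
               for e in [0.1, 0.3, 0.6, 1.0, 2.0]]
        assert all(a <= b for a, b in zip(rrs, rrs[1:]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(30)
        a = recurrence_matrix(embed(s), EmbeddingConfig(epsilon=0.5)).matrix
        b = recurrence_matrix(embed(3 * s), EmbeddingConfig(epsilon=1.5)).matrix
        np.testing.assert_array_equal(a, b)


class TestAutoEpsilon:
    def test_target_one_is_max_distance(self):
        s = np.array([0.0, 1.0, 5.0])
        assert auto_epsilon(embed(s), "TARGET_RR", 1.0) == 5.0

    def test_std_fraction(self):
        s = np.array([2.0, -2.0] * 10)  # std 2
        assert auto_epsilon(embed(s), "STD_FRACTION", 0.2) == pytest.approx(0.4)

    def test_std_fraction_degenerate_rejected(self):
        with pytest.raises(ValueError):
            auto_epsilon(embed(np.full(5, 1.0)), "STD_FRACTION", 0.2)

    def test_target_rr_achieved_within_one_cell(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(50)
        traj = embed(s)
        eps = auto_epsilon(traj, "TARGET_RR", 0.1)
        rr = rqa_features(recurrence_matrix(traj, EmbeddingConfig(epsilon=eps))).rr
        assert 0.1 <= rr <= 0.1 + 1 / 50 ** 2 + 1e-12
        # smallest such epsilon: shrinking it drops below the target
        rr_less = rqa_features(recurrence_matrix(
            traj, EmbeddingConfig(epsilon=eps * (1 - 1e-9)))).rr
        assert rr_less < rr


def test_logistic_periodic_more_deterministic_than_chaotic():
    from aad.synthetic import make_toy_series

    per = make_toy_series("LOGISTIC", 200, {"r": 3.2}, seed=0)
    cha = make_toy_series("LOGISTIC", 200, {"r": 4.0}, seed=0)
    det_p = rqa_from_series(per, eps_value=0.1).det
    det_c = rqa_from_series(cha, eps_value=0.1).det
    assert det_p > det_c


def test_rp_csv_export_round_trip(tmp_path):
    from aad.rqa import save_rp_csv

    rng = np.random.default_rng(1)
    rp = recurrence_matrix(embed(rng.standard_normal(20)),
                           EmbeddingConfig(epsilon=0.5))
    path = tmp_path / "rp.csv"
    save_rp_csv(rp, path)
    back = np.loadtxt(path, delimiter=",", dtype=int)
    np.testing.assert_array_equal(back, rp.matrix)


def test_rp_png_export_writes_image(tmp_path):
    from aad.rqa import save_rp_png

    rp = recurrence_matrix(embed(np.sin(np.linspace(0, 20, 50))),
                           EmbeddingConfig(epsilon=0.3))
    path = tmp_path / "rp.png"
    save_rp_png(rp, path)
    assert path.stat().st_size > 0
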