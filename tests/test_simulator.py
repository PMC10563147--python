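"""Fragment sampling, channel emission, ML decoding, error-rate estimation."""

import numpy as np
import pytest

from ogmap import (
    BinnedGenome,
    ChannelModel,
    confidence_interval,
    emit_labels,
    ml_decode,
    sample_fragment,
    simulate_error_rate,
)


def _binned(*vecs, bin_size=1000, cap=2):
    return BinnedGenome(
        record_ids=tuple(f"r{i}" for i in range(len(vecs))),
        counts=tuple(np.asarray(v, dtype=np.int64) for v in vecs),
        bin_size=bin_size,
        cap=cap,
    )


def _near_noiseless(cap=2, eps=1e-6):
    m = np.full((cap + 1, cap + 1), eps)
    np.fill_diagonal(m, 1 - cap * eps)
    return ChannelModel(cap=cap, p_x=np.array([0.6, 0.3, 0.1]), p_y_given_x=m)


class TestSampleFragment:
    def test_single_valid_offset(self):
        b = _binned([0, 1, 2])
        f = sample_fragment(b, 3, np.random.default_rng(0))
        assert (f.record_id, f.start_bin) == ("r0", 0)
        assert f.x_vec.tolist() == [0, 1, 2]

    def test_record_choice_proportional_to_valid_offsets(self):
        # 101 vs 201 valid start bins for n = 100
        b = _binned([0] * 200, [0] * 300)
        rng = np.random.default_rng(1)
        picks = sum(sample_fragment(b, 100, rng).record_id == "r0" for _ in range(10_000))
        p = 101 / 302
        sigma = np.sqrt(p * (1 - p) * 10_000)
        assert abs(picks - 10_000 * p) < 5 * sigma

    def test_no_record_long_enough(self):
        with pytest.raises(ValueError):
            sample_fragment(_binned([0, 1]), 5, np.random.default_rng(0))


class TestEmitLabels:
    def test_deterministic_channel_copies_input(self):
        m = ChannelModel(cap=2, p_x=np.full(3, 1 / 3), p_y_given_x=np.eye(3))
        x = np.array([0, 2, 1, 1, 0])
        y = emit_labels(x, m, np.random.default_rng(0))
        assert y.tolist() == x.tolist()

    def test_frequencies_match_likelihood_row(self, table1):
        x = np.ones(10**5, dtype=np.int64)
        y = emit_labels(x, table1, np.random.default_rng(2))
        freqs = np.bincount(y, minlength=3) / x.size
        for b in range(3):
            p = table1.p_y_given_x[1, b]
            assert abs(freqs[b] - p) < 3 * np.sqrt(p * (1 - p) / x.size)

    def test_same_seed_reproduces(self, table1):
        x = np.random.default_rng(0).integers(0, 3, size=100)
        a = emit_labels(x, table1, np.random.default_rng(9))
        b = emit_labels(x, table1, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_rejects_unknown_symbol(self, table1):
        with pytest.raises(ValueError):
            emit_labels(np.array([3]), table1, np.random.default_rng(0))


def _oracle_decode(y_vec, binned, model, floor=None, tol=1e-9):
    """Naive exhaustive double-loop scorer, written independently.

    Scores within ``tol`` count as tied, matching the decoder's contract.
    """
    pyx = model.p_y_given_x
    if floor is not None:
        pyx = np.maximum(pyx, floor)
    logp = [[float(np.log(pyx[a, b])) for b in range(pyx.shape[1])] for a in range(pyx.shape[0])]
    n = len(y_vec)
    best = None
    for rec_id, x in zip(binned.record_ids, binned.counts):
        for orient, vec in (("forward", list(x)), ("reverse", list(x)[::-1])):
            for start in range(len(vec) - n + 1):
                s = 0.0
                for j in range(n):
                    s += logp[vec[start + j]][int(y_vec[j])]
                if best is None or round(s / tol) > round(best[3] / tol):
                    best = (rec_id, start, orient, s)
    return best


class TestMLDecode:
    def test_unique_window_recovered_under_low_noise(self):
        b = _binned([0, 0, 1, 2, 0, 2, 1, 0])
        got = ml_decode(np.array([1, 2, 0]), b, _near_noiseless())
        assert got[:3] == ("r0", 2, "forward")

    def test_palindromic_genome_tie_broken_forward(self):
        # reversed bin vector equals the forward one: exact score tie
        b = _binned([1, 0, 2, 0, 1])
        got = ml_decode(np.array([0, 2, 0]), b, _near_noiseless())
        assert got[:3] == ("r0", 1, "forward")

    def test_agrees_with_naive_oracle(self, table1):
        rng = np.random.default_rng(17)
        for _ in range(120):
            n_recs = int(rng.integers(1, 3))
            vecs = [rng.integers(0, 3, size=int(rng.integers(5, 60))) for _ in range(n_recs)]
            n = int(rng.integers(2, 6))
            if max(v.size for v in vecs) < n:
                continue
            b = _binned(*vecs)
            y = rng.integers(0, 3, size=n)
            got = ml_decode(y, b, table1)
            want = _oracle_decode(y, b, table1)
            assert got[:3] == want[:3]
            assert got[3] == pytest.approx(want[3], abs=1e-9)

    def test_zero_likelihood_requires_floor(self):
        m = ChannelModel(cap=1, p_x=np.array([0.5, 0.5]), p_y_given_x=np.eye(2))
        b = _binned([0, 1, 0], cap=1)
        with pytest.raises(ValueError, match="floor"):
            ml_decode(np.array([1, 0]), b, m)
        got = ml_decode(np.array([1, 0]), b, m, floor=1e-12)
        assert got[:3] == ("r0", 1, "forward")


class TestConfidenceInterval:
    def test_boundaries(self):
        assert confidence_interval(0, 512)[0] == 0.0
        assert confidence_interval(512, 512)[1] == 1.0

    def test_half_matches_closed_form_wilson(self):
        """Oracle: the Wilson formula evaluated directly."""
        z = 1.959963984540054
        n, p = 512, 0.5
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        lo, hi = confidence_interval(256, 512)
        assert lo == pytest.approx(center - half, abs=1e-9)
        assert hi == pytest.approx(center + half, abs=1e-9)
        assert hi - lo == pytest.approx(0.087, abs=2e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence_interval(1, 0)
        with pytest.raises(ValueError):
            confidence_interval(5, 4)


class TestSimulateErrorRate:
    def test_noiseless_channel_maps_perfectly(self, small_binned):
        m = _near_noiseless()
        px = np.bincount(small_binned.all_counts(), minlength=3) / small_binned.n_bins
        est = simulate_error_rate(
            small_binned, None, m.with_px(px), 50_000, trials=64, seed=0
        )
        assert est.errors == 0 and est.ci95[0] == 0.0

    def test_independent_channel_decodes_at_chance(self, small_binned, independent_channel):
        px = np.bincount(small_binned.all_counts(), minlength=3) / small_binned.n_bins
        m = independent_channel.with_px(px)
        est = simulate_error_rate(small_binned, None, m, 50_000, trials=64, seed=0)
        assert est.rate > 0.95
        assert est.theory.degenerate and est.theory.epsilon == 1.0

    def test_deterministic_in_seed(self, small_binned, table1):
        a = simulate_error_rate(small_binned, None, table1, 20_000, trials=32, seed=5)
        b = simulate_error_rate(small_binned, None, table1, 20_000, trials=32, seed=5)
        assert (a.errors, a.rate, a.ci95) == (b.errors, b.rate, b.ci95)

    def test_margin_relaxes_error_definition(self, small_binned, table1):
        strict = simulate_error_rate(small_binned, None, table1, 20_000, trials=128, seed=1)
        loose = simulate_error_rate(
            small_binned, None, table1, 20_000, trials=128, seed=1, margin_bins=1
        )
        assert loose.errors <= strict.errors

    def test_orientation_symmetry(self, small_binned, table1):
        """Reversed fragments decode with statistically identical error rates."""
        from ogmap.simulator import _decode_batch, sample_fragment, emit_labels

        px = np.bincount(small_binned.all_counts(), minlength=3) / small_binned.n_bins
        model = table1.with_px(px)
        n, trials = 30, 192
        n_bins = small_binned.counts[0].size
        frags, Y = [], np.empty((trials, n), dtype=np.int64)
        for t in range(trials):
            rng = np.random.default_rng([11, t])
            f = sample_fragment(small_binned, n, rng)
            Y[t] = emit_labels(f.x_vec, model, rng)
            frags.append(f)
        fwd = _decode_batch(Y, small_binned, model, None)
        rev = _decode_batch(Y[:, ::-1], small_binned, model, None)
        err_f = err_r = 0
        for f, df, dr in zip(frags, fwd, rev):
            err_f += df[:3] != (f.record_id, f.start_bin, "forward")
            # a reversed read truly originates at the mirrored offset
            err_r += dr[:3] != (f.record_id, n_bins - n - f.start_bin, "reverse")
        p1, p2 = err_f / trials, err_r / trials
        pool = (err_f + err_r) / (2 * trials)
        se = np.sqrt(max(pool * (1 - pool), 1e-12) * 2 / trials)
        assert abs(p1 - p2) < 2.576 * se + 1e-9  # alpha = 0.01
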