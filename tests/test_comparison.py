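"""Nested model comparison, paired statistics, noise floor, cluster test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from soundscape_trf import (
    FeatureSet,
    EEGRecording,
    cluster_permutation_time,
    combine,
    events_to_markers,
    fdr_bh,
    generate_event_train,
    make_triphasic_kernel,
    nested_comparison,
    onset_noise_floor,
    pink_noise,
    shuffle_preserving_ioi,
    synthesize_eeg,
    wilcoxon_signed_rank,
)
from soundscape_trf.synth import event_signal

from conftest import QUICK_LAMBDAS, onset_feature

RATE = 100.0


def _category_eeg(duration_s, n_events, kernels: dict, snr_db, seed):
    """EEG whose response kernel depends on the event category."""
    events = generate_event_train(
        duration_s, n_events, min_gap_s=0.6,
        categories=tuple(kernels), condition_split=0.5, seed=seed,
    )
    n = int(duration_s * RATE)
    sig = np.zeros(n)
    for cat, k in kernels.items():
        sig += event_signal(events.select(category=cat), k, n, RATE)
    n_ch = 6
    data = np.tile(sig[:, None], (1, n_ch))
    ref = make_triphasic_kernel(RATE)
    sigma = np.mean(np.abs(ref.amplitude)) * 10 ** (-snr_db / 20)
    data += sigma * pink_noise(n, n_ch, seed=seed + 1)
    return events, EEGRecording(data, RATE)


class TestNestedComparison:
    def test_self_consistency_on_noiseless_data(self):
        kernel = make_triphasic_kernel(RATE)
        events = generate_event_train(120.0, 80, seed=41)
        eeg = synthesize_eeg(events, kernel, np.inf, 4, RATE, duration_s=120.0)
        # correlations are undefined on constant event-free segments of
        # noiseless data only if a segment lacks events; 80 events avoid that
        feats = onset_feature(events, eeg.n_samples)
        table = nested_comparison({"onsets": feats}, eeg, n_segments=6,
                                  lambda_grid=QUICK_LAMBDAS)
        assert np.all(table["mean_channel_r"] > 0.99)

    def test_si_markers_add_predictive_power(self):
        # category-specific kernels: SI markers carry real extra signal
        k1 = make_triphasic_kernel(RATE, peak_amplitudes=(1, -2, 1))
        k2 = make_triphasic_kernel(RATE, peak_latencies_s=(0.08, 0.16, 0.3),
                                   peak_amplitudes=(-1, 2.5, -1))
        deltas = []
        for rep in range(6):
            events, eeg = _category_eeg(120.0, 80, {"beep": k1, "alarm": k2},
                                        snr_db=5.0, seed=100 + 7 * rep)
            base = onset_feature(events, eeg.n_samples)
            markers = events_to_markers(events, eeg.n_samples, RATE)
            table = nested_comparison(
                {"AC": base, "AC+SI": combine(base, markers)}, eeg,
                n_segments=6, lambda_grid=QUICK_LAMBDAS,
            )
            means = table.groupby("model_id")["mean_channel_r"].mean()
            deltas.append(means["AC+SI"] - means["AC"])
        assert np.mean(deltas) >= 0
        assert sum(d >= 0 for d in deltas) >= 5

    def test_condition_split_is_null_when_kernels_identical(self):
        kernel = make_triphasic_kernel(RATE)
        deltas = []
        for rep in range(5):
            events = generate_event_train(
                120.0, 80, categories=("beep", "alarm"),
                condition_split=0.5, seed=200 + rep,
            )
            eeg = synthesize_eeg(events, kernel, 5.0, 6, RATE,
                                 duration_s=120.0, seed=300 + rep)
            base = onset_feature(events, eeg.n_samples)
            markers = events_to_markers(events, eeg.n_samples, RATE)
            split = events_to_markers(events, eeg.n_samples, RATE,
                                      condition_split=True)
            table = nested_comparison(
                {"AC+SI": combine(base, markers),
                 "AC+SI+CP": combine(base, split)},
                eeg, n_segments=6, lambda_grid=QUICK_LAMBDAS,
            )
            means = table.groupby("model_id")["mean_channel_r"].mean()
            deltas.append(means["AC+SI+CP"] - means["AC+SI"])
        assert np.mean(deltas) < 0.005

    def test_zero_feature_model_rejected(self, small_eeg):
        empty = FeatureSet(np.zeros((small_eeg.n_samples, 0)), [], [], RATE)
        with pytest.raises(ValueError):
            nested_comparison({"empty": empty}, small_eeg)


class TestWilcoxon:
    def test_identical_pairs(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero"):
            W, Z, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_uniform_dominance_gives_zero_w(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        x = y + rng.uniform(0.1, 1.0, 20)
        W, Z, p = wilcoxon_signed_rank(x, y)
        assert W == 0.0
        assert p < 0.001

    def test_exact_p_matches_sign_flip_enumeration(self):
        d = np.array([0.7, -0.2, 1.4, 0.5, -1.1, 0.3])
        x = np.zeros(6) + d
        y = np.zeros(6)
        W, Z, p = wilcoxon_signed_rank(x, y)
        # brute force: all 2^6 sign assignments of the |d| ranks
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            wm = ranks.sum() - wp
            if min(wp, wm) <= w_obs:
                count += 1
        assert p == pytest.approx(count / 2**6)


class TestFdrBH:
    def test_all_ones_no_rejections(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0], 0.05)
        assert not reject.any()

    def test_step_up_by_hand(self):
        reject, _ = fdr_bh([0.01, 0.02, 0.03, 0.5], 0.05)
        assert np.array_equal(reject, [True, True, True, False])

    def test_duplicate_p_share_adjusted_value(self):
        _, adj = fdr_bh([0.02, 0.02, 0.9], 0.05)
        assert adj[0] == adj[1]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_step_up_definition(self, pvals):
        q = 0.05
        reject, _ = fdr_bh(pvals, q)
        p = np.asarray(pvals)
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i / m * q:
                k_max = i
        expected = np.zeros(m, bool)
        expected[order[:k_max]] = True
        assert np.array_equal(reject, expected)


class TestIoiShuffle:
    def test_two_onsets_gap_preserved(self):
        v = np.zeros(100)
        v[[10, 37]] = 1
        out = shuffle_preserving_ioi(v, seed=3)
        idx = np.flatnonzero(out)
        assert len(idx) == 2 and idx[1] - idx[0] == 27

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_interval_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(2000, size=50, replace=False))
        v = np.zeros(2000)
        v[idx] = 1
        out = shuffle_preserving_ioi(v, seed=seed)
        new_idx = np.flatnonzero(out)
        assert len(new_idx) == 50
        assert np.array_equal(np.sort(np.diff(idx)), np.sort(np.diff(new_idx)))
        assert new_idx.max() < 2000

    def test_same_seed_same_shuffle(self):
        v = np.zeros(500)
        v[np.arange(10) * 43 + 7] = 1
        assert np.array_equal(
            shuffle_preserving_ioi(v, seed=9), shuffle_preserving_ioi(v, seed=9)
        )


class TestNoiseFloor:
    def test_null_scores_bookkeeping(self, small_eeg, small_onsets):
        nf = onset_noise_floor(small_onsets, small_eeg, n_perm=5,
                               n_segments=4, lambda_grid=QUICK_LAMBDAS, seed=1)
        assert nf.n_perm == 5
        assert nf.ci_low <= nf.ci_high

    def test_signal_lifts_true_score_above_ci(self, small_events, small_eeg,
                                              small_onsets):
        from soundscape_trf import fit_predict_cv

        true_score = float(np.nanmean(fit_predict_cv(
            small_onsets, small_eeg, n_segments=4, lambda_grid=QUICK_LAMBDAS)))
        nf = onset_noise_floor(small_onsets, small_eeg, n_perm=20,
                               n_segments=4, lambda_grid=QUICK_LAMBDAS, seed=2)
        assert true_score > nf.ci_high

    def test_pure_noise_null_centered_near_zero(self):
        eeg = EEGRecording(pink_noise(6000, 4, seed=77), RATE)
        events = generate_event_train(60.0, 40, seed=78)
        feats = onset_feature(events, 6000)
        nf = onset_noise_floor(feats, eeg, n_perm=20, n_segments=4,
                               lambda_grid=QUICK_LAMBDAS, seed=3)
        assert abs(np.mean(nf.null_scores)) < 0.01
        from soundscape_trf import fit_predict_cv

        true_score = float(np.nanmean(fit_predict_cv(
            feats, eeg, n_segments=4, lambda_grid=QUICK_LAMBDAS)))
        assert nf.ci_low - 0.01 < true_score < nf.ci_high + 0.01


class TestClusterPermutation:
    def _weights(self, seed, n_units=12, n_lags=61, noise=0.1):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n_units, n_lags)) * noise

    def test_identical_conditions_no_clusters(self):
        a = self._weights(1)
        assert cluster_permutation_time(a, a.copy(), n_perm=100, seed=0) == []

    def test_injected_effect_found_at_its_locus(self):
        a = self._weights(2)
        b = self._weights(3)
        b[:, 30:41] += 1.0  # constant offset at lags 30-40
        clusters = cluster_permutation_time(a, b, n_perm=500, seed=4)
        sig = [c for c in clusters if c.p_value < 0.05]
        assert len(sig) == 1
        assert sig[0].start <= 31 and sig[0].stop >= 40
        assert sig[0].p_value <= 0.01

    def test_p_values_on_permutation_grid(self):
        a = self._weights(5)
        b = self._weights(6)
        b[:, 10:20] += 0.15
        clusters = cluster_permutation_time(a, b, n_perm=200, seed=7)
        for c in clusters:
            assert (c.p_value * 200) == pytest.approx(round(c.p_value * 200))

    def test_too_few_units_rejected(self):
        a = self._weights(8, n_units=4)
        with pytest.raises(ValueError, match="6 units"):
            cluster_permutation_time(a, a, n_perm=100)
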