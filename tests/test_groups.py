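"""Trinary significance patterns, three-group classification, Haar
features and the 50-75 s response AUC."""

import numpy as np
import pandas as pd
import pytest

from scnlight.clustering import N_BASELINE_BINS, N_LIGHT_BINS
from scnlight.groups import (
    PATTERN_LEN,
    ZT_ORDER,
    SignificancePattern,
    classify_groups,
    group_composition,
    haar_features,
    haar_inverse,
    response_auc,
    significance_pattern,
)

FR = 23.0
N = 2760


def _trial_bins(rng, light_shift=0.0, n_trials=9, noise=0.3):
    bins = rng.normal(0, noise, (n_trials, 24))
    bins[:, N_BASELINE_BINS:] += light_shift
    return bins


def haar_matrix(n: int) -> np.ndarray:
    """Orthonormal Haar matrix built by recursion (independent oracle)."""
    if n == 1:
        return np.array([[1.0]])
    h = haar_matrix(n // 2)
    top = np.kron(h, [1.0, 1.0])
    bot = np.kron(np.eye(n // 2), [1.0, -1.0])
    return np.vstack([top, bot]) / np.sqrt(2.0)


class TestSignificancePattern:
    def test_null_neuron_nonzero_rate_bounded(self):
        rng = np.random.default_rng(0)
        any_hit, reps = 0, 150
        for _ in range(reps):
            pat = significance_pattern({zt: _trial_bins(rng) for zt in ZT_ORDER})
            any_hit += int(np.any(pat.values != 0))
        # 3 independent ZT blocks, each gated at alpha=0.05
        p_fam = 1 - 0.95**3
        assert any_hit / reps <= p_fam + 3 * np.sqrt(p_fam * (1 - p_fam) / reps)

    def test_planted_zt16_elevation_fills_zt16_block_only(self):
        rng = np.random.default_rng(1)
        bins = {
            16: _trial_bins(rng, light_shift=3.0),
            22: _trial_bins(rng),
            8: _trial_bins(rng),
        }
        pat = significance_pattern(bins)
        assert (pat.block(16) == 1).sum() >= 16
        assert np.abs(pat.block(22)).sum() <= 2
        assert np.abs(pat.block(8)).sum() <= 2

    def test_sign_flip_negates_pattern(self):
        rng = np.random.default_rng(2)
        bins = {zt: _trial_bins(rng, light_shift=2.5) for zt in ZT_ORDER}
        pat = significance_pattern(bins)
        flipped = significance_pattern({zt: -b for zt, b in bins.items()})
        np.testing.assert_array_equal(flipped.values, -pat.values)

    def test_vanishing_alpha_gives_all_zero_pattern(self):
        rng = np.random.default_rng(3)
        bins = {zt: _trial_bins(rng, light_shift=3.0) for zt in ZT_ORDER}
        pat = significance_pattern(bins, alpha=1e-300)
        assert np.all(pat.values == 0)

    def test_missing_zt_flagged_with_zero_block(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning):
            pat = significance_pattern({16: _trial_bins(rng, light_shift=3.0)})
        assert pat.incomplete
        assert np.all(pat.block(22) == 0) and np.all(pat.block(8) == 0)

    def test_pattern_validation(self):
        with pytest.raises(ValueError):
            SignificancePattern(np.zeros(10))
        with pytest.raises(ValueError):
            SignificancePattern(np.full(PATTERN_LEN, 2))


class TestClassifyGroups:
    def _patterns(self, rng, n1=5, n2=3, n3=40, flip_rate=0.05):
        pats = []
        for _ in range(n1):
            v = np.zeros(PATTERN_LEN, int)
            v[:N_LIGHT_BINS] = 1  # ZT-16 activated
            pats.append(v)
        for _ in range(n2):
            v = np.zeros(PATTERN_LEN, int)
            v[N_LIGHT_BINS : 2 * N_LIGHT_BINS] = -1  # ZT-22 inhibited
            pats.append(v)
        for _ in range(n3):
            v = rng.choice([-1, 0, 1], size=PATTERN_LEN, p=[0.05, 0.9, 0.05])
            pats.append(v)
        return np.asarray(pats, dtype=float)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(0)
        X = self._patterns(rng)
        groups, assignments = classify_groups(X, seed=0)
        np.testing.assert_array_equal(groups[:5], 1)
        np.testing.assert_array_equal(groups[5:8], 2)
        assert (groups[8:] == 3).mean() >= 0.95
        assert assignments[0].group == 1

    def test_label_permutation_invariance_across_seeds(self):
        rng = np.random.default_rng(1)
        X = self._patterns(rng)
        ref, _ = classify_groups(X, seed=0)
        for seed in (1, 2, 3):
            g, _ = classify_groups(X, seed=seed)
            np.testing.assert_array_equal(g, ref)

    def test_all_zero_patterns_go_to_group3(self):
        with pytest.warns(UserWarning):
            groups, _ = classify_groups(np.zeros((10, PATTERN_LEN)), seed=0)
        assert np.all(groups == 3)


class TestHaar:
    def test_all_zero_series_all_zero_coefficients(self):
        hf = haar_features(np.zeros(N_LIGHT_BINS))
        np.testing.assert_array_equal(hf.coefficients, 0.0)

    def test_constant_run_has_zero_interior_details(self):
        hf = haar_features(np.ones(N_LIGHT_BINS))
        # level-1 detail pairs (2k, 2k+1): inside the constant run bins 0-17
        # all pairs are equal, so details vanish; only pads/boundary remain
        d1 = hf.coefficients[16:]
        np.testing.assert_array_equal(d1[:9], 0.0)
        np.testing.assert_array_equal(d1[10:], 0.0)  # pad region
        assert hf.coefficients[0] != 0.0  # approximation carries the mean

    def test_involution_and_parseval_against_matrix_oracle(self):
        rng = np.random.default_rng(0)
        H = haar_matrix(32)
        for _ in range(300):
            s = rng.integers(-1, 2, N_LIGHT_BINS).astype(float)
            hf = haar_features(s)
            rec = haar_inverse(hf.coefficients)
            np.testing.assert_allclose(rec[:18], s, atol=1e-12)
            np.testing.assert_allclose(rec[18:], 0.0, atol=1e-12)
            padded = np.zeros(32)
            padded[:18] = s
            # energy preserved, and coefficient multiset matches H @ x
            assert np.sum(hf.coefficients**2) == pytest.approx(np.sum(s**2), abs=1e-10)
            np.testing.assert_allclose(
                np.sort(np.abs(hf.coefficients)), np.sort(np.abs(H @ padded)), atol=1e-10
            )

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            haar_features(np.zeros(10))
        with pytest.raises(ValueError):
            haar_features(np.full(N_LIGHT_BINS, 0.5))


class TestAUC:
    def test_zero_and_constant_traces(self):
        assert response_auc(np.zeros(N), FR) == 0.0
        assert response_auc(np.ones(N), FR) == pytest.approx(25.0)

    def test_matches_trapezoid_oracle(self, rng):
        z = rng.normal(size=N)
        t = np.arange(N) / FR - 30.0
        sel = (t >= 50.0) & (t <= 75.0)
        expected = np.trapezoid(z[sel], t[sel])
        assert response_auc(z, FR) == pytest.approx(expected, abs=1e-10)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            response_auc(np.zeros(N), FR, window=(100.0, 200.0))


class TestGroupComposition:
    def _labels(self, rng, groups, bias_zt=None):
        rows = []
        for neuron, g in enumerate(groups):
            for zt in (16, 22, 8):
                for trial in range(9):
                    if g == 1 and zt == 16 and bias_zt:
                        lab = rng.choice([1, 2, 3, 4])
                    elif g == 2 and zt == 22 and bias_zt:
                        lab = rng.choice([5, 6])
                    else:
                        lab = rng.integers(1, 8)
                    rows.append({"neuron_id": neuron, "zt": zt, "label": lab})
        return pd.DataFrame(rows)

    def test_fractions_sum_with_c7_complement_to_one(self, rng):
        groups = np.array([1] * 3 + [2] * 3 + [3] * 10)
        labels = self._labels(rng, groups, bias_zt=True)
        fractions, _ = group_composition(labels, groups)
        c7 = (
            labels.assign(group=groups[labels["neuron_id"]], c7=labels["label"] == 7)
            .groupby(["group", "zt"])["c7"]
            .mean()
            .reset_index()
        )
        merged = fractions.merge(c7, on=["group", "zt"])
        total = merged["activation_frac"] + merged["inhibition_frac"] + merged["c7"]
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_planted_group1_activation_contrast_detected(self, rng):
        groups = np.array([1] * 6 + [2] * 5 + [3] * 20)
        labels = self._labels(rng, groups, bias_zt=True)
        _, tests = group_composition(labels, groups)
        sig = tests.query(
            "zt == 16 and measure == 'activation_frac' and group_a == 1 and significant"
        )
        assert len(sig) > 0
        sig22 = tests.query(
            "zt == 22 and measure == 'inhibition_frac' and significant"
        )
        assert any((row.group_a == 2) or (row.group_b == 2) for row in sig22.itertuples())

    def test_uniform_labels_rarely_significant(self):
        rng = np.random.default_rng(7)
        hits, reps = 0, 40
        groups = np.array([1] * 6 + [2] * 5 + [3] * 20)
        for _ in range(reps):
            labels = self._labels(rng, groups, bias_zt=None)
            _, tests = group_composition(labels, groups)
            hits += int(tests["significant"].any())
        assert hits / reps <= 0.35  # 6 ANOVA families at alpha=0.05
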