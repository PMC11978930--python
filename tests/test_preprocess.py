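"""Mutual-information registration, trace extraction, detrend and Eq.-style
Z-normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnlight.preprocess import (
    apply_translation,
    detrend,
    extract_trace,
    mattes_mi,
    normalize_trace,
    preprocess_trace,
    register_translation,
    register_stack,
    subtract_background,
)
from scnlight.synthetic import archetype_waveform, generate_image_stack

FR = 23.0
N = 2760
T = np.arange(N) / FR


def _entropy(image, n_bins=32):
    h, _ = np.histogram(image, bins=n_bins, range=(image.min(), image.max()))
    p = h / h.sum()
    p = p[p > 0]
    return -np.sum(p * np.log(p))


class TestMutualInformation:
    def test_identity_equals_marginal_entropy(self, rng):
        img = rng.normal(size=(64, 64))
        assert mattes_mi(img, img) == pytest.approx(_entropy(img), rel=1e-10)

    def test_independent_noise_near_zero_within_permutation_band(self, rng):
        img = rng.normal(size=(128, 128))
        noise = rng.normal(size=(128, 128))
        mi = mattes_mi(img, noise)
        # permutation oracle: shuffled-pixel MI spans the chance band
        perms = []
        for _ in range(20):
            shuffled = rng.permutation(noise.ravel()).reshape(noise.shape)
            perms.append(mattes_mi(img, shuffled))
        assert mi < np.mean(perms) + 5 * np.std(perms) + 1e-9
        assert mi < 0.1 * mattes_mi(img, img)

    def test_bijective_intensity_remap_preserves_mi(self):
        checker = np.indices((32, 32)).sum(axis=0) % 2
        assert mattes_mi(checker, 1 - checker) == pytest.approx(
            mattes_mi(checker, checker), abs=1e-12
        )

    def test_constant_image_degenerate(self):
        with pytest.warns(UserWarning):
            assert mattes_mi(np.ones((8, 8)), np.arange(64.0).reshape(8, 8)) == 0.0
        with pytest.raises(ValueError):
            mattes_mi(np.zeros((4, 4)), np.zeros((5, 5)))


class TestRegistration:
    def test_self_registration_is_zero(self, rng):
        img = rng.normal(size=(64, 64))
        est = register_translation(img, img, search_bound=8)
        assert (est.t_x, est.t_y) == (0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_free_integer_shifts_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(-10, 11, size=2)
        stack, _, _ = generate_image_stack(
            2, np.vstack([[0, 0], truth]), shape=(128, 128), seed=seed
        )
        est = register_translation(stack[1], stack[0], search_bound=12)
        assert (est.t_x, est.t_y) == tuple(truth)

    def test_coarse_to_fine_matches_exhaustive(self):
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            truth = rng.integers(-10, 11, size=2)
            stack, _, _ = generate_image_stack(
                2, np.vstack([[0, 0], truth]), shape=(128, 128), seed=seed
            )
            ex = register_translation(stack[1], stack[0], 12, strategy="exhaustive")
            cf = register_translation(stack[1], stack[0], 12, strategy="coarse_to_fine")
            assert (ex.t_x, ex.t_y) == (cf.t_x, cf.t_y) == tuple(truth)

    def test_matches_phase_correlation_oracle(self):
        from skimage.registration import phase_cross_correlation

        stack, _, _ = generate_image_stack(
            2, np.array([[0, 0], [5, -7]]), shape=(128, 128), seed=4
        )
        est = register_translation(stack[1], stack[0], search_bound=10)
        shift, _, _ = phase_cross_correlation(stack[0], stack[1])
        # skimage returns the (row, col) shift that registers moving to ref
        assert (est.t_x, est.t_y) == (int(-shift[1]), int(-shift[0]))

    def test_noisy_recovery_within_one_pixel(self):
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(200 + seed)
            truth = rng.integers(-8, 9, size=2)
            stack, _, _ = generate_image_stack(
                2, np.vstack([[0, 0], truth]), shape=(128, 128),
                noise_sd=50.0, seed=seed,  # ~10% of the ~500-unit range
            )
            est = register_translation(stack[1], stack[0], search_bound=10)
            if max(abs(est.t_x - truth[0]), abs(est.t_y - truth[1])) <= 1:
                hits += 1
        assert hits == 15

    def test_register_stack_flags_excessive_motion(self):
        shifts = np.array([[0, 0], [2, 1], [12, 0]])
        stack, _, _ = generate_image_stack(3, shifts, shape=(128, 128), seed=0)
        corrected, ests, excessive = register_stack(stack, search_bound=15, qc_shift_px=10)
        assert [(e.t_x, e.t_y) for e in ests] == [(0, 0), (2, 1), (12, 0)]
        assert excessive
        # corrected frames agree with the reference away from edges
        assert np.abs(corrected[1][20:-20, 20:-20] - stack[0][20:-20, 20:-20]).max() < 1e-9

    def test_degenerate_image_zero_shift_with_warning(self):
        with pytest.warns(UserWarning):
            est = register_translation(np.zeros((64, 64)), np.zeros((64, 64)), 8)
        assert est.degenerate and (est.t_x, est.t_y) == (0, 0)


class TestExtraction:
    def test_uniform_frames_give_constant_trace(self):
        stack = np.full((5, 8, 8), 7.0)
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        np.testing.assert_array_equal(extract_trace(stack, mask), np.full(5, 7.0))

    def test_two_pixel_mask_averages(self):
        stack = np.zeros((2, 4, 4))
        stack[:, 0, 0] = [1.0, 3.0]
        stack[:, 1, 1] = [5.0, 7.0]
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        np.testing.assert_allclose(extract_trace(stack, mask), [3.0, 5.0])

    def test_planted_roi_signal_recovered(self):
        rng = np.random.default_rng(0)
        sig = 100 + 50 * np.sin(np.linspace(0, 6 * np.pi, 40))
        stack = np.zeros((40, 16, 16))
        mask = np.zeros((16, 16), bool)
        mask[5:9, 5:9] = True
        stack[:, mask] = sig[:, None]
        extracted = extract_trace(stack, mask)
        assert np.corrcoef(extracted, sig)[0, 1] > 0.99

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_trace(np.zeros((2, 4, 4)), np.zeros((4, 4), bool))


class TestBackground:
    def test_zero_background_is_identity_and_self_cancels(self, rng):
        trace = rng.normal(size=100)
        np.testing.assert_array_equal(subtract_background(trace, np.zeros(100)), trace)
        np.testing.assert_array_equal(subtract_background(trace, trace), np.zeros(100))
        with pytest.raises(ValueError):
            subtract_background(trace, np.zeros(99))

    def test_shared_stimulus_artifact_removed(self, rng):
        artifact = np.zeros(N)
        artifact[690:] = 40.0  # light-locked offset in both ROI and background
        trace = 5000 + rng.normal(0, 5, N) + artifact
        background = 30 + rng.normal(0, 5, N) + artifact
        cleaned = subtract_background(trace, background)
        light_shift = cleaned[690:].mean() - cleaned[:690].mean()
        assert abs(light_shift) < 1.0


class TestDetrend:
    def test_constant_trace_unchanged(self):
        const = np.full(N, 321.0)
        out, rep = detrend(const, FR)
        assert rep.a == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(out, const, atol=1e-6)

    def test_pure_exponential_recovered(self):
        out, rep = detrend(500.0 * np.exp(-T / 300.0) + 100.0, FR)
        assert np.abs(out - 100.0).max() < 0.5
        assert rep.tau == pytest.approx(300.0, rel=1e-3)

    def test_fast_oscillation_preserved(self):
        osc = 200.0 * np.sin(2 * np.pi * T / 0.5)
        out, _ = detrend(2000.0 * np.exp(-T / 2000.0) + osc + 300.0, FR)
        assert np.corrcoef(out, osc + 300.0)[0, 1] > 0.99

    def test_idempotent_on_clean_fixtures(self):
        for trace in (
            500.0 * np.exp(-T / 300.0) + 100.0,
            2000.0 * np.exp(-T / 2000.0) + 300.0,
        ):
            once, _ = detrend(trace, FR)
            twice, _ = detrend(once, FR)
            assert np.abs(twice - once).max() < 1e-6 * np.ptp(once)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.zeros(50), FR)


class TestNormalize:
    def test_step_trace_signs(self):
        trace = np.where(T < 30.0, 100.0, 110.0)
        nt = normalize_trace(trace, FR)
        assert np.all(nt.z[:690] == 0.0)
        assert np.all(nt.z[690:] > 0.0)

    def test_matches_literal_formula_on_seeded_traces(self, rng):
        for _ in range(100):
            trace = rng.normal(5000.0, 300.0, N)
            nt = normalize_trace(trace, FR)
            f_b = np.median(trace[:690])
            f_s = trace.std()
            np.testing.assert_allclose(nt.z, (trace - f_b) / f_s, atol=1e-12)
            assert abs(np.median(nt.z[:690])) < 1e-12

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 50.0, allow_nan=False),
        offset=st.floats(-1e3, 1e3, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, scale, offset, seed):
        trace = np.random.default_rng(seed).normal(100.0, 10.0, N)
        a = normalize_trace(trace, FR)
        b = normalize_trace(scale * trace + offset, FR)
        np.testing.assert_allclose(a.z, b.z, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalize_trace(np.full(N, 5.0), FR)


class TestPipeline:
    def test_zero_noise_pipeline_reproduces_archetype_shapes(self, clean_cohort):
        """background -> detrend -> normalize preserves the planted waveform."""
        from scnlight.pipeline import normalize_cohort

        z = normalize_cohort(clean_cohort)
        light = T >= 30.0
        t_light = T[light] - 30.0
        for i, tr in enumerate(clean_cohort.traces):
            arch = clean_cohort.truth_trial_clusters[i]
            if arch == 4:  # marginal: no waveform to compare against
                continue
            ideal = archetype_waveform(arch, t_light)
            got = z[i][light]
            cos = got @ ideal / (np.linalg.norm(got) * np.linalg.norm(ideal))
            assert cos > 0.99, f"archetype {arch}: cosine {cos:.3f}"

    def test_preprocess_trace_end_to_end(self, rng):
        raw = 8000.0 * np.exp(-T / 2000.0) + rng.normal(0, 50, N)
        nt = preprocess_trace(raw, FR, background=np.full(N, 30.0))
        assert abs(np.median(nt.z[:690])) < 1e-12
        assert nt.f_std > 0
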