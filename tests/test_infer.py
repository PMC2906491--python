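"""The MUMM likelihood and the metamotif nested sampler."""

import numpy as np
import pytest

from metamotif.estimate import estimate_background
from metamotif.infer import (
    InferenceConfig,
    InferenceState,
    MixingMatrix,
    dataset_log_likelihood,
    mumm_log_likelihood,
    nested_sample,
    pad_motif,
    propose_move,
    sample_state_from_prior,
)
from metamotif.model import ALPHA_MAX, ALPHA_MIN, Metamotif, PWM
from metamotif.simulate import sample_background_motifs

from conftest import mumm_enumeration_oracle, random_metamotif


class TestPadMotif:
    def test_zero_padding_is_identity(self, small_motifs, background):
        assert pad_motif(small_motifs[0], 0, background) is small_motifs[0]

    def test_padded_shape_and_content(self, rng, background):
        pwm = sample_background_motifs(1, 20, background, rng)[0]
        padded = pad_motif(pwm, 15, background)
        assert len(padded) == 50
        np.testing.assert_allclose(
            padded.weights[:15], np.tile(background.mean, (15, 1))
        )
        np.testing.assert_allclose(
            padded.weights[-15:], np.tile(background.mean, (15, 1))
        )
        np.testing.assert_allclose(padded.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_negative_padding_rejected(self, small_motifs, background):
        with pytest.raises(ValueError):
            pad_motif(small_motifs[0], -1, background)


class TestMummLikelihood:
    def test_empty_metamotif_set_is_pure_background(self, rng, background):
        from scipy.special import gammaln
        from metamotif.infer import INFERENCE_WEIGHT_FLOOR

        pwm = sample_background_motifs(1, 6, background, rng)[0]
        padded = pad_motif(pwm, 2, background)
        got = mumm_log_likelihood(padded, [], background, unpadded_length=6)
        a = background.alpha
        logb = gammaln(a).sum() - gammaln(a.sum())
        logx = np.log(padded.floored(INFERENCE_WEIGHT_FLOOR))
        expected = float((logx @ (a - 1.0) - logb).sum())
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("revcomp", [False, True])
    @pytest.mark.parametrize("l_max", [0, 2, 3])
    @pytest.mark.parametrize("n_mm", [1, 2])
    def test_dp_equals_exhaustive_path_enumeration(
        self, rng, background, revcomp, l_max, n_mm
    ):
        for trial in range(4):
            l_x = int(rng.integers(3, 9))
            pwm = sample_background_motifs(1, l_x, background, rng)[0]
            padded = pad_motif(pwm, l_max, background)
            mms = [
                random_metamotif(rng, int(rng.integers(2, 5)), f"m{k}")
                for k in range(n_mm)
            ]
            got = mumm_log_likelihood(
                padded, mms, background, revcomp=revcomp, unpadded_length=l_x
            )
            want = mumm_enumeration_oracle(padded, mms, background, revcomp, l_x)
            assert got == pytest.approx(want, rel=1e-9)

    def test_oversized_metamotif_contributes_no_paths(self, rng, background):
        pwm = sample_background_motifs(1, 4, background, rng)[0]
        huge = random_metamotif(rng, 12, "huge")
        with_m = mumm_log_likelihood(pwm, [huge], background)
        without = mumm_log_likelihood(pwm, [], background)
        assert with_m == pytest.approx(without, rel=1e-12)


class TestDatasetLikelihood:
    def _config(self, **kw):
        defaults = dict(
            num_metamotifs=1, min_length=3, max_length=4, expected_fraction=0.5
        )
        defaults.update(kw)
        return InferenceConfig(**defaults)

    def test_all_zero_mixing_is_background_plus_prior(self, rng, background):
        import math

        motifs = sample_background_motifs(5, 8, background, rng)
        cfg = self._config()
        mm = random_metamotif(rng, 3)
        state = InferenceState((mm,), MixingMatrix(np.zeros((1, 5), dtype=int)))
        got = dataset_log_likelihood(motifs, state, background, cfg)
        per_motif = sum(
            mumm_log_likelihood(
                pad_motif(m, cfg.max_length, background),
                [],
                background,
                unpadded_length=len(m),
            )
            for m in motifs
        )
        assert got == pytest.approx(per_motif + 5 * math.log(0.5), rel=1e-12)

    def test_single_pair_matches_mumm_plus_prior(self, rng, background):
        import math

        motifs = sample_background_motifs(1, 8, background, rng)
        cfg = self._config()
        mm = random_metamotif(rng, 3)
        state = InferenceState((mm,), MixingMatrix(np.ones((1, 1), dtype=int)))
        got = dataset_log_likelihood(motifs, state, background, cfg)
        want = mumm_log_likelihood(
            pad_motif(motifs[0], 4, background),
            [mm],
            background,
            unpadded_length=8,
        ) + math.log(0.5)
        assert got == pytest.approx(want, rel=1e-12)

    def test_switching_on_a_matching_metamotif_raises_likelihood(
        self, rng, background
    ):
        from metamotif.model import sample_pwm
        from metamotif.simulate import fixture_metamotifs

        fk = fixture_metamotifs()[0]
        motifs = sample_background_motifs(4, 20, background, rng)
        inst = sample_pwm(fk, rng)
        w = motifs[0].weights.copy()
        w[4 : 4 + len(fk)] = inst.weights
        motifs[0] = PWM(motifs[0].name, w)

        cfg = InferenceConfig(
            num_metamotifs=1, min_length=4, max_length=14, expected_fraction=0.5
        )
        clipped = Metamotif("fk", np.clip(fk.alpha, ALPHA_MIN, ALPHA_MAX))
        q_off = np.zeros((1, 4), dtype=int)
        q_on = q_off.copy()
        q_on[0, 0] = 1
        ll_off = dataset_log_likelihood(
            motifs, InferenceState((clipped,), MixingMatrix(q_off)), background, cfg
        )
        ll_on = dataset_log_likelihood(
            motifs, InferenceState((clipped,), MixingMatrix(q_on)), background, cfg
        )
        assert ll_on > ll_off


class TestMoves:
    def _state_and_config(self, rng, n=2, p=6):
        cfg = InferenceConfig(
            num_metamotifs=n, min_length=3, max_length=8, expected_fraction=0.3
        )
        return sample_state_from_prior(cfg, rng, p), cfg

    def test_proposals_keep_clip_and_length_invariants(self, rng):
        state, cfg = self._state_and_config(rng)
        for _ in range(10_000):
            state = propose_move(state, cfg, rng)
            for mm in state.metamotifs:
                assert cfg.min_length <= len(mm) <= cfg.max_length
                assert np.all(mm.alpha >= ALPHA_MIN - 1e-12)
                assert np.all(mm.alpha <= ALPHA_MAX + 1e-12)
            assert np.isin(state.mixing.entries, (0, 1)).all()

    def test_precision_move_preserves_mean(self, rng):
        # isolate the precision move by fixing the generator seed per trial
        state, cfg = self._state_and_config(rng, n=1)
        preserved = 0
        for trial in range(400):
            move_rng = np.random.default_rng(trial)
            new = propose_move(state, cfg, move_rng)
            old_mm, new_mm = state.metamotifs[0], new.metamotifs[0]
            if len(old_mm) != len(new_mm):
                continue
            changed = np.where(
                np.abs(old_mm.alpha - new_mm.alpha).sum(axis=1) > 1e-12
            )[0]
            if changed.size != 1:
                continue
            i = changed[0]
            mean_same = np.allclose(
                old_mm.means[i], new_mm.means[i], atol=1e-9
            )
            prec_same = np.isclose(
                old_mm.precisions[i], new_mm.precisions[i], atol=1e-9
            )
            if mean_same and not prec_same:
                preserved += 1  # a precision move
            if prec_same and not mean_same:
                preserved += 1  # a mean move
        assert preserved > 50  # both constrained move types occur and hold

    def test_prior_sample_statistics(self, rng):
        cfg = InferenceConfig(
            num_metamotifs=2, min_length=3, max_length=7, expected_fraction=0.3
        )
        occupancies = []
        lengths = set()
        for _ in range(2_000):
            st = sample_state_from_prior(cfg, rng, 10)
            occupancies.append(st.mixing.entries.mean())
            for mm in st.metamotifs:
                lengths.add(len(mm))
                assert np.all(mm.alpha >= ALPHA_MIN)
                assert np.all(mm.alpha <= ALPHA_MAX)
        # Bernoulli(0.3) occupancy within 3 standard errors
        se = np.sqrt(0.3 * 0.7 / (2_000 * 20))
        assert abs(np.mean(occupancies) - 0.3) < 3 * se
        assert lengths == {3, 4, 5, 6, 7}


@pytest.fixture(scope="module")
def tiny_run():
    rng = np.random.default_rng(5)
    motifs = sample_background_motifs(8, 10, rng=rng)
    cfg = InferenceConfig(
        num_metamotifs=1,
        min_length=3,
        max_length=6,
        expected_fraction=0.3,
        ensemble_size=10,
        iterations=60,
        moves_per_decorrelation=5,
        seed=3,
    )
    return motifs, cfg, nested_sample(motifs, cfg)


class TestNestedSampling:
    def test_removed_likelihoods_non_decreasing(self, tiny_run):
        _, _, res = tiny_run
        diffs = np.diff(res.removed_log_likelihoods)
        assert np.all(diffs >= -1e-9)

    def test_seeded_determinism(self, tiny_run):
        motifs, cfg, res = tiny_run
        res2 = nested_sample(motifs, cfg)
        np.testing.assert_allclose(
            res.best_state.log_likelihood, res2.best_state.log_likelihood
        )
        for a, b in zip(res.best_state.metamotifs, res2.best_state.metamotifs):
            np.testing.assert_allclose(a.alpha, b.alpha)
        np.testing.assert_array_equal(
            res.best_state.mixing.entries, res2.best_state.mixing.entries
        )

    def test_posterior_weights_normalised(self, tiny_run):
        _, _, res = tiny_run
        total = sum(w for _, w in res.posterior)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.isfinite(res.log_evidence_trace))

    def test_custom_background_respected(self, tiny_run, background):
        motifs, cfg, _ = tiny_run
        res = nested_sample(motifs, cfg, background=background)
        assert np.isfinite(res.best_state.log_likelihood)
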