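"""Filter-to-PWM extraction, nullification influence, and interaction fits."""

import numpy as np
import pytest

from epimotif.cnn import ModelConfig, SequenceCNN
from epimotif.dataset import one_hot
from epimotif.interpret import (ExtractionConfig, activation_threshold,
                                extract_pwm, first_layer_activations,
                                influence, influence_heatmap_table,
                                influence_table, interaction, nullify,
                                nullification_means, top_motifs)
from epimotif.pwm import information_content

from conftest import sharp_pwm, random_sequences, implant, sample_instance


class TestActivationThreshold:
    @pytest.mark.parametrize("amax, amin, beta, expect",
                             [(1.0, 0.0, 0.5, 0.5),
                              (2.0, 0.5, 0.4, 0.6),
                              (3.0, 3.0, 0.5, 0.0)])
    def test_arithmetic(self, amax, amin, beta, expect):
        assert activation_threshold(amax, amin, beta) == pytest.approx(expect)

    @pytest.mark.parametrize("beta", [0.0, 1.0, -0.2, 1.5])
    def test_beta_range(self, beta):
        with pytest.raises(ValueError):
            activation_threshold(1.0, 0.0, beta)

    def test_inverted_extremes(self):
        with pytest.raises(ValueError):
            activation_threshold(0.0, 1.0, 0.5)


class TestFirstLayerActivations:
    def test_nonnegative_everywhere(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        acts = first_layer_activations(tiny_trained_model, X[:16])
        assert np.all(acts >= 0)

    def test_all_n_input_position_independent(self, tiny_trained_model):
        X = one_hot("N" * 100)[None]
        acts = first_layer_activations(tiny_trained_model, X)
        assert np.allclose(acts, acts[:, :1, :], atol=1e-6)

    def test_unfitted_model_refused(self, rng):
        cfg = ModelConfig(n_tasks=1, conv_filters=(2, 2, 2), conv_widths=(5, 3, 3),
                          pool_sizes=(2, 2, 2), fc_units=4, context_size=60)
        model = SequenceCNN(None, cfg)
        with pytest.raises(RuntimeError):
            first_layer_activations(model, np.zeros((1, 60, 4), dtype=np.float32))

    def test_single_filter_toy_matches_direct_convolution(self, rng):
        """Hand-computed sum_{l,d} W_ld X_{i+l,d} with ReLU equals the layer."""
        cfg = ModelConfig(n_tasks=1, conv_filters=(1, 2, 2), conv_widths=(4, 3, 3),
                          pool_sizes=(2, 2, 2), fc_units=4, context_size=40,
                          dtype="float64")
        model = SequenceCNN(None, cfg)
        model.fitted = True
        X = np.stack([one_hot(s, dtype=np.float64)
                      for s in random_sequences(rng, 3, 40)])
        acts = model.conv1_activations(X)
        W = model.layers[0].params["W"].reshape(4, 4, 1)
        b = model.layers[0].params["b"][0]
        for n in range(3):
            for i in range(40 - 4 + 1):
                direct = sum(W[l, d, 0] * X[n, i + l, d]
                             for l in range(4) for d in range(4)) + b
                assert acts[n, i, 0] == pytest.approx(max(direct, 0.0))


class EngineeredModel:
    """1-filter model whose first layer is the exact log-odds of a PWM."""

    def __init__(self, pwm, context=60, dtype="float64"):
        cfg = ModelConfig(n_tasks=1, conv_filters=(1, 2, 2),
                          conv_widths=(pwm.width, 3, 3), pool_sizes=(2, 2, 2),
                          fc_units=4, context_size=context, dtype=dtype)
        self.model = SequenceCNN(None, cfg)
        self.model.fitted = True
        lo = np.log2(pwm.freq_matrix / 0.25)
        W = self.model.layers[0].params["W"]
        W[:] = lo.reshape(-1, 1)
        self.model.layers[0].params["b"][:] = 0.0


class TestExtractPwm:
    def test_engineered_filter_recovers_planted_pwm(self, rng):
        planted = sharp_pwm("ACGTTGCAGT", p=0.9)
        em = EngineeredModel(planted)
        seqs = []
        for _ in range(150):
            s = random_sequences(rng, 1, 60)[0]
            s = implant(s, sample_instance(planted, rng), int(rng.integers(0, 50)))
            seqs.append(one_hot(s, dtype=np.float64))
        X = np.stack(seqs)
        pwm = extract_pwm(em.model, 0, X)
        assert pwm is not None
        tv = np.abs(pwm.freq_matrix - planted.freq_matrix).sum(axis=1) / 2
        assert np.all(tv <= 0.1)

    def test_extraction_equals_bruteforce_threshold_counting(self, rng):
        """Implementation vs direct k-mer scoring + counting at each beta."""
        planted = sharp_pwm("TTGACCAA", p=0.85)
        em = EngineeredModel(planted)
        X = np.stack([one_hot(s, dtype=np.float64)
                      for s in random_sequences(rng, 40, 60)])
        cfg = ExtractionConfig()
        got = extract_pwm(em.model, 0, X, cfg)
        acts = em.model.conv1_activations(X)[:, :, 0]
        amax, amin = acts.max(), acts.min()
        best = None
        w = planted.width
        for beta in cfg.beta_grid:
            thr = (amax - amin) * beta
            counts = np.full((w, 4), cfg.pseudocount)
            n_sites = 0
            for n in range(X.shape[0]):
                for p in range(acts.shape[1]):
                    if acts[n, p] > thr:
                        counts += X[n, p:p + w, :]
                        n_sites += 1
            if n_sites == 0:
                continue
            freq = counts / counts.sum(axis=1, keepdims=True)
            ic = information_content(freq)
            if best is None or ic > best[0]:
                best = (ic, freq, beta, n_sites)
        if got is None:
            assert best is None or best[0] <= 0
        else:
            assert got.beta_used == best[2]
            assert got.n_sites == best[3]
            assert np.allclose(got.freq_matrix, best[1], atol=1e-9)

    def test_dead_filter_returns_none(self, rng):
        planted = sharp_pwm("ACGTACGT")
        em = EngineeredModel(planted)
        em.model.layers[0].params["W"][:] = -1.0  # never activates post-ReLU
        X = np.stack([one_hot(s, dtype=np.float64)
                      for s in random_sequences(rng, 10, 60)])
        assert extract_pwm(em.model, 0, X) is None

    def test_empty_test_set_error(self, tiny_trained_model):
        with pytest.raises(ValueError):
            extract_pwm(tiny_trained_model, 0,
                        np.zeros((0, 100, 4), dtype=np.float32))

    def test_invalid_beta_grid(self):
        with pytest.raises(ValueError):
            ExtractionConfig(beta_grid=(0.0, 0.5))


class TestNullify:
    def test_mean_equals_bruteforce_average(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        acts = tiny_trained_model.conv1_activations(X)
        means = nullification_means(tiny_trained_model, [0, 3], X)
        assert means[0] == pytest.approx(float(acts[:, :, 0].mean()))
        assert means[3] == pytest.approx(float(acts[:, :, 3].mean()))

    def test_empty_set_is_identity(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        view = nullify(tiny_trained_model, [], X)
        assert np.array_equal(view.predict(X[:6]), tiny_trained_model.predict(X[:6]))

    def test_unknown_filter_index(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        with pytest.raises(KeyError):
            nullify(tiny_trained_model, [99], X)

    def test_original_model_untouched(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        before = tiny_trained_model.predict(X[:4])
        nullify(tiny_trained_model, [1], X).predict(X[:4])
        assert np.array_equal(tiny_trained_model.predict(X[:4]), before)


class TestInfluence:
    def test_zero_when_predictions_unchanged(self, rng):
        """A filter with a constant (dead) activation map changes nothing
        when replaced by its mean, so its influence is exactly zero."""
        planted = sharp_pwm("ACGTTGCAGT")
        em = EngineeredModel(planted)
        em.model.layers[0].params["b"][:] = -100.0  # ReLU clamps the map to 0
        X = np.stack([one_hot(s, dtype=np.float64)
                      for s in random_sequences(rng, 12, 60)])
        rec = influence(em.model, 0, X)
        assert rec.influence == 0.0

    def test_deterministic(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        a = influence(tiny_trained_model, 0, X)
        b = influence(tiny_trained_model, 0, X)
        assert a.influence == b.influence

    def test_invariant_to_test_set_order(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        perm = np.random.default_rng(0).permutation(X.shape[0])
        a = influence(tiny_trained_model, 2, X)
        b = influence(tiny_trained_model, 2, X[perm])
        assert a.influence == pytest.approx(b.influence, rel=1e-6)

    def test_all_equals_sum_of_tasks(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        rec = influence(tiny_trained_model, 1, X, task="all")
        assert rec.influence == pytest.approx(sum(rec.per_task.values()))

    def test_empty_test_set(self, tiny_trained_model):
        with pytest.raises(ValueError):
            influence(tiny_trained_model, 0, np.zeros((0, 100, 4), dtype=np.float32))

    def test_heatmap_table_matches_individual_calls(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        pwms = {k: sharp_pwm("ACGTACGTAC", name=f"f{k}") for k in range(4)}
        tab = influence_heatmap_table(tiny_trained_model, pwms, X, top_n=100)
        assert len(tab) == 4
        col = tiny_trained_model.dataset.task_names[0]
        maxes = tab[col].to_numpy()
        assert np.all(np.diff(maxes) <= 1e-12)  # sorted descending by row max
        for _, row in tab.iterrows():
            rec = influence(tiny_trained_model, int(row["filter"]), X,
                            task=col)
            assert row[col] == pytest.approx(rec.influence)


class TestTopMotifs:
    def _records(self, scores):
        from epimotif.interpret import InfluenceRecord
        return [InfluenceRecord(i, "all", s, {}, 10, s / 10)
                for i, s in enumerate(scores)]

    def test_k_larger_than_n_returns_all(self):
        recs = self._records([3.0, 1.0])
        assert len(top_motifs(recs, k=10)) == 2

    def test_sorted_descending_with_tiebreak(self):
        recs = self._records([1.0, 3.0, 1.0, 5.0])
        out = top_motifs(recs, k=3)
        assert [r.filter_index for r in out] == [3, 1, 0]

    def test_agrees_with_full_sort(self, rng):
        scores = rng.random(20).tolist()
        recs = self._records(scores)
        out = top_motifs(recs, k=5)
        expect = sorted(range(20), key=lambda i: (-scores[i], i))[:5]
        assert [r.filter_index for r in out] == expect


class TestInteraction:
    def test_same_seed_identical(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        a = interaction(tiny_trained_model, 0, 1, 0, X, n_sequences=50, seed=3)
        b = interaction(tiny_trained_model, 0, 1, 0, X, n_sequences=50, seed=3)
        assert a.gamma == b.gamma and a.p_value == b.p_value

    def test_symmetric_in_pair(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        ij = interaction(tiny_trained_model, 0, 1, 0, X, n_sequences=50, seed=3)
        ji = interaction(tiny_trained_model, 1, 0, 0, X, n_sequences=50, seed=3)
        assert ij.gamma == pytest.approx(ji.gamma, rel=1e-9)
        assert ij.alpha == pytest.approx(ji.beta, rel=1e-6)

    def test_identical_pair_rejected(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        with pytest.raises(ValueError):
            interaction(tiny_trained_model, 2, 2, 0, X)

    def test_too_few_sequences(self, tiny_trained_model):
        X, _ = tiny_trained_model.dataset.subset("test")
        with pytest.raises(ValueError):
            interaction(tiny_trained_model, 0, 1, 0, X, n_sequences=5)

    def test_gamma_matches_statsmodels_oracle(self, tiny_trained_model):
        """Refit the no-intercept regression from the same deltas by the
        normal equations and compare gamma."""
        X, _ = tiny_trained_model.dataset.subset("test")
        rec = interaction(tiny_trained_model, 0, 1, 0, X, n_sequences=60, seed=8)
        if rec.degenerate:
            pytest.skip("degenerate regressors in this toy model")
        model = tiny_trained_model
        rng = np.random.default_rng(8)
        idx = rng.choice(X.shape[0], size=60, replace=60 > X.shape[0])
        acts = model.conv1_activations(X)
        from epimotif.interpret import nullification_means
        vals = nullification_means(model, [0, 1], X, acts)
        sub = acts[idx]
        p0 = model.predict_from_acts(sub)[:, 0]
        pi = model.predict_from_acts(sub, nullify={0: vals[0]})[:, 0]
        pj = model.predict_from_acts(sub, nullify={1: vals[1]})[:, 0]
        pij = model.predict_from_acts(sub, nullify=vals)[:, 0]
        di, dj, dij = (p0 - pi) ** 2, (p0 - pj) ** 2, (p0 - pij) ** 2
        A = np.column_stack([di, dj, di * dj]).astype(np.float64)
        coef = np.linalg.lstsq(A, dij.astype(np.float64), rcond=None)[0]
        assert rec.gamma == pytest.approx(coef[2], rel=1e-6, abs=1e-10)
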