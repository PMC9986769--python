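"""Relational-unit census, forward-pass contracts, loss, and dropout variants."""

import numpy as np
import pytest

import rrnlandmarks as r
from rrnlandmarks import Landmark as L
from rrnlandmarks.model import PredictionSet, substream, variational_dropout_layer


@pytest.fixture(scope="module")
def five_model(tiny_mlp_spec):
    return r.build_rrn(r.builtin_configuration("five"), tiny_mlp_spec, seed=5)


class TestCensus:
    @pytest.mark.parametrize("name,total", [
        ("five", 25), ("three-regular", 9), ("three-cross", 9),
        ("six", 36), ("nine", 81),
    ])
    def test_builtin_ru_counts(self, tiny_mlp_spec, name, total):
        model = r.build_rrn(r.builtin_configuration(name), tiny_mlp_spec, seed=0)
        assert r.count_relational_units(model) == total
        n = model.config.n
        assert len(model.pairwise_units) == n * (n - 1)
        assert len(model.global_units) == n

    def test_two_input_configuration_has_four_rus(self, tiny_mlp_spec):
        cfg = r.ConfigurationSpec("two", (L.Me, L.CdL), (L.Na,))
        model = r.build_rrn(cfg, tiny_mlp_spec, seed=0)
        assert r.count_relational_units(model) == 4

    def test_global_unit_output_width_is_3m(self, five_model):
        assert five_model.output_dim == 3 * five_model.config.m

    def test_seeded_initialization_is_deterministic(self, tiny_dense_spec):
        cfg = r.builtin_configuration("five")
        a = r.build_rrn(cfg, tiny_dense_spec, seed=9)
        b = r.build_rrn(cfg, tiny_dense_spec, seed=9)
        for (_, ta), (_, tb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(ta.data, tb.data)


class TestPairwiseRelation:
    def test_output_length_and_determinism(self, five_model, complete_case):
        cfg = five_model.config
        feats = r.feature_batch(complete_case, cfg)
        v1 = five_model.pairwise_relation(L.Me, L.CdL, feats[(L.Me, L.CdL)])
        v2 = five_model.pairwise_relation(L.Me, L.CdL, feats[(L.Me, L.CdL)])
        assert v1.shape == (five_model.ru_spec.relation_dim,)
        np.testing.assert_array_equal(v1, v2)  # inference is deterministic

    def test_units_are_unshared(self, tiny_mlp_spec, complete_case):
        """Perturbing one pair's parameters changes only that pair's output."""
        cfg = r.builtin_configuration("three-regular")
        model = r.build_rrn(cfg, tiny_mlp_spec, seed=3)
        feats = r.feature_batch(complete_case, cfg)
        before = {p: model.pairwise_relation(*p, feats[p]) for p in model.pairs}
        victim = model.pairs[2]
        idx = model.pairs.index(victim)
        for _, t in model._pairwise.params():
            t.data[idx] += 0.5
        after = {p: model.pairwise_relation(*p, feats[p]) for p in model.pairs}
        for p in model.pairs:
            if p == victim:
                assert not np.allclose(before[p], after[p])
            else:
                np.testing.assert_array_equal(before[p], after[p])

    def test_same_landmark_rejected(self, five_model):
        with pytest.raises(r.ValidationError):
            five_model.pairwise_relation(L.Me, L.Me, np.zeros(19))


class TestAggregateMean:
    def test_identical_relations_average_to_themselves(self, five_model):
        v = np.arange(8.0)
        rels = {(L.Me, j): v for j in five_model.config.input_set if j is not L.Me}
        np.testing.assert_allclose(five_model.aggregate_mean(L.Me, rels), v)

    def test_hand_mean_n3(self, tiny_mlp_spec):
        cfg = r.builtin_configuration("three-regular")
        model = r.build_rrn(cfg, tiny_mlp_spec, seed=0)
        e0 = np.zeros(8); e0[0] = 1.0
        e1 = np.zeros(8); e1[1] = 1.0
        rels = {(L.Me, L.CdL): e0, (L.Me, L.CdR): e1}
        out = model.aggregate_mean(L.Me, rels)
        np.testing.assert_allclose(out[:2], [0.5, 0.5])

    def test_iteration_order_free(self, five_model):
        rng = np.random.default_rng(0)
        rels = {(L.Me, j): rng.normal(size=8)
                for j in five_model.config.input_set if j is not L.Me}
        fwd = five_model.aggregate_mean(L.Me, rels)
        rev = five_model.aggregate_mean(L.Me, dict(reversed(list(rels.items()))))
        np.testing.assert_allclose(fwd, rev)

    def test_missing_pair_rejected(self, five_model):
        with pytest.raises(r.ValidationError):
            five_model.aggregate_mean(L.Me, {(L.Me, L.CdL): np.zeros(8)})


class TestPredict:
    def test_consensus_is_mean_of_per_input(self, five_model, complete_case):
        ps = r.predict(five_model, complete_case)
        assert ps.consensus.shape == (9, 3)
        stack = np.stack(list(ps.per_input_predictions.values()))
        assert stack.shape == (5, 9, 3)
        np.testing.assert_allclose(ps.consensus, stack.mean(axis=0), atol=1e-6)

    def test_input_order_permutation_invariance(self, tiny_mlp_spec,
                                                complete_case):
        base = r.builtin_configuration("five")
        shuffled = r.ConfigurationSpec("five", tuple(reversed(base.input_set)),
                                       base.target_set)
        a = r.predict(r.build_rrn(base, tiny_mlp_spec, seed=4), complete_case)
        b = r.predict(r.build_rrn(shuffled, tiny_mlp_spec, seed=4), complete_case)
        np.testing.assert_allclose(a.consensus, b.consensus, atol=1e-6)

    def test_missing_input_landmark_rejected(self, five_model):
        case = r.LandmarkCase("c", np.ones(3), {L.Me: np.zeros(3)})
        with pytest.raises(r.DataError):
            r.predict(five_model, case)


class TestLoss:
    def test_zero_iff_exact_fit(self, five_model, complete_case):
        truth = {lm: complete_case.positions[lm]
                 for lm in five_model.config.target_set}
        exact = PredictionSet(
            target_set=five_model.config.target_set,
            per_input_predictions={
                i: np.stack([truth[lm] for lm in five_model.config.target_set])
                for i in five_model.config.input_set},
            consensus=np.stack([truth[lm]
                                for lm in five_model.config.target_set]))
        assert r.rrn_loss(exact, complete_case, five_model.config) == 0.0
        exact.per_input_predictions[L.Me][0] += 0.1
        assert r.rrn_loss(exact, complete_case, five_model.config) > 0.0

    def test_single_term_hand_value(self):
        """n=1, m=1, residual (1,2,2) -> squared norm 9."""
        cfg = r.ConfigurationSpec("two", (L.Me, L.CdL), (L.Na,))
        case = r.LandmarkCase("c", np.ones(3), {
            L.Me: np.zeros(3), L.CdL: np.ones(3), L.Na: np.zeros(3)})
        ps = PredictionSet(target_set=(L.Na,),
                           per_input_predictions={L.Me: np.array([[1.0, 2.0, 2.0]])},
                           consensus=np.array([[1.0, 2.0, 2.0]]))
        assert r.rrn_loss(ps, case, cfg) == pytest.approx(9.0)

    def test_matches_brute_force_double_loop(self, five_model, complete_case):
        rng = np.random.default_rng(8)
        cfg = five_model.config
        preds = {i: rng.normal(size=(cfg.m, 3))
                 for i in cfg.input_set}
        ps = PredictionSet(target_set=cfg.target_set,
                           per_input_predictions=preds,
                           consensus=np.mean(list(preds.values()), axis=0))
        # independent oracle: explicit double loop over inputs and targets
        total = 0.0
        for i in cfg.input_set:
            for k, lm in enumerate(cfg.target_set):
                diff = preds[i][k] - complete_case.positions[lm]
                total += float(diff @ diff)
        expected = total / (cfg.n * cfg.m)
        assert r.rrn_loss(ps, complete_case, cfg) == pytest.approx(expected,
                                                                   abs=1e-9)

    def test_missing_target_truth_rejected(self, five_model):
        case = r.LandmarkCase("c", np.ones(3), {
            lm: np.zeros(3) for lm in five_model.config.input_set})
        ps = r.predict(five_model, case)
        with pytest.raises(r.DataError):
            r.rrn_loss(ps, case, five_model.config)


class TestTargetedDropout:
    def test_gamma_zero_keeps_everything(self):
        mask = r.targeted_dropout_mask(np.arange(10.0), gamma=0.0, alpha=1.0,
                                       seed=0)
        np.testing.assert_array_equal(mask, 1.0)

    def test_hand_example_two_smallest_dropped(self):
        mask = r.targeted_dropout_mask([0.1, -0.9, 0.3, 2.0], gamma=0.5,
                                       alpha=1.0, seed=0)
        np.testing.assert_array_equal(mask, [0.0, 1.0, 0.0, 1.0])

    def test_membership_matches_brute_force_sort(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            w = rng.normal(size=rng.integers(2, 60))
            gamma = float(rng.uniform(0, 1))
            mask = r.targeted_dropout_mask(w, gamma=gamma, alpha=1.0, seed=1)
            k = int(np.floor(gamma * w.size))
            target = sorted(range(w.size), key=lambda i: (abs(w[i]), i))[:k]
            np.testing.assert_array_equal(np.flatnonzero(mask == 0.0),
                                          np.sort(target))

    def test_empirical_drop_rate_is_alpha(self):
        w = np.linspace(0.1, 1.0, 40)
        k = 20  # gamma=0.5 target set
        dropped = 0
        for trial in range(4000):
            mask = r.targeted_dropout_mask(w, gamma=0.5, alpha=0.5, seed=trial)
            assert np.all(mask[k:] == 1.0)  # non-target weights untouched
            dropped += int((mask[:k] == 0.0).sum())
        rate = dropped / (4000 * k)
        assert rate == pytest.approx(0.5, abs=0.02)


class TestVariationalDropout:
    def _layer(self, dim=6):
        return r.VariationalDropout(1, dim, "vd", init_log_alpha=-2.0)

    def test_inference_equals_identity(self):
        layer = self._layer()
        x = np.random.default_rng(0).normal(size=(1, 4, 6))
        np.testing.assert_array_equal(
            variational_dropout_layer(x, layer, mode="infer"), x)

    def test_zero_variance_training_equals_inference(self):
        layer = r.VariationalDropout(1, 6, "vd", init_log_alpha=-60.0)
        x = np.random.default_rng(1).normal(size=(1, 4, 6))
        out = variational_dropout_layer(x, layer, mode="train",
                                        rng=np.random.default_rng(2))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_monte_carlo_mean_converges_to_inference(self):
        layer = self._layer()
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 1, 6))
        draws = np.stack([
            variational_dropout_layer(x, layer, mode="train", rng=rng)
            for _ in range(10_000)])
        alpha = np.exp(-2.0)
        se = np.abs(x) * np.sqrt(alpha) / np.sqrt(10_000)
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - x),
                                     3 * se + 1e-12)

    def test_invalid_mode_rejected(self):
        with pytest.raises(r.ValidationError):
            variational_dropout_layer(np.zeros((1, 1, 6)), self._layer(),
                                      mode="banana")


class TestTrainingMechanics:
    @pytest.mark.parametrize("ru", ["mlp", "dense_block"])
    def test_gradient_step_decreases_loss(self, template, ru):
        """End-to-end differentiability: a small SGD step reduces the loss."""
        spec = r.RUSpec(ru_type=ru, relation_dim=8, mlp_hidden=(16, 16),
                        dtype="float64")
        cfg = r.builtin_configuration("five")
        model = r.build_rrn(cfg, spec, seed=1)
        cases = [r.sample_case(template, "normal", r.DEFAULT_SPACING, seed=s)
                 for s in range(8)]
        from rrnlandmarks.training import _cohort_arrays
        _, feats, me, targets = _cohort_arrays(cases, cfg)
        X = np.ascontiguousarray(np.swapaxes(feats, 0, 1))
        model.set_offset_normalization(targets - me[:, None, :])
        loss0 = model.training_loss(X, me, targets)
        loss0.backward()
        for _, t in model.parameters():
            if t.grad is not None:
                t.data -= 1e-6 * t.grad
        loss1 = model.training_loss(X, me, targets)
        assert float(loss1.data) < float(loss0.data)

    def test_kl_term_added_for_variational(self, template):
        spec = r.RUSpec(ru_type="mlp", relation_dim=8, mlp_hidden=(16, 16),
                        dropout=r.DropoutSpec(variant="variational"),
                        dtype="float64")
        cfg = r.builtin_configuration("three-regular")
        model = r.build_rrn(cfg, spec, seed=1)
        case = r.sample_case(template, "normal", r.DEFAULT_SPACING, seed=1)
        from rrnlandmarks.training import _cohort_arrays
        _, feats, me, targets = _cohort_arrays([case], cfg)
        X = np.ascontiguousarray(np.swapaxes(feats, 0, 1))
        rng = substream(0, "noise")
        loss = model.training_loss(X, me, targets, rng=rng)
        assert np.isfinite(float(loss.data))
        loss.backward()
        vd_params = [t for name, t in model.parameters() if "log_alpha" in name]
        assert vd_params and all(t.grad is not None for t in vd_params)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_dense_spec,
                                              template, complete_case):
        cfg = r.builtin_configuration("five")
        model = r.build_rrn(cfg, tiny_dense_spec, seed=2)
        cases = [r.sample_case(template, "normal", r.DEFAULT_SPACING, seed=s)
                 for s in range(6)]
        tc = r.TrainConfig(epochs=1, seed=0, ru_spec=tiny_dense_spec)
        model, _ = r.train(model, cases, tc)
        before = r.predict(model, complete_case).consensus
        r.save_checkpoint(model, tmp_path / "ckpt.npz", extra={"note": "test"})
        loaded = r.load_checkpoint(tmp_path / "ckpt.npz")
        after = r.predict(loaded, complete_case).consensus
        np.testing.assert_allclose(before, after, atol=1e-7)
        assert r.count_relational_units(loaded) == 25
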