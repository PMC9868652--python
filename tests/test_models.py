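"""Structured network: layer widths, masking/sparsity contracts,
parameter accounting, determinism, and checkpointing."""

import numpy as np
import pytest

import strudem as sd
from strudem.models import ModelSpec, build_model, forward, load_checkpoint, \
    save_checkpoint


class TestStructure:
    @pytest.mark.parametrize("level,strategy,width", [
        ("base", None, 206),
        ("combo", None, 32),
        ("composite", "g1", 5),
        ("composite", "g2", 3),
        ("composite", "g3", 7),
    ])
    def test_final_layer_width(self, panel, level, strategy, width):
        m = build_model(panel, ModelSpec(level=level, strategy=strategy))
        assert m.final_layer_width == width

    def test_toy_base_width(self):
        tax = sd.toy_taxonomy(3, 3, 1)
        m = build_model(tax, ModelSpec(level="base"))
        assert m.final_layer_width == 3

    def test_missing_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            ModelSpec(level="composite", strategy=None)

    def test_embedding_widths_in_forward(self, panel):
        m = build_model(panel, ModelSpec(level="composite", strategy="g1"),
                        n_bins=4)
        X = np.random.default_rng(0).normal(size=(7, 206, 4))
        out = m.embeddings(X)
        assert out.level1.shape == (7, 206)
        assert out.level2.shape == (7, 32)
        assert out.level3.shape == (7, 5)
        assert out.logits.shape == (7, 2)

    def test_parameter_count_closed_form(self, toy_tax):
        # toy: 10 variables in 5 combos of 2, 2 composites over (3, 2) combos
        H, B = 8, 6
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1",
                                           embed_hidden=H), n_bins=B)
        V, C, K = 10, 5, 2
        expected = (V * B * H + V * H      # per-variable layer 1
                    + V * H + V            # per-variable layer 2
                    + V + C                # combo weights (2 members each) + bias
                    + C + K                # composite weights + bias
                    + 2 * K + 2)           # prediction head
        assert m.n_parameters() == expected


class TestForward:
    def test_zero_input_gives_even_logits(self, toy_tax):
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1"),
                        n_bins=5)
        out = m.embeddings(np.zeros((3, 10, 5)))
        assert np.allclose(out.logits, np.log(0.5))
        assert np.allclose(np.exp(out.logits).sum(axis=1), 1.0)

    def test_rows_are_probabilities(self, toy_cohort, toy_tax):
        tc = toy_cohort["tc"]
        m = build_model(toy_tax, ModelSpec(level="combo"), n_bins=tc.n_bins)
        p = m.predict_proba(tc.values)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_forward_deterministic(self, toy_cohort, toy_tax):
        tc = toy_cohort["tc"]
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1"),
                        n_bins=tc.n_bins)
        a = m.predict_log_proba(tc.values)
        b = m.predict_log_proba(tc.values)
        assert np.array_equal(a, b)

    def test_shape_error_names_axis(self, toy_tax):
        m = build_model(toy_tax, ModelSpec(level="base"), n_bins=5)
        with pytest.raises(ValueError, match="variables axis"):
            m.predict_proba(np.zeros((2, 9, 5)))
        with pytest.raises(ValueError, match="bins axis"):
            m.predict_proba(np.zeros((2, 10, 7)))

    def test_seeded_init_reproducible(self, toy_tax):
        spec = ModelSpec(level="composite", strategy="g1", seed=13)
        m1 = build_model(toy_tax, spec, n_bins=5)
        m2 = build_model(toy_tax, spec, n_bins=5)
        for k in m1.weights_:
            assert np.array_equal(m1.weights_[k], m2.weights_[k])

    def test_forward_rejects_reordered_variables(self, toy_tax, toy_cohort):
        tc = toy_cohort["tc"]
        m = build_model(toy_tax, ModelSpec(level="base"), n_bins=tc.n_bins)
        shuffled = sd.TensorizedCohort(
            patients=tc.patients, variables=list(reversed(tc.variables)),
            values=tc.values, bin_edges=tc.bin_edges, labels=tc.labels)
        with pytest.raises(ValueError, match="variables axis"):
            forward(m, shuffled)


class TestStructuralSparsity:
    def test_perturbation_confined_to_combo(self, toy_tax):
        """Changing a variable's input moves only its own combo (and the
        combo's composite) embedding."""
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1"),
                        n_bins=5)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 10, 5))
        base = m.embeddings(X)
        v = toy_tax.variables.index("var_3")
        combo = toy_tax.combo_map["var_3"]
        ci = m.combos_.index(combo)
        comp = toy_tax.strategies["g1"][combo]
        ki = m.composites_.index(comp)
        X2 = X.copy()
        X2[:, v, :] += 1.0
        pert = m.embeddings(X2)
        d2 = np.abs(pert.level2 - base.level2)
        d3 = np.abs(pert.level3 - base.level3)
        assert (d2[:, ci] > 0).all()
        d2[:, ci] = 0
        assert np.all(d2 == 0)
        d3[:, ki] = 0
        assert np.all(d3 == 0)

    def test_finite_difference_gradient_zero_across_groups(self, panel):
        """Finite differences: d(level-2 of combo c)/d(input of v) == 0
        exactly whenever v is not a member of c; analogous at level 3."""
        m = build_model(panel, ModelSpec(level="composite", strategy="g1"),
                        n_bins=3)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 206, 3))
        base = m.embeddings(X)
        for v in rng.choice(206, size=6, replace=False):
            combo = panel.combo_map[panel.variables[v]]
            ci = m.combos_.index(combo)
            ki = m.composites_.index(panel.strategies["g1"][combo])
            X2 = X.copy()
            X2[:, v, rng.integers(3)] += 0.37
            out = m.embeddings(X2)
            g2 = out.level2 - base.level2
            g3 = out.level3 - base.level3
            g2[:, ci] = 0
            g3[:, ki] = 0
            assert np.all(g2 == 0)
            assert np.all(g3 == 0)

    def test_masked_weights_stay_zero_through_training(self, toy_cohort,
                                                       toy_tax):
        tc = toy_cohort["tc"]
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1"))
        m.set_params(max_epochs=3)
        m.fit(tc.values, tc.labels)
        assert np.all(m.weights_["A"][m.combo_mask_ == 0] == 0)
        assert np.all(m.weights_["G"][m.composite_mask_ == 0] == 0)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, toy_tax, toy_cohort):
        tc = toy_cohort["tc"]
        m = build_model(toy_tax, ModelSpec(level="composite", strategy="g1"))
        m.set_params(max_epochs=2)
        m.fit(tc.values, tc.labels)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        back = load_checkpoint(path, toy_tax)
        assert np.array_equal(back.predict_log_proba(tc.values),
                              m.predict_log_proba(tc.values))

    def test_refuses_mismatched_taxonomy(self, tmp_path, toy_tax):
        m = build_model(toy_tax, ModelSpec(level="base"), n_bins=4)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        other = sd.toy_taxonomy(12, 6, 2)
        with pytest.raises(ValueError, match="taxonomy"):
            load_checkpoint(path, other)
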