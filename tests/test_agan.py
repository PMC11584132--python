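"""The adversarial imputer: building blocks, losses, training, end-to-end."""

import math

import numpy as np
import pytest

from aganimpute import (
    AGANImputer,
    AttributeVector,
    MixedTypeTable,
    NormalizationParams,
    SyntheticSpec,
    TrainingConfig,
    attribute_projection,
    build_mask,
    generate,
    impute,
    infer_attributes,
    normalize,
    swish,
)
from aganimpute.amputate import AmputationSpec, ampute_mcar
from aganimpute.gan import (
    assemble_input,
    compose_imputed,
    d_loss,
    g_loss,
    gradient_penalty,
    train,
)
from aganimpute.networks import MLP
from aganimpute.table import ShapeMismatchError


class TestSwish:
    def test_zero_is_fixed_point(self):
        for beta in (0.1, 1.0, 7.0):
            assert swish(0.0, beta) == 0.0

    def test_value_at_one(self):
        assert math.isclose(swish(1.0, 1.0), 1 / (1 + math.exp(-1)), rel_tol=1e-12)

    def test_approaches_identity_for_large_x(self):
        assert abs(swish(50.0, 1.0) / 50.0 - 1.0) < 1e-12

    def test_closed_form_on_grid(self):
        xs = np.linspace(-8, 8, 1000)
        np.testing.assert_allclose(
            swish(xs, 1.7), xs / (1 + np.exp(-1.7 * xs)), atol=1e-12
        )


class TestAssembleInput:
    def test_fully_observed_returns_x(self, rng):
        x = rng.uniform(size=(3, 4))
        m = np.ones((3, 4))
        noise = rng.uniform(-0.01, 0.01, size=(3, 4))
        np.testing.assert_array_equal(assemble_input(x, m, noise), x)

    def test_fully_missing_returns_noise(self, rng):
        x = np.full((3, 4), np.nan)
        noise = rng.uniform(-0.01, 0.01, size=(3, 4))
        np.testing.assert_array_equal(
            assemble_input(x, np.zeros((3, 4)), noise), noise
        )

    def test_mixed_2x2_selects_elementwise(self):
        x = np.array([[1.0, np.nan], [np.nan, 4.0]])
        m = np.array([[1, 0], [0, 1]])
        noise = np.array([[9.0, 8.0], [7.0, 6.0]])
        z = assemble_input(x, m, noise)
        np.testing.assert_array_equal(z, [[1.0, 8.0], [7.0, 4.0]])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            assemble_input(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))


class TestAttributeProjection:
    @pytest.fixture
    def attrs(self):
        return AttributeVector(
            [0, 1, 2],
            {1: np.array([0.0, 1.0]), 2: np.array([0.0, 1.0, 2.0, 3.0])},
        )

    def test_binary_snaps_to_nearest_level(self, attrs):
        x = np.array([[2.4, 0.73, 2.4]])
        out = attribute_projection(x, attrs)
        assert out[0, 1] == 1.0

    def test_nominal_snaps_to_nearest_category(self, attrs):
        out = attribute_projection(np.array([[0.0, 0.0, 2.4]]), attrs)
        assert out[0, 2] == 2.0

    def test_real_column_unchanged(self, attrs):
        out = attribute_projection(np.array([[2.4, 0.0, 0.0]]), attrs)
        assert out[0, 0] == 2.4

    def test_idempotent(self, attrs, rng):
        x = rng.uniform(-1, 4, size=(20, 3))
        once = attribute_projection(x, attrs)
        np.testing.assert_array_equal(once, attribute_projection(once, attrs))


class TestComposeImputed:
    def _setup(self):
        vals = np.array([[2.5, 0.0], [4.5, 1.0]])
        t = MixedTypeTable(vals, ["r", "b"])
        x_norm, p = normalize(t)
        a = infer_attributes(t)
        return t, x_norm, p, a

    def test_no_missing_returns_input_exactly(self):
        t, x_norm, p, a = self._setup()
        m = build_mask(t)
        res = compose_imputed(x_norm, np.full((2, 2), 0.5), m, a, p, x_original=t)
        np.testing.assert_array_equal(res.x_hat.values, t.values)

    def test_single_missing_cell_comes_from_generator(self):
        t, x_norm, p, a = self._setup()
        holed = MixedTypeTable(
            np.array([[2.5, 0.0], [np.nan, 1.0]]), ["r", "b"]
        )
        m = build_mask(holed)
        x_norm_h, _ = normalize(t)  # params from the complete table
        x_bar = np.array([[0.9, 0.9], [0.75, 0.9]])
        res = compose_imputed(x_norm_h, x_bar, m, a, p, x_original=holed)
        # only (1, 0) is generated: 0.75 * (4.5 - 2.5) + 2.5 = 4.0; real, unprojected
        assert res.x_hat.values[1, 0] == pytest.approx(4.0)
        assert res.x_hat.values[0, 0] == 2.5
        assert res.x_hat.values[0, 1] == 0.0

    def test_all_missing_equals_projected_denormalized_x_bar(self):
        t, x_norm, p, a = self._setup()
        from aganimpute import MaskMatrix

        m = MaskMatrix(np.zeros((2, 2), dtype=int))
        x_bar = np.array([[0.5, 0.7], [0.25, 0.2]])
        res = compose_imputed(x_norm, x_bar, m, a, p)
        np.testing.assert_allclose(res.x_hat.values[:, 0], [3.5, 3.0])
        np.testing.assert_array_equal(res.x_hat.values[:, 1], [1.0, 0.0])


class TestLosses:
    def test_d_loss_at_half_is_ln2(self):
        m = np.array([[1, 0], [0, 1]])
        assert d_loss(np.full((2, 2), 0.5), m) == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_discriminator_loss_near_zero(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert d_loss(m, m) < 1e-5

    def test_d_loss_matches_brute_force_per_cell_sum(self, rng):
        for _ in range(20):
            d = rng.uniform(0.05, 0.95, size=(5, 4))
            m = (rng.uniform(size=(5, 4)) < 0.6).astype(float)
            brute = -np.mean(
                [
                    m[i, j] * math.log(d[i, j])
                    + (1 - m[i, j]) * math.log(1 - d[i, j])
                    for i in range(5)
                    for j in range(4)
                ]
            )
            assert d_loss(d, m) == pytest.approx(brute, abs=1e-9)

    def test_g_loss_worked_example(self):
        # one missing cell scored 0.5, one observed cell with residual 0.2
        d = np.array([[0.5, 0.9]])
        m = np.array([[0.0, 1.0]])
        x = np.array([[0.0, 0.5]])
        x_bar = np.array([[0.3, 0.7]])
        expected = -math.log(0.5) + 10 * 0.2**2
        assert g_loss(d, m, x, x_bar, alpha=10) == pytest.approx(expected, abs=1e-9)

    def test_g_loss_matches_brute_force(self, rng):
        for _ in range(20):
            d = rng.uniform(0.05, 0.95, size=(5, 4))
            m = (rng.uniform(size=(5, 4)) < 0.6).astype(float)
            x = rng.uniform(size=(5, 4))
            xb = rng.uniform(size=(5, 4))
            alpha = 3.7
            miss = [(i, j) for i in range(5) for j in range(4) if m[i, j] == 0]
            obs = [(i, j) for i in range(5) for j in range(4) if m[i, j] == 1]
            adv = -np.mean([math.log(d[i, j]) for i, j in miss]) if miss else 0.0
            rec = np.mean([(x[i, j] - xb[i, j]) ** 2 for i, j in obs]) if obs else 0.0
            assert g_loss(d, m, x, xb, alpha) == pytest.approx(
                adv + alpha * rec, abs=1e-9
            )

    def test_g_loss_without_missing_cells_has_no_adversarial_term(self):
        m = np.ones((2, 2))
        x = np.zeros((2, 2))
        xb = np.full((2, 2), 0.1)
        assert g_loss(np.full((2, 2), 0.5), m, x, xb, 2.0) == pytest.approx(
            2.0 * 0.01, abs=1e-12
        )


class TestGradientPenalty:
    def test_constant_discriminator_gives_one(self):
        net = MLP([3, 4, 3], np.random.default_rng(0))
        for W in net.W:
            W[:] = 0.0
        assert gradient_penalty(net, np.zeros((5, 3))) == pytest.approx(1.0)

    def test_linear_discriminator_matches_hand_formula(self):
        net = MLP([3, 3], np.random.default_rng(0))  # single linear layer
        w = np.array([0.6, -1.2, 2.0])
        net.W[0][:] = 0.0
        net.W[0][:, 0] = w  # per-row critic score = w . x
        expected = (np.linalg.norm(w) - 1.0) ** 2
        x = np.random.default_rng(1).normal(size=(7, 3))
        assert gradient_penalty(net, x) == pytest.approx(expected, abs=1e-6)

    def test_nonnegative(self, rng):
        net = MLP([4, 6, 4], np.random.default_rng(5))
        assert gradient_penalty(net, rng.normal(size=(10, 4))) >= 0


class TestTraining:
    @pytest.fixture
    def amputed(self):
        t, labels, attrs = generate(SyntheticSpec(n=120, seed=4))
        holed, mask, gt = ampute_mcar(t, AmputationSpec(rate=0.3, seed=5))
        return t, holed, mask

    def test_same_seed_gives_identical_traces(self, amputed, quick_cfg):
        _, holed, mask = amputed
        x_norm, _ = normalize(holed, mask)
        a = infer_attributes(holed)
        _, _, tr1 = train(x_norm, mask, a, quick_cfg)
        _, _, tr2 = train(x_norm, mask, a, quick_cfg)
        assert tr1["g"] == tr2["g"]
        assert tr1["d"] == tr2["d"]
        assert tr1["pretrain"] == tr2["pretrain"]

    def test_loss_traces_are_finite(self, amputed, quick_cfg):
        _, holed, mask = amputed
        x_norm, _ = normalize(holed, mask)
        a = infer_attributes(holed)
        _, _, traces = train(x_norm, mask, a, quick_cfg)
        for key in ("pretrain", "g", "d"):
            assert traces[key], f"{key} trace empty"
            assert np.all(np.isfinite(traces[key]))

    def test_discriminator_updates_once_per_period(self, amputed, quick_cfg):
        _, holed, mask = amputed
        x_norm, _ = normalize(holed, mask)
        a = infer_attributes(holed)
        _, _, traces = train(x_norm, mask, a, quick_cfg)
        n_iter = quick_cfg.iterations_for(holed.n)
        assert len(traces["g"]) == n_iter
        assert len(traces["d"]) == math.ceil(n_iter / quick_cfg.d_update_period)


class TestImpute:
    def test_complete_input_returned_unchanged_with_empty_traces(
        self, small_mixed_table, quick_cfg
    ):
        res = impute(small_mixed_table, quick_cfg)
        np.testing.assert_array_equal(res.x_hat.values, small_mixed_table.values)
        assert res.g_loss_trace == [] and res.d_loss_trace == []

    def test_observed_cells_bit_identical_and_categories_valid(self, quick_cfg):
        t, _, _ = generate(SyntheticSpec(n=150, seed=6))
        holed, mask, _ = ampute_mcar(t, AmputationSpec(rate=0.3, seed=7))
        res = impute(holed, quick_cfg)
        assert res.x_hat.n_missing == 0
        obs = mask.m == 1
        assert np.array_equal(res.x_hat.values[obs], holed.values[obs])
        attrs = res.attributes
        for j in attrs.categorical_columns():
            assert np.isin(res.x_hat.values[:, j], attrs.category_sets[j]).all()

    def test_identical_seed_gives_identical_result(self, quick_cfg):
        t, _, _ = generate(SyntheticSpec(n=100, seed=8))
        holed, _, _ = ampute_mcar(t, AmputationSpec(rate=0.2, seed=9))
        r1 = impute(holed, quick_cfg)
        r2 = impute(holed, quick_cfg)
        np.testing.assert_array_equal(r1.x_hat.values, r2.x_hat.values)
        assert r1.g_loss_trace == r2.g_loss_trace


class TestEstimator:
    def test_sklearn_param_round_trip(self):
        imp = AGANImputer(alpha=5.0, epochs=2)
        params = imp.get_params()
        assert params["alpha"] == 5.0
        clone = AGANImputer(**params)
        assert clone.get_params() == params

    def test_fit_transform_completes_matrix(self, quick_cfg):
        t, _, _ = generate(SyntheticSpec(n=100, seed=10))
        holed, mask, _ = ampute_mcar(t, AmputationSpec(rate=0.25, seed=11))
        imp = AGANImputer(**quick_cfg.to_dict())
        out = imp.fit_transform(holed.values)
        assert not np.isnan(out).any()
        obs = mask.m == 1
        np.testing.assert_array_equal(out[obs], holed.values[obs])

    def test_transform_rejects_wrong_width(self, quick_cfg):
        t, _, _ = generate(SyntheticSpec(n=80, seed=12))
        holed, _, _ = ampute_mcar(t, AmputationSpec(rate=0.2, seed=13))
        imp = AGANImputer(**quick_cfg.to_dict()).fit(holed.values)
        with pytest.raises(ShapeMismatchError):
            imp.transform(np.zeros((3, holed.d + 1)))

    def test_learned_swish_beta_mode_trains(self, quick_cfg):
        t, _, _ = generate(SyntheticSpec(n=80, seed=14))
        holed, _, _ = ampute_mcar(t, AmputationSpec(rate=0.2, seed=15))
        cfg = dict(quick_cfg.to_dict(), swish_beta="learned")
        imp = AGANImputer(**cfg).fit(holed.values)
        assert np.all(np.isfinite(imp.g_loss_trace_))

    def test_save_writes_checkpoint(self, quick_cfg, tmp_path):
        t, _, _ = generate(SyntheticSpec(n=80, seed=16))
        holed, _, _ = ampute_mcar(t, AmputationSpec(rate=0.2, seed=17))
        imp = AGANImputer(**quick_cfg.to_dict()).fit(holed.values)
        path = tmp_path / "model.npz"
        imp.save(path)
        archive = np.load(path)
        assert "gen/W0" in archive and "col_min" in archive


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = TrainingConfig(alpha=3.0, epochs=17, swish_beta="learned")
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert TrainingConfig.from_yaml(p) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig.from_dict({"learning_rat": 0.1})

    def test_reference_defaults(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 1e-6
        assert cfg.batch_size == 128
        assert cfg.pretrain_epochs == 30
        assert cfg.epochs == 200
        assert cfg.hidden_units == 64
        assert cfg.d_update_period == 8
        assert (cfg.noise_low, cfg.noise_high) == (-0.01, 0.01)
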