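"""Loss, gradients (against the finite-difference oracle) and training."""

import dataclasses

import numpy as np
import pytest

from avsmotion.data import DatasetSpec, generate_dataset
from avsmotion.ganglion import (GanglionParams, connection_state,
                                direction_slot, ideal_direction_params)
from avsmotion.learning import (TrainConfig, backward_gradients,
                                cross_entropy_loss, encode_dataset,
                                evaluate_accuracy, forward_batch,
                                numeric_gradient_oracle, sgd_step,
                                train_model)
from avsmotion.lgn import LGNParams
from avsmotion.retina import CENTER_SLOT


@pytest.fixture(scope="module")
def small_8x8_encoded():
    spec = DatasetSpec(image_height=8, image_width=8,
                       configurations=("RD",), object_sizes=(5,),
                       pairs_per_direction=1, seed=21)
    pairs, _ = generate_dataset(spec)
    return encode_dataset(pairs)


def batch_loss_fn(ds, idx, gparams, lparams, which):
    """Loss as a function of one parameter tensor, for the FD oracle."""
    def fn(value):
        p = gparams.copy()
        setattr(p, which, value)
        return forward_batch(ds, idx, p, lparams)["loss"]
    return fn


class TestCrossEntropy:
    def test_closed_forms(self):
        T = np.eye(8)[2]
        assert cross_entropy_loss(T, T) == pytest.approx(0.0)
        assert cross_entropy_loss(np.full(8, 0.125), T) == pytest.approx(np.log(8))
        D = np.full(8, 0.5 / 7)
        D[2] = 0.5
        assert cross_entropy_loss(D, T) == pytest.approx(np.log(2))

    def test_zero_probability_clamped_with_warning(self):
        D = np.zeros(8)
        D[0] = 1.0
        T = np.eye(8)[3]
        with pytest.warns(RuntimeWarning):
            loss = cross_entropy_loss(D, T)
        assert np.isfinite(loss) and loss > 20


class TestGradientOracle:
    def test_quadratic_is_exact_to_step_squared(self):
        x0 = np.array([1.0, -2.0, 0.5])
        grad = numeric_gradient_oracle(lambda x: float((x**2).sum()), x0, 1e-5)
        assert np.allclose(grad, 2 * x0, atol=1e-9)

    def test_step_sweep_plateau(self):
        x0 = np.array([0.3])
        errs = [abs(numeric_gradient_oracle(lambda x: float(np.sin(x[0])), x0, h)[0]
                    - np.cos(0.3)) for h in (1e-3, 1e-4, 1e-5)]
        assert max(errs) < 1e-6


class TestBackwardGradients:
    def test_exact_mode_matches_finite_differences(self, small_8x8_encoded, rng):
        """Core oracle: analytic gradients vs central differences on random
        8x8 pairs, every coordinate, both parameter tensors."""
        ds = small_8x8_encoded
        gparams = GanglionParams.init_random(rng, scheme="uniform")
        lparams = LGNParams()
        idx = np.arange(2)
        cache = forward_batch(ds, idx, gparams, lparams)
        gw, gq = backward_gradients(cache, gparams, lparams, mode="exact")
        for which, analytic in (("w", gw), ("q", gq)):
            fd = numeric_gradient_oracle(
                batch_loss_fn(ds, idx, gparams, lparams, which),
                getattr(gparams, which).copy(), step=1e-5)
            denom = np.maximum(np.maximum(np.abs(fd), np.abs(analytic)), 1e-10)
            rel = np.abs(fd - analytic) / denom
            ok = (rel <= 1e-6) | (np.abs(fd - analytic) <= 1e-10)
            assert ok.all(), f"{which}: max rel {rel.max():.2e}"

    def test_gated_init_gradcheck(self, small_8x8_encoded, rng):
        """Same agreement at the default (gated) initialization."""
        ds = small_8x8_encoded
        gparams = GanglionParams.init_random(rng)
        lparams = LGNParams()
        idx = np.arange(len(ds))
        cache = forward_batch(ds, idx, gparams, lparams)
        gw, gq = backward_gradients(cache, gparams, lparams, mode="exact")
        fd = numeric_gradient_oracle(
            batch_loss_fn(ds, idx, gparams, lparams, "q"),
            gparams.q.copy(), step=1e-5)
        assert np.abs(fd - gq).max() < 1e-9

    def test_zero_input_weight_gradient_vanishes(self, rng):
        """dS/dw carries a factor x, so weights never touched by an active
        input receive exactly zero gradient."""
        spec = DatasetSpec(image_height=8, image_width=8,
                           configurations=("DL",), object_sizes=(2,),
                           pairs_per_direction=1, seed=5)
        pairs, _ = generate_dataset(spec)
        ds = encode_dataset(pairs)
        gparams = GanglionParams.init_random(rng)
        lparams = LGNParams()
        cache = forward_batch(ds, np.arange(len(ds)), gparams, lparams)
        gw, _ = backward_gradients(cache, gparams, lparams)
        never_active = cache["Xr"].max(axis=0) == 0  # (9, C)
        # (slot, channel) pairs that never fired anywhere in the batch:
        for i in range(9):
            for c in range(3):
                if never_active[i, c]:
                    assert np.all(gw[i, :, :, c] == 0)

    def test_paper_literal_mode_runs_and_differs(self, small_8x8_encoded, rng):
        ds = small_8x8_encoded
        gparams = GanglionParams.init_random(rng)
        lparams = LGNParams()
        cache = forward_batch(ds, np.arange(2), gparams, lparams)
        gw_e, _ = backward_gradients(cache, gparams, lparams, mode="exact")
        gw_l, _ = backward_gradients(cache, gparams, lparams, mode="paper_literal")
        assert gw_l.shape == gw_e.shape
        assert not np.allclose(gw_e, gw_l)
        # the printed teacher factor only feeds the true directions' neurons
        labels = cache["labels"]
        untouched = [m for m in range(8) if m + 1 not in labels]
        assert np.all(gw_l[:, :, untouched, :] == 0)

    def test_single_step_decreases_loss(self, small_8x8_encoded, rng):
        ds = small_8x8_encoded
        gparams = GanglionParams.init_random(rng)
        lparams = LGNParams()
        idx = np.array([3])
        cache = forward_batch(ds, idx, gparams, lparams)
        gw, gq = backward_gradients(cache, gparams, lparams)
        stepped = sgd_step(gparams, gw, gq, learning_rate=0.1)
        assert forward_batch(ds, idx, stepped, lparams)["loss"] < cache["loss"]

    def test_missing_intermediate_rejected(self, rng):
        with pytest.raises(ValueError, match="intermediate"):
            backward_gradients({"Xr": None}, GanglionParams.init_random(rng),
                               LGNParams())


class TestSgdStep:
    def test_zero_gradient_and_zero_rate_are_identity(self, rng):
        p = GanglionParams.init_random(rng)
        z = np.zeros_like(p.w)
        out = sgd_step(p, z, z, 0.5)
        assert np.array_equal(out.w, p.w) and np.array_equal(out.q, p.q)

    def test_only_w_and_q_change(self, rng):
        p = GanglionParams.init_random(rng)
        g = np.ones_like(p.w)
        out = sgd_step(p, g, g, 0.1)
        assert np.allclose(out.w, p.w - 0.1)
        assert np.array_equal(out.d, p.d)
        assert np.array_equal(out.v, p.v)

    def test_nonfinite_gradient_names_coordinate(self, rng):
        p = GanglionParams.init_random(rng)
        g = np.zeros_like(p.w)
        g[2, 0, 5, 1] = np.nan
        with pytest.raises(FloatingPointError, match=r"\(2, 0, 5, 1\)"):
            sgd_step(p, g, np.zeros_like(p.q), 0.1)


class TestTraining:
    def test_small_dl_run_reaches_perfect_train_accuracy(self):
        """A small balanced high-contrast set (80 DL pairs of size 16) is
        fit perfectly by the default optimizer within 400 epochs."""
        spec = DatasetSpec(configurations=("DL",), object_sizes=(16,),
                           pairs_per_direction=10, seed=42)
        pairs, _ = generate_dataset(spec)
        ds = encode_dataset(pairs)
        cfg = TrainConfig(epochs=400, batch_size=8, seed=0,
                          early_stop_patience=400)
        params, history = train_model(ds, cfg)
        assert evaluate_accuracy(params, LGNParams(), ds) == 1.0
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_same_seed_gives_identical_trajectories(self, small_8x8_encoded):
        cfg = TrainConfig(epochs=5, seed=11)
        p1, h1 = train_model(small_8x8_encoded, cfg)
        p2, h2 = train_model(small_8x8_encoded, cfg)
        assert np.array_equal(p1.w, p2.w) and np.array_equal(p1.q, p2.q)
        assert h1.equals(h2)

    def test_untrained_model_sits_at_chance(self):
        """With uniform random parameters, accuracy on a balanced set stays
        within 3 binomial standard errors of 1/8."""
        spec = DatasetSpec(configurations=("LD",), object_sizes=(16,),
                           pairs_per_direction=25, seed=13)
        pairs, _ = generate_dataset(spec)
        ds = encode_dataset(pairs)
        params = GanglionParams.init_random(np.random.default_rng(99),
                                            scheme="uniform")
        acc = evaluate_accuracy(params, LGNParams(), ds)
        se = np.sqrt(0.125 * 0.875 / len(pairs))
        assert abs(acc - 0.125) <= 3 * se

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TrainConfig())

    def test_trained_synapses_align_with_motion_geometry(self):
        """After training on high-contrast data, each direction's neurons
        keep the centre gate excitatory and most often turn the synapse at
        the direction's own displacement slot excitatory."""
        spec = DatasetSpec(configurations=("LD",), object_sizes=(8, 16),
                           pairs_per_direction=10, seed=3)
        pairs, _ = generate_dataset(spec)
        ds = encode_dataset(pairs)
        params, _ = train_model(ds, TrainConfig(epochs=300, batch_size=8,
                                                seed=1,
                                                early_stop_patience=300))
        n_center = n_own = 0
        for m in range(1, 9):
            for c in range(3):
                if connection_state(params.w[CENTER_SLOT, 0, m - 1, c],
                                    params.q[CENTER_SLOT, 0, m - 1, c]) == "excitatory":
                    n_center += 1
                slot = direction_slot(m)
                if connection_state(params.w[slot, 0, m - 1, c],
                                    params.q[slot, 0, m - 1, c]) == "excitatory":
                    n_own += 1
        assert n_center >= 20  # out of 24 (m, c) neurons
        assert n_own >= 13     # majority criterion

    def test_ideal_params_are_perfect_on_high_contrast(self, small_dl_pairs):
        pairs, _ = small_dl_pairs
        ds = encode_dataset(pairs)
        assert evaluate_accuracy(ideal_direction_params(), LGNParams(), ds) == 1.0

    def test_loss_nonincreasing_with_tiny_rate_full_batch(self, small_8x8_encoded):
        """Full-batch descent with a sufficiently small step never increases
        the loss over consecutive epochs."""
        ds = small_8x8_encoded
        cfg = TrainConfig(learning_rate=1e-3, epochs=10, batch_size=len(ds),
                          seed=0, early_stop_patience=100, min_delta=0.0)
        _, hist = train_model(ds, cfg)
        losses = hist.train_loss.to_numpy()
        assert (np.diff(losses) <= 1e-12).all()
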