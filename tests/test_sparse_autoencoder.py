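"""Autoencoder cost/gradient correctness, SCG behaviour, stacking and prediction."""

import numpy as np
import pytest
from scipy.special import expit

import pdprognosis as pp
from pdprognosis import sparse_autoencoder as sae


def finite_difference(fun, w, h=1e-6):
    g = np.empty_like(w)
    for i in range(len(w)):
        e = np.zeros_like(w); e[i] = h
        g[i] = (fun(w + e)[0] - fun(w - e)[0]) / (2 * h)
    return g


def random_layer(rng, d=3, h=2, **hyper):
    hy = sae.SparseAEHyper(hidden_size=h, **hyper)
    return sae.SparseAELayer(
        0.5 * rng.standard_normal((h, d)), 0.1 * rng.standard_normal(h),
        0.5 * rng.standard_normal((d, h)), 0.1 * rng.standard_normal(d), hy)


# -- cost function ---------------------------------------------------------

def test_perfect_reconstruction_costs_zero():
    """Constant data at 0.5 is exactly representable with zero weights."""
    hy = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    layer = sae.SparseAELayer(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)), np.zeros(3), hy)
    X = np.full((5, 3), 0.5)
    cost, _ = sae.ae_cost_grad(layer, X)
    assert cost == pytest.approx(0.0, abs=1e-15)


def test_kl_term_vanishes_at_target_activation():
    """When the mean activation equals the target rho, the sparsity term is 0."""
    rho = 0.5  # zero weights give activations exactly 0.5
    with pytest.warns(UserWarning):
        hy = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=4, sparsity_prop=rho)
    layer = sae.SparseAELayer(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)), np.zeros(3), hy)
    X = np.full((4, 3), 0.5)
    cost, _ = sae.ae_cost_grad(layer, X)
    assert cost == pytest.approx(0.0, abs=1e-12)


def test_l2_term_counts_weights_not_biases():
    hy = sae.SparseAEHyper(hidden_size=1, l2_weight=0.004, sparsity_reg=0, sparsity_prop=0.1)
    W1 = np.array([[2.0]]); W2 = np.array([[3.0]])
    layer = sae.SparseAELayer(W1, np.array([5.0]), W2, np.array([7.0]), hy)
    X = np.full((2, 1), 0.5)
    cost, _ = sae.ae_cost_grad(layer, X)
    layer0 = sae.SparseAELayer(W1, np.array([5.0]), W2, np.array([7.0]),
                               sae.SparseAEHyper(hidden_size=1, l2_weight=0,
                                                 sparsity_reg=0, sparsity_prop=0.1))
    cost0, _ = sae.ae_cost_grad(layer0, X)
    assert cost - cost0 == pytest.approx(0.004 * 0.5 * (4 + 9), rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_analytic_gradient_matches_finite_differences(seed):
    rng = np.random.default_rng(seed)
    layer = random_layer(rng)
    X = rng.random((4, 3))
    w = sae._pack(layer.W1, layer.b1, layer.W2, layer.b2)
    fun = lambda v: sae._ae_cost_grad_flat(v, X, 2, layer.hyper)
    g_fd = finite_difference(fun, w)
    g = fun(w)[1]
    rel = np.abs(g - g_fd) / np.maximum(np.abs(g_fd), 1e-8)
    assert rel.max() < 1e-5


def test_stack_and_softmax_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    X = rng.random((6, 4))
    Y = np.zeros((6, 2)); Y[np.arange(6), rng.integers(0, 2, 6)] = 1
    # softmax head alone
    H = rng.random((6, 3))
    w = 0.3 * rng.standard_normal(2 * 3 + 2)
    fun = lambda v: sae._softmax_cost_grad(v, H, Y)
    rel = np.abs(fun(w)[1] - finite_difference(fun, w))
    assert rel.max() < 1e-6
    # full stack (4 -> 3 -> 2 -> softmax)
    shapes = [(3, 4), (2, 3), (2, 2)]
    nw = sum(h * d + h for h, d in shapes)
    w = 0.3 * rng.standard_normal(nw)
    fun = lambda v: sae._stack_cost_grad(v, X, Y, shapes)
    rel = np.abs(fun(w)[1] - finite_difference(fun, w))
    assert rel.max() < 1e-6


def test_saturation_signalled():
    hy = sae.SparseAEHyper(hidden_size=1, l2_weight=0, sparsity_reg=4, sparsity_prop=0.1)
    layer = sae.SparseAELayer(np.full((1, 2), 50.0), np.array([100.0]),
                              np.zeros((2, 1)), np.zeros(2), hy)
    X = np.full((3, 2), 0.9)
    with pytest.raises(FloatingPointError):
        sae.ae_cost_grad(layer, X, on_saturation="raise")
    with pytest.warns(UserWarning, match="saturated"):
        sae.ae_cost_grad(layer, X, on_saturation="clip")


# -- scaled conjugate gradient --------------------------------------------

def test_scg_quadratic_reaches_closed_form_minimum():
    rng = np.random.default_rng(11)
    M = rng.standard_normal((5, 5))
    A = M @ M.T + 0.1 * np.eye(5)
    b = rng.standard_normal(5)
    fun = lambda w: (0.5 * w @ A @ w - b @ w, A @ w - b)
    w, trace = sae.scg_minimize(fun, rng.standard_normal(5), max_iter=50, tol=1e-12)
    assert np.linalg.norm(w - np.linalg.solve(A, b)) < 1e-8
    diffs = np.diff(trace)
    assert (diffs <= 1e-12 * np.maximum(1, np.abs(trace[:-1]))).all()


def test_scg_terminates_immediately_at_minimum():
    A = np.eye(3)
    fun = lambda w: (0.5 * w @ A @ w, A @ w)
    w, trace = sae.scg_minimize(fun, np.zeros(3), max_iter=100, tol=1e-10)
    assert np.array_equal(w, np.zeros(3))
    assert len(trace) == 1


def test_scg_rosenbrock():
    def rosen(w):
        x, y = w
        return ((1 - x)**2 + 100 * (y - x * x)**2,
                np.array([-2 * (1 - x) - 400 * x * (y - x * x), 200 * (y - x * x)]))
    w, _ = sae.scg_minimize(rosen, np.array([-1.2, 1.0]), max_iter=5000, tol=1e-10)
    assert rosen(w)[0] < 1e-6
    assert np.allclose(w, [1, 1], atol=1e-3)


def test_scg_aborts_on_nonfinite_start():
    fun = lambda w: (np.inf, w)
    with pytest.raises(RuntimeError):
        sae.scg_minimize(fun, np.ones(2))


# -- layer training --------------------------------------------------------

def test_training_deterministic():
    rng = np.random.default_rng(5)
    X = rng.random((30, 8))
    hy = dict(hidden_size=3, max_epochs=100, seed=9)
    a = sae.train_sparse_autoencoder(X, sae.SparseAEHyper(**hy))
    b = sae.train_sparse_autoencoder(X, sae.SparseAEHyper(**hy))
    assert np.array_equal(a.W1, b.W1) and np.array_equal(a.b2, b.b2)


def test_linear_manifold_reconstruction():
    """Data on a 2-D linear manifold in 10-D is reconstructed almost
    perfectly by a 2-unit bottleneck without regularisation."""
    rng = np.random.default_rng(0)
    T = rng.uniform(-1, 1, (200, 2))
    A = rng.standard_normal((2, 10))
    X = T @ A
    X = (X - X.min(0)) / (X.max(0) - X.min(0)) * 0.6 + 0.2
    hy = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=0,
                           sparsity_prop=0.1, max_epochs=2000, seed=0)
    layer = sae.train_sparse_autoencoder(X, hy)
    Xhat = expit(sae.encode(layer, X) @ layer.W2.T + layer.b2)
    assert ((X - Xhat)**2).mean() < 0.05 * X.var()


def test_bottleneck_cannot_reconstruct_isotropic_2d():
    """A 1-unit code cannot represent 2-D isotropic data (information
    bottleneck lower-bounds the error)."""
    rng = np.random.default_rng(1)
    X = rng.random((200, 2))
    hy = sae.SparseAEHyper(hidden_size=1, l2_weight=0, sparsity_reg=0,
                           sparsity_prop=0.1, max_epochs=1000, seed=0)
    layer = sae.train_sparse_autoencoder(X, hy)
    Xhat = expit(sae.encode(layer, X) @ layer.W2.T + layer.b2)
    assert ((X - Xhat)**2).mean() > 0.2 * X.var()


def test_sparsity_pressure_and_monotonicity(clean_patients):
    """Stronger KL penalties pin the mean activation at the target and mean
    activation is non-increasing in beta."""
    table, _, _ = clean_patients
    params = pp.fit_scaler(table, table.subject_ids)
    X = pp.preprocessing.scale_matrix(table.values, params)
    acts = []
    for beta in (0.5, 2.0, 6.0, 20.0):
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            hy = sae.SparseAEHyper(hidden_size=20, sparsity_reg=beta,
                                   sparsity_prop=0.05, max_epochs=200, seed=0)
        layer = sae.train_sparse_autoencoder(X, hy)
        acts.append(float(sae.encode(layer, X).mean()))
    assert 0.02 <= acts[-1] <= 0.15
    assert all(b <= a + 0.02 for a, b in zip(acts, acts[1:]))


# -- encoding and stacking -------------------------------------------------

def test_encode_examples():
    hy = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    zero = sae.SparseAELayer(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)), np.zeros(3), hy)
    assert np.allclose(sae.encode(zero, np.random.default_rng(0).random((4, 3))), 0.5)
    hy1 = sae.SparseAEHyper(hidden_size=1, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    one = sae.SparseAELayer(np.array([[2.0]]), np.array([-1.0]),
                            np.array([[1.0]]), np.array([0.0]), hy1)
    assert sae.encode(one, np.array([[1.0]]))[0, 0] == pytest.approx(expit(1.0))
    with pytest.raises(ValueError):
        sae.encode(one, np.ones((2, 3)))


def test_stacked_dimensions_chain():
    rng = np.random.default_rng(2)
    X = rng.random((40, 30))
    y = rng.integers(0, 2, 40)
    model = sae.train_stacked_classifier(X, y, hidden_sizes=(20, 10),
                                         pretrain_iters=20, softmax_iters=20,
                                         finetune_iters=20, seed=0)
    codes = X
    for enc in model.encoders:
        codes = sae.encode(enc, codes)
    assert codes.shape == (40, 10)
    P = sae.predict_proba(model, X)
    assert P.shape == (40, 2)
    assert np.allclose(P.sum(axis=1), 1, atol=1e-9)


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).random((10, 4))
    with pytest.raises(ValueError, match="single class"):
        sae.train_stacked_classifier(X, np.zeros(10, int))


def test_finetune_zero_iterations_is_greedy_stack():
    rng = np.random.default_rng(4)
    X = rng.random((30, 6))
    y = rng.integers(0, 2, 30)
    kw = dict(hidden_sizes=(4, 2), pretrain_iters=50, softmax_iters=50, seed=1)
    greedy = sae.train_stacked_classifier(X, y, finetune_iters=0, **kw)
    again = sae.train_stacked_classifier(X, y, finetune_iters=0, **kw)
    assert np.array_equal(sae.predict_proba(greedy, X), sae.predict_proba(again, X))


def test_finetuning_does_not_increase_training_cost():
    rng = np.random.default_rng(6)
    X = rng.random((40, 8))
    y = (X[:, 0] > 0.5).astype(int)
    model = sae.train_stacked_classifier(X, y, hidden_sizes=(4, 2),
                                         pretrain_iters=50, softmax_iters=50,
                                         finetune_iters=200, seed=0)
    ft = model.training_log["finetune_cost"]
    assert ft[-1] <= ft[0] + 1e-12


def test_predict_proba_matches_hand_evaluation():
    """Three-feature toy stack recomputed with raw sigmoid/softmax algebra."""
    hy2 = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    hy1 = sae.SparseAEHyper(hidden_size=1, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    enc1 = sae.SparseAELayer(np.array([[0.5, -1.0, 2.0], [1.0, 0.0, -0.5]]),
                             np.array([0.1, -0.2]),
                             np.zeros((3, 2)), np.zeros(3), hy2)
    enc2 = sae.SparseAELayer(np.array([[1.5, -0.7]]), np.array([0.3]),
                             np.zeros((2, 1)), np.zeros(2), hy1)
    Ws = np.array([[2.0], [-1.0]]); bs = np.array([0.1, 0.2])
    model = sae.StackedClassifier([enc1, enc2], Ws, bs)
    x = np.array([[0.2, 0.8, 0.5]])
    h1 = expit(x @ enc1.W1.T + enc1.b1)
    h2 = expit(h1 @ enc2.W1.T + enc2.b1)
    logits = h2 @ Ws.T + bs
    expect = np.exp(logits) / np.exp(logits).sum()
    assert np.allclose(sae.predict_proba(model, x), expect, atol=1e-12)


def test_zero_softmax_weights_give_half_half():
    hy = sae.SparseAEHyper(hidden_size=2, l2_weight=0, sparsity_reg=0, sparsity_prop=0.1)
    enc = sae.SparseAELayer(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)), np.zeros(3), hy)
    model = sae.StackedClassifier([enc], np.zeros((2, 2)), np.zeros(2))
    P = sae.predict_proba(model, np.random.default_rng(0).random((5, 3)))
    assert np.allclose(P, 0.5)


def test_classifier_json_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    X = rng.random((20, 5))
    y = rng.integers(0, 2, 20)
    model = sae.train_stacked_classifier(X, y, hidden_sizes=(3, 2),
                                         pretrain_iters=30, softmax_iters=30,
                                         finetune_iters=30, seed=2)
    sae.classifier_to_json(model, tmp_path / "m.json")
    back = sae.classifier_from_json(tmp_path / "m.json")
    assert np.array_equal(sae.predict_proba(back, X), sae.predict_proba(model, X))


def test_hyper_range_warnings():
    with pytest.warns(UserWarning):
        sae.SparseAEHyper(hidden_size=2, l2_weight=0.5)
    with pytest.warns(UserWarning):
        sae.SparseAEHyper(hidden_size=2, sparsity_reg=50)
    with pytest.raises(ValueError):
        sae.SparseAEHyper(hidden_size=0)


def test_sequential_search_returns_in_grid():
    rng = np.random.default_rng(8)
    X = rng.random((60, 10))
    y = (X[:, 0] + X[:, 1] > 1).astype(int)
    best, acc = sae.sequential_hyperparameter_search(
        X[:40], y[:40], X[40:], y[40:], hidden_sizes=(4, 2),
        l2_grid=(0.001, 0.009), beta_grid=(2.0, 6.0), rho_grid=(0.05, 0.2),
        pretrain_iters=30, softmax_iters=30, finetune_iters=60, seed=0)
    assert best["l2_weight"] in (0.001, 0.009)
    assert best["sparsity_reg"] in (2.0, 6.0)
    assert 0 <= acc <= 1
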