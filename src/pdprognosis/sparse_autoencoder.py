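"""Stacked sparse autoencoder with SoftMax head, trained by scaled conjugate gradient.

Each layer is a one-hidden-layer autoencoder with logistic-sigmoid encoder
and decoder, trained to minimise an adjusted mean-square-error cost

    J = (1/N) * sum_n ||x_n - xhat_n||^2
        + lambda * 0.5 * (sum W1^2 + sum W2^2)          (L2, biases exempt)
        + beta * sum_i KL(rho || rho_hat_i)             (sparsity)

where rho_hat_i is the mean activation of hidden unit i over the batch and
KL(rho||q) = rho*log(rho/q) + (1-rho)*log((1-rho)/(1-q)).  Gradients are
exact analytic backpropagation; optimisation is Møller's scaled conjugate
gradient (SCG) — a line-search-free conjugate gradient with a
Levenberg–Marquardt-scaled second-order step estimate — run full batch.

Layers are stacked greedily (layer 2 trains on layer 1's codes), a SoftMax
classification head is trained on the final codes by cross-entropy, and the
whole encoder chain + head is then fine-tuned end-to-end on the same
cross-entropy (decoders and regularisers dropped).  Weights start from
N(0, 0.01^2) with zero biases, so every fit is deterministic given its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit as sigmoid

RHO_CLIP = 1e-8

# Hyperparameter ranges used in the original sequential sweeps; values
# outside them are allowed but flagged.
L2_RANGE = (0.001, 0.009)
BETA_RANGE = (2.0, 6.0)
RHO_RANGE = (0.05, 0.20)


@dataclass
class SparseAEHyper:
    """Hyperparameters of one sparse autoencoder layer.

    ``l2_weight`` (lambda) scales the L2 weight penalty, ``sparsity_reg``
    (beta) the KL sparsity penalty, ``sparsity_prop`` (rho) is the target
    mean hidden activation, ``max_epochs`` caps SCG iterations.
    """

    hidden_size: int
    l2_weight: float = 0.004
    sparsity_reg: float = 4.0
    sparsity_prop: float = 0.10
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not (0 < self.sparsity_prop < 1):
            raise ValueError("sparsity_prop must lie in (0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if self.l2_weight != 0 and not (L2_RANGE[0] <= self.l2_weight <= L2_RANGE[1]):
            warnings.warn(f"l2_weight {self.l2_weight} outside the usual sweep range {L2_RANGE}")
        if self.sparsity_reg != 0 and not (BETA_RANGE[0] <= self.sparsity_reg <= BETA_RANGE[1]):
            warnings.warn(f"sparsity_reg {self.sparsity_reg} outside the usual sweep range {BETA_RANGE}")
        if not (RHO_RANGE[0] <= self.sparsity_prop <= RHO_RANGE[1]):
            warnings.warn(f"sparsity_prop {self.sparsity_prop} outside the usual sweep range {RHO_RANGE}")


@dataclass
class SparseAELayer:
    """One trained autoencoder layer (encoder + decoder weights)."""

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (input, hidden)
    b2: np.ndarray  # (input,)
    hyper: SparseAEHyper
    cost_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, d = self.W1.shape
        if self.W2.shape != (d, h) or self.b1.shape != (h,) or self.b2.shape != (d,):
            raise ValueError("inconsistent layer shapes")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("layer weights must be finite")


# ----------------------------------------------------------------------
# parameter packing


def _pack(*arrays) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unpack_ae(w: np.ndarray, d: int, h: int):
    i = 0
    W1 = w[i:i + h * d].reshape(h, d); i += h * d
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + d * h].reshape(d, h); i += d * h
    b2 = w[i:i + d]
    return W1, b1, W2, b2


# ----------------------------------------------------------------------
# sparse-autoencoder cost and gradient


def _ae_cost_grad_flat(w, X, h, hyper: SparseAEHyper, on_saturation: str = "clip"):
    """Cost and exact gradient of the sparse-AE objective at flat weights *w*."""
    N, d = X.shape
    W1, b1, W2, b2 = _unpack_ae(w, d, h)
    lam, beta, rho = hyper.l2_weight, hyper.sparsity_reg, hyper.sparsity_prop

    H = sigmoid(X @ W1.T + b1)            # (N, h)
    Xhat = sigmoid(H @ W2.T + b2)         # (N, d)
    rho_hat = H.mean(axis=0)

    if beta > 0 and ((rho_hat <= RHO_CLIP).any() or (rho_hat >= 1 - RHO_CLIP).any()):
        if on_saturation == "raise":
            raise FloatingPointError("mean hidden activation saturated at 0 or 1")
        warnings.warn("mean hidden activation saturated; clipping for the KL term")
    rho_hat_c = np.clip(rho_hat, RHO_CLIP, 1 - RHO_CLIP)

    resid = Xhat - X
    cost = float((resid**2).sum() / N)
    cost += lam * 0.5 * float((W1**2).sum() + (W2**2).sum())
    if beta > 0:
        kl = rho * np.log(rho / rho_hat_c) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat_c))
        cost += beta * float(kl.sum())

    delta_out = (2.0 / N) * resid * Xhat * (1 - Xhat)          # (N, d)
    gW2 = delta_out.T @ H + lam * W2
    gb2 = delta_out.sum(axis=0)
    back = delta_out @ W2                                      # (N, h)
    if beta > 0:
        kl_grad = -rho / rho_hat_c + (1 - rho) / (1 - rho_hat_c)
        back = back + (beta / N) * kl_grad
    delta_hid = back * H * (1 - H)
    gW1 = delta_hid.T @ X + lam * W1
    gb1 = delta_hid.sum(axis=0)
    return cost, _pack(gW1, gb1, gW2, gb2)


def ae_cost_grad(layer: SparseAELayer, X, on_saturation: str = "clip"):
    """Adjusted-MSE cost with L2 and KL-sparsity penalties, and its exact
    analytic gradient (flat, ordered W1, b1, W2, b2)."""
    X = np.asarray(X, float)
    h, d = layer.W1.shape
    if X.ndim != 2 or X.shape[1] != d:
        raise ValueError(f"X must be (N, {d})")
    w = _pack(layer.W1, layer.b1, layer.W2, layer.b2)
    return _ae_cost_grad_flat(w, X, h, layer.hyper, on_saturation=on_saturation)


# ----------------------------------------------------------------------
# Møller's scaled conjugate gradient


def scg_minimize(cost_grad_fn, w0, max_iter: int = 500, tol: float = 1e-6):
    """Minimise a smooth function by scaled conjugate gradient.

    *cost_grad_fn* maps a flat weight vector to ``(cost, gradient)``.
    Returns ``(w, trace)`` where *trace* is the list of accepted costs
    (monotone non-increasing).  Terminates when the gradient norm drops
    below *tol* or after *max_iter* iterations.  A non-finite cost at the
    current iterate aborts with a diagnostic; a non-finite trial step is
    treated as a failed step and the damping is raised.
    """
    w = np.asarray(w0, float).copy()
    n = len(w)
    f, g = cost_grad_fn(w)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise RuntimeError("non-finite cost or gradient at the starting point")
    trace = [float(f)]
    r = -g
    p = r.copy()
    success = True
    lam = 1e-6
    lam_bar = 0.0
    sigma0 = 1e-4
    pnorm2 = float(p @ p)
    delta = 0.0

    if np.linalg.norm(r) < tol or max_iter == 0:
        return w, trace

    for k in range(1, max_iter + 1):
        if success:
            pnorm2 = float(p @ p)
            if pnorm2 == 0.0:
                break
            sigma = sigma0 / np.sqrt(pnorm2)
            _, g_sigma = cost_grad_fn(w + sigma * p)
            if not np.all(np.isfinite(g_sigma)):
                lam = min(lam * 4, 1e20)
                success = False
                continue
            s = (g_sigma - g) / sigma
            delta = float(p @ s)
        delta_k = delta + (lam - lam_bar) * pnorm2
        if delta_k <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta_k / pnorm2)
            delta_k = -delta_k + lam * pnorm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new, g_new = cost_grad_fn(w + alpha * p)
        if np.isfinite(f_new):
            Delta = 2.0 * delta_k * (f - f_new) / (mu * mu)
            # At the double-precision floor the cost difference is pure
            # rounding noise; trust the second-order model step there so
            # terminal convergence is not throttled by comparison noise.
            if abs(f - f_new) <= 4 * np.finfo(float).eps * (abs(f) + abs(f_new)):
                Delta = 1.0
        else:
            Delta = -np.inf
        if Delta >= 0:  # accept the step
            w = w + alpha * p
            f = float(f_new)
            g = g_new
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()  # periodic restart along steepest descent
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            trace.append(f)
            if Delta >= 0.75:
                lam = max(lam / 4.0, 1e-20)
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = min(lam + delta_k * (1 - Delta) / pnorm2, 1e20)
        if np.linalg.norm(r) < tol:
            break
    return w, trace


# ----------------------------------------------------------------------
# layer training and encoding


def train_sparse_autoencoder(X, hyper: SparseAEHyper, tol: float = 1e-6) -> SparseAELayer:
    """Train one sparse autoencoder layer on data *X* (values in [0, 1]).

    Weights initialise from N(0, 0.01^2) with the layer seed, biases zero;
    identical data + hyperparameters + seed give identical weights.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 samples")
    d = X.shape[1]
    h = hyper.hidden_size
    if h >= d:
        warnings.warn(f"hidden_size {h} >= input dimension {d}; no compression")
    rng = np.random.default_rng(hyper.seed)
    W1 = 0.01 * rng.standard_normal((h, d))
    W2 = 0.01 * rng.standard_normal((d, h))
    w0 = _pack(W1, np.zeros(h), W2, np.zeros(d))
    w, trace = scg_minimize(lambda v: _ae_cost_grad_flat(v, X, h, hyper),
                            w0, max_iter=hyper.max_epochs, tol=tol)
    W1, b1, W2, b2 = _unpack_ae(w, d, h)
    return SparseAELayer(W1, b1, W2, b2, hyper, cost_trace=[float(c) for c in trace])


def encode(layer: SparseAELayer, X) -> np.ndarray:
    """Hidden code sigmoid(W1 x + b1); entries lie in (0, 1)."""
    X = np.asarray(X, float)
    if X.shape[-1] != layer.W1.shape[1]:
        raise ValueError(f"expected {layer.W1.shape[1]} input features, got {X.shape[-1]}")
    return sigmoid(X @ layer.W1.T + layer.b1)


# ----------------------------------------------------------------------
# stacked classifier


@dataclass
class StackedClassifier:
    """Encoder chain + SoftMax head mapping scaled features to 2-class
    probabilities (class order: 0 = better category, 1 = worse category)."""

    encoders: list[SparseAELayer]
    Ws: np.ndarray  # (n_classes, code_dim)
    bs: np.ndarray  # (n_classes,)
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dim = None
        for enc in self.encoders:
            if dim is not None and enc.W1.shape[1] != dim:
                raise ValueError("encoder dimensions do not chain")
            dim = enc.W1.shape[0]
        if dim is not None and self.Ws.shape[1] != dim:
            raise ValueError("softmax input dimension does not match final code")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _unpack_softmax(w, c, h):
    return w[: c * h].reshape(c, h), w[c * h:]


def _softmax_cost_grad(w, H, Y):
    """Mean cross-entropy of a linear softmax on codes H with one-hot Y."""
    N = H.shape[0]
    c = Y.shape[1]
    Ws, bs = _unpack_softmax(w, c, H.shape[1])
    P = _softmax(H @ Ws.T + bs)
    cost = float(-np.sum(Y * np.log(np.clip(P, 1e-300, None))) / N)
    delta = (P - Y) / N
    return cost, _pack(delta.T @ H, delta.sum(axis=0))


def _stack_shapes(encoders, n_classes):
    shapes = []
    for enc in encoders:
        h, d = enc.W1.shape
        shapes.append((h, d))
    shapes.append((n_classes, encoders[-1].W1.shape[0] if encoders else None))
    return shapes


def _pack_stack(encoders, Ws, bs):
    parts = []
    for enc in encoders:
        parts += [enc.W1, enc.b1]
    parts += [Ws, bs]
    return _pack(*parts)


def _unpack_stack(w, shapes):
    mats = []
    i = 0
    for h, d in shapes:
        W = w[i:i + h * d].reshape(h, d); i += h * d
        b = w[i:i + h]; i += h
        mats.append((W, b))
    return mats


def _stack_cost_grad(w, X, Y, shapes):
    """Cross-entropy of the full encoder chain + softmax; exact backprop."""
    mats = _unpack_stack(w, shapes)
    acts = [X]
    for W, b in mats[:-1]:
        acts.append(sigmoid(acts[-1] @ W.T + b))
    Ws, bs = mats[-1]
    N = X.shape[0]
    P = _softmax(acts[-1] @ Ws.T + bs)
    cost = float(-np.sum(Y * np.log(np.clip(P, 1e-300, None))) / N)
    delta = (P - Y) / N                    # (N, c)
    grads = [(delta.T @ acts[-1], delta.sum(axis=0))]
    back = delta @ Ws
    for li in range(len(mats) - 2, -1, -1):
        A = acts[li + 1]
        d_here = back * A * (1 - A)
        grads.append((d_here.T @ acts[li], d_here.sum(axis=0)))
        if li > 0:
            back = d_here @ mats[li][0]
    grads.reverse()
    return cost, _pack(*[a for Wb in grads for a in Wb])


def train_stacked_classifier(
    X,
    labels,
    hidden_sizes: tuple[int, ...] = (20, 10),
    hyper_kwargs: dict | None = None,
    pretrain_iters: int = 150,
    softmax_iters: int = 150,
    finetune_iters: int = 300,
    seed: int = 0,
) -> StackedClassifier:
    """Greedy layerwise pretraining, SoftMax head, then joint fine-tuning.

    *X* is the scaled training matrix, *labels* the binary outcome (1 =
    worse category).  Each layer's autoencoder trains on the previous
    layer's codes; the head trains by cross-entropy on the final codes; the
    encoder chain + head is then fine-tuned end-to-end by cross-entropy
    (decoders discarded, regularisers dropped).
    """
    X = np.asarray(X, float)
    y = np.asarray(labels, int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0

    hyper_kwargs = dict(hyper_kwargs or {})
    hyper_kwargs.setdefault("max_epochs", pretrain_iters)
    encoders: list[SparseAELayer] = []
    codes = X
    for li, h in enumerate(hidden_sizes):
        hyper = SparseAEHyper(hidden_size=h, seed=seed * 1000 + li, **hyper_kwargs)
        layer = train_sparse_autoencoder(codes, hyper)
        encoders.append(layer)
        codes = encode(layer, codes)

    rng = np.random.default_rng(seed * 1000 + 97)
    Ws0 = 0.01 * rng.standard_normal((2, codes.shape[1]))
    w0 = _pack(Ws0, np.zeros(2))
    w_sm, sm_trace = scg_minimize(lambda v: _softmax_cost_grad(v, codes, Y),
                                  w0, max_iter=softmax_iters, tol=1e-8)
    Ws, bs = _unpack_softmax(w_sm, 2, codes.shape[1])

    shapes = [(enc.W1.shape) for enc in encoders] + [(2, codes.shape[1])]
    w_stack0 = _pack_stack(encoders, Ws, bs)
    w_ft, ft_trace = scg_minimize(lambda v: _stack_cost_grad(v, X, Y, shapes),
                                  w_stack0, max_iter=finetune_iters, tol=1e-8)
    mats = _unpack_stack(w_ft, shapes)
    for enc, (W, b) in zip(encoders, mats[:-1]):
        enc.W1, enc.b1 = W, b
    Ws, bs = mats[-1]

    log = {
        "pretrain_cost": [enc.cost_trace for enc in encoders],
        "softmax_cost": sm_trace,
        "finetune_cost": ft_trace,
    }
    return StackedClassifier(encoders, Ws, bs, training_log=log)


def predict_proba(model: StackedClassifier, X) -> np.ndarray:
    """Subject x class probability matrix P; rows sum to 1."""
    A = np.asarray(X, float)
    for enc in model.encoders:
        A = encode(enc, A)
    return _softmax(A @ model.Ws.T + model.bs)


# ----------------------------------------------------------------------
# serialization and hyperparameter search


def classifier_to_json(model: StackedClassifier, path) -> None:
    d = {
        "encoders": [
            {
                "W1": enc.W1.tolist(), "b1": enc.b1.tolist(),
                "W2": enc.W2.tolist(), "b2": enc.b2.tolist(),
                "hyper": {
                    "hidden_size": enc.hyper.hidden_size,
                    "l2_weight": enc.hyper.l2_weight,
                    "sparsity_reg": enc.hyper.sparsity_reg,
                    "sparsity_prop": enc.hyper.sparsity_prop,
                    "max_epochs": enc.hyper.max_epochs,
                    "seed": enc.hyper.seed,
                },
            }
            for enc in model.encoders
        ],
        "Ws": model.Ws.tolist(),
        "bs": model.bs.tolist(),
    }
    Path(path).write_text(json.dumps(d))


def classifier_from_json(path) -> StackedClassifier:
    d = json.loads(Path(path).read_text())
    encoders = [
        SparseAELayer(
            np.asarray(e["W1"]), np.asarray(e["b1"]),
            np.asarray(e["W2"]), np.asarray(e["b2"]),
            SparseAEHyper(**e["hyper"]),
        )
        for e in d["encoders"]
    ]
    return StackedClassifier(encoders, np.asarray(d["Ws"]), np.asarray(d["bs"]))


def sequential_hyperparameter_search(
    X_train,
    y_train,
    X_val,
    y_val,
    hidden_sizes: tuple[int, ...] = (20, 10),
    l2_grid=(0.001, 0.004, 0.009),
    beta_grid=(2.0, 4.0, 6.0),
    rho_grid=(0.05, 0.10, 0.20),
    seed: int = 0,
    **train_kwargs,
):
    """One-variable-at-a-time grid search on validation accuracy.

    Starting from the middle of each grid, lambda, beta and rho are swept in
    turn, keeping the best value of each before moving to the next.
    Returns ``(best_kwargs, best_accuracy)``.
    """
    current = {"l2_weight": l2_grid[len(l2_grid) // 2],
               "sparsity_reg": beta_grid[len(beta_grid) // 2],
               "sparsity_prop": rho_grid[len(rho_grid) // 2]}

    def val_acc(kwargs):
        model = train_stacked_classifier(X_train, y_train, hidden_sizes=hidden_sizes,
                                         hyper_kwargs=kwargs, seed=seed, **train_kwargs)
        pred = predict_proba(model, X_val).argmax(axis=1)
        return float(np.mean(pred == np.asarray(y_val)))

    best_acc = val_acc(current)
    for key, grid in (("l2_weight", l2_grid), ("sparsity_reg", beta_grid), ("sparsity_prop", rho_grid)):
        for value in grid:
            if value == current[key]:
                continue
            trial = dict(current); trial[key] = value
            acc = val_acc(trial)
            if acc > best_acc:
                best_acc, current = acc, trial
    return current, best_acc
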