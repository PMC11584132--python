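"""Minimal dense networks with hand-derived gradients.

Both adversaries are small multilayer perceptrons: swish hidden units and a
per-cell sigmoid output.  Everything the training loop needs is implemented
directly on numpy arrays:

* forward pass with cached pre-activations,
* reverse-mode gradients w.r.t. parameters and inputs,
* the gradient penalty ``mean_i (||g_i||_2 - 1)^2`` where
  ``g_i = d/dx_i sum_j logit_ij`` is the input-gradient of the summed
  pre-sigmoid critic score of row *i* — including its exact parameter
  gradient, obtained by backpropagating through a forward-mode
  (Jacobian-vector) sweep,
* Adam.

The second-order sweep needs the first two derivatives of each activation;
for swish ``f(x) = x * sigmoid(beta x)`` these are

    f'(x)  = s + beta x s (1 - s)
    f''(x) = 2 beta s (1 - s) + beta^2 x s (1 - s)(1 - 2 s)

with ``s = sigmoid(beta x)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["swish", "MLP", "Adam"]


def swish(x, beta: float = 1.0):
    """Swish activation ``x * sigmoid(beta * x)``."""
    return x * expit(beta * np.asarray(x, dtype=float))


def _swish_d1(x, beta):
    s = expit(beta * x)
    return s + beta * x * s * (1.0 - s)


def _swish_d2(x, beta):
    s = expit(beta * x)
    return 2.0 * beta * s * (1.0 - s) + beta**2 * x * s * (1.0 - s) * (1.0 - 2.0 * s)


def _swish_dbeta(x, beta):
    s = expit(beta * x)
    return x * x * s * (1.0 - s)


class MLP:
    """Fully connected net: swish hidden layers, sigmoid (or identity) output.

    Parameters are Glorot-uniform initialised from the supplied generator so
    a run is reproducible end to end.  ``learn_beta`` promotes the swish
    slope of each hidden layer to a trainable scalar.
    """

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        output_activation: str = "sigmoid",
        swish_beta: float = 1.0,
        learn_beta: bool = False,
    ):
        if len(widths) < 2 or any(w < 1 for w in widths):
            raise ValueError("need input/output widths >= 1")
        if output_activation not in ("sigmoid", "identity"):
            raise ValueError(f"unknown output activation {output_activation!r}")
        self.widths = list(widths)
        self.output_activation = output_activation
        self.learn_beta = learn_beta
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.betas = [float(swish_beta)] * (len(widths) - 2)

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self) -> list[np.ndarray]:
        params = [*self.W, *self.b]
        if self.learn_beta:
            params.append(np.asarray(self.betas, dtype=float))
        return params

    def set_parameters(self, params: list[np.ndarray]) -> None:
        L = self.n_layers
        self.W = [np.asarray(p, dtype=float) for p in params[:L]]
        self.b = [np.asarray(p, dtype=float) for p in params[L : 2 * L]]
        if self.learn_beta:
            self.betas = [float(v) for v in params[2 * L]]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for l in range(self.n_layers):
            state[f"W{l}"] = self.W[l]
            state[f"b{l}"] = self.b[l]
        state["betas"] = np.asarray(self.betas, dtype=float)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for l in range(self.n_layers):
            self.W[l] = np.asarray(state[f"W{l}"], dtype=float)
            self.b[l] = np.asarray(state[f"b{l}"], dtype=float)
        self.betas = [float(v) for v in np.asarray(state["betas"])]

    # -- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Return activated output; with ``cache`` also the intermediates
        needed by :meth:`backward` as ``(out, cache_dict)``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.widths[0]:
            raise ValueError(
                f"expected input width {self.widths[0]}, got shape {X.shape}"
            )
        hs = [X]
        pre = []
        h = X
        for l in range(self.n_layers - 1):
            a = h @ self.W[l] + self.b[l]
            h = swish(a, self.betas[l])
            pre.append(a)
            hs.append(h)
        z = h @ self.W[-1] + self.b[-1]
        out = expit(z) if self.output_activation == "sigmoid" else z
        if cache:
            return out, {"hs": hs, "pre": pre, "z": z, "out": out}
        return out

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # -- reverse mode -------------------------------------------------------
    def backward(self, cache, grad_out=None, grad_logits=None):
        """Gradients of a scalar loss given its gradient w.r.t. the output
        (post-activation) and/or the output logits.

        Returns ``(grads, grad_input)`` where ``grads`` aligns with
        :meth:`parameters`.
        """
        hs, pre, z = cache["hs"], cache["pre"], cache["z"]
        dz = np.zeros_like(z)
        if grad_logits is not None:
            dz += grad_logits
        if grad_out is not None:
            if self.output_activation == "sigmoid":
                s = cache["out"]
                dz += grad_out * s * (1.0 - s)
            else:
                dz += grad_out
        dW = [None] * self.n_layers
        db = [None] * self.n_layers
        dbeta = np.zeros(len(self.betas))
        dW[-1] = hs[-1].T @ dz
        db[-1] = dz.sum(axis=0)
        dh = dz @ self.W[-1].T
        for l in range(self.n_layers - 2, -1, -1):
            da = dh * _swish_d1(pre[l], self.betas[l])
            dbeta[l] = float(np.sum(dh * _swish_dbeta(pre[l], self.betas[l])))
            dW[l] = hs[l].T @ da
            db[l] = da.sum(axis=0)
            dh = da @ self.W[l].T
        grads = [*dW, *db]
        if self.learn_beta:
            grads.append(dbeta)
        return grads, dh

    def input_gradient_of_logit_sum(self, X: np.ndarray) -> np.ndarray:
        """``g_i = d/dx_i sum_j z_ij`` for every row, ``z`` the output logits."""
        _, cache = self.forward(X, cache=True)
        _, g = self.backward(cache, grad_logits=np.ones_like(cache["z"]))
        return g

    # -- gradient penalty (second order) -------------------------------------
    def gradient_penalty(self, X: np.ndarray):
        """Penalty ``mean_i (||g_i|| - 1)^2`` and its parameter gradients.

        The parameter gradient needs differentiation through the
        input-gradient itself.  Writing ``T = sum_i v_i . g_i`` with the
        constant co-vector ``v_i = (2/n)(||g_i|| - 1) g_i / ||g_i||``, the
        chain rule gives ``d(penalty)/dtheta = dT/dtheta``, and ``T`` equals
        the directional (forward-mode) derivative of the summed logits along
        ``V`` — so one tangent sweep plus a reverse sweep over the doubled
        computation graph yields the exact gradient.  The trainable swish
        slope, when enabled, is treated as a constant inside this term.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        _, cache = self.forward(X, cache=True)
        _, g = self.backward(cache, grad_logits=np.ones_like(cache["z"]))
        norms = np.linalg.norm(g, axis=1)
        penalty = float(np.mean((norms - 1.0) ** 2))
        coef = np.where(norms > 1e-12, 2.0 * (norms - 1.0) / np.maximum(norms, 1e-12), 0.0)
        V = (coef[:, None] * g) / n

        hs, pre = cache["hs"], cache["pre"]
        # forward-mode sweep: tangents of every hidden activation along V
        hdots = [V]
        adots = []
        hdot = V
        for l in range(self.n_layers - 1):
            adot = hdot @ self.W[l]
            hdot = _swish_d1(pre[l], self.betas[l]) * adot
            adots.append(adot)
            hdots.append(hdot)
        # T = sum of zdot = sum(hdots[-1] @ W[-1]); reverse over (h, hdot)
        dW = [np.zeros_like(W) for W in self.W]
        db = [np.zeros_like(b) for b in self.b]
        ones = np.ones((n, self.widths[-1]))
        dW[-1] = hdots[-1].T @ ones
        P = np.zeros_like(hs[-1])          # dT/dh
        Q = ones @ self.W[-1].T            # dT/dhdot
        for l in range(self.n_layers - 2, -1, -1):
            f1 = _swish_d1(pre[l], self.betas[l])
            f2 = _swish_d2(pre[l], self.betas[l])
            A = P * f1 + Q * f2 * adots[l]  # dT/da
            B = Q * f1                      # dT/dadot
            dW[l] = hs[l].T @ A + hdots[l].T @ B
            db[l] = A.sum(axis=0)
            P = A @ self.W[l].T
            Q = B @ self.W[l].T
        grads = [*dW, *db]
        if self.learn_beta:
            grads.append(np.zeros(len(self.betas)))
        return penalty, grads


class Adam:
    """Adam with the conventional (0.9, 0.999) moment decays."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(np.asarray(p, dtype=float)) for p in params]
        self.v = [np.zeros_like(np.asarray(p, dtype=float)) for p in params]
        self.t = 0

    def step(self, params, grads):
        """Return updated copies of ``params`` given matching ``grads``."""
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            g = np.asarray(g, dtype=float)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
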