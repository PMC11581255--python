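"""Convolutional autoencoder (CAE) classifier.

The CAE encodes ``d``-length patches of its input through ``m`` kernels
(a convolution expressed patch-wise: ``o_ij = relu(w_j . x_i + b_j)``),
decodes them linearly (``x_hat_i = W_hat o_i + b_hat``) and is trained
by minibatch stochastic gradient descent on the mean squared
reconstruction error over patches,

    J_cae = (1/p) sum_i ||x_i - x_hat_i||^2 .

Class labels come from a softmax head on the patch-pooled code,
trained jointly with a composite loss ``J_cae + lambda * CE``; the
reconstruction term regularizes the code, the cross-entropy term makes
it discriminative.  All gradients are analytic (verified against
central finite differences in the test suite) and runs are
reproducible from the seed.

Inputs are 1-D sample vectors (e.g. pooled feature vectors from the
dense feature extractor, or flattened preprocessed epochs); samples are
zero-padded to a multiple of the patch length and cut into
non-overlapping patches by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def relu(x):
    """Rectifier ``max(x, 0)``, elementwise."""
    return np.maximum(x, 0.0)


@dataclass
class CAEConfig:
    n_kernels: int = 32          # m
    patch_len: int = 4           # d
    stride: int | None = None    # None -> non-overlapping (stride = d)
    num_classes: int = 2
    lambda_ce: float = 1.0
    lr: float = 0.1
    batch_size: int = 8
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if self.patch_len < 1 or self.n_kernels < 1:
            raise ValueError("patch_len and n_kernels must be positive")


@dataclass
class CAEParams:
    """theta = {W, b, W_hat, b_hat} plus the softmax head (Wc, bc)."""

    W: np.ndarray        # (m, d)
    b: np.ndarray        # (m,)
    W_hat: np.ndarray    # (d, m)
    b_hat: np.ndarray    # (d,)
    Wc: np.ndarray       # (K, m)
    bc: np.ndarray       # (K,)

    @classmethod
    def init(cls, cfg: CAEConfig, rng: np.random.Generator) -> "CAEParams":
        m, d, k = cfg.n_kernels, cfg.patch_len, cfg.num_classes
        return cls(W=rng.standard_normal((m, d)) * np.sqrt(2.0 / d),
                   b=np.zeros(m),
                   W_hat=rng.standard_normal((d, m)) * np.sqrt(1.0 / m),
                   b_hat=np.zeros(d),
                   Wc=np.zeros((k, m)),  # head starts at uniform probabilities
                   bc=np.zeros(k))

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b, "W_hat": self.W_hat,
                "b_hat": self.b_hat, "Wc": self.Wc, "bc": self.bc}


def encode(x_patch: np.ndarray, params: CAEParams) -> np.ndarray:
    """Code of one patch: ``o_j = relu(w_j . x + b_j)`` (non-negative)."""
    x_patch = np.asarray(x_patch, dtype=float)
    if x_patch.shape[-1] != params.W.shape[1]:
        raise ValueError("patch length does not match encoder kernels")
    return relu(x_patch @ params.W.T + params.b)


def decode(o: np.ndarray, params: CAEParams) -> np.ndarray:
    """Linear reconstruction ``x_hat = W_hat o + b_hat``."""
    o = np.asarray(o, dtype=float)
    if o.shape[-1] != params.W_hat.shape[1]:
        raise ValueError("code length does not match decoder kernels")
    return o @ params.W_hat.T + params.b_hat


def reconstruction_cost(patches: np.ndarray, params: CAEParams) -> float:
    """Mean squared reconstruction error over a patch set."""
    patches = np.atleast_2d(np.asarray(patches, dtype=float))
    if patches.shape[0] == 0:
        raise ValueError("need at least one patch")
    xhat = decode(encode(patches, params), params)
    return float(np.mean(np.sum((patches - xhat) ** 2, axis=1)))


def extract_patches(x: np.ndarray, d: int, stride: int | None = None
                    ) -> np.ndarray:
    """Cut a 1-D sample into ``d``-length patches (zero-padded tail)."""
    x = np.asarray(x, dtype=float).ravel()
    stride = d if stride is None else stride
    pad = (-x.size) % d if x.size % d else 0
    if pad:
        x = np.pad(x, (0, pad))
    starts = range(0, x.size - d + 1, stride)
    return np.stack([x[s:s + d] for s in starts])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_backward(params: CAEParams, X_patches: np.ndarray,
                      y_onehot: np.ndarray | None, lam: float):
    """Loss and analytic gradients for a batch.

    ``X_patches``: (n, p, d).  Returns (J_cae, ce, grads dict).
    """
    n, p, d = X_patches.shape
    pre = X_patches @ params.W.T + params.b           # (n, p, m)
    O = relu(pre)
    Xhat = O @ params.W_hat.T + params.b_hat          # (n, p, d)
    diff = Xhat - X_patches
    j_cae = float(np.mean(np.sum(diff ** 2, axis=2)))  # mean over patches & samples

    # reconstruction gradients (J averaged over patches then samples)
    dXhat = 2.0 * diff / (p * n)                      # (n, p, d)
    gW_hat = np.einsum("npd,npm->dm", dXhat, O)
    gb_hat = dXhat.sum(axis=(0, 1))
    dO = dXhat @ params.W_hat                          # (n, p, m)

    ce = 0.0
    gWc = np.zeros_like(params.Wc)
    gbc = np.zeros_like(params.bc)
    if y_onehot is not None:
        z = O.mean(axis=1)                             # pooled code (n, m)
        probs = _softmax(z @ params.Wc.T + params.bc)  # (n, K)
        ce = float(-np.mean(np.sum(y_onehot * np.log(probs + 1e-300), axis=1)))
        dlogits = lam * (probs - y_onehot) / n         # (n, K)
        gWc = dlogits.T @ z
        gbc = dlogits.sum(axis=0)
        dz = dlogits @ params.Wc                       # (n, m)
        dO = dO + dz[:, None, :] / p

    dpre = dO * (pre > 0)
    gW = np.einsum("npm,npd->md", dpre, X_patches)
    gb = dpre.sum(axis=(0, 1))
    grads = {"W": gW, "b": gb, "W_hat": gW_hat, "b_hat": gb_hat,
             "Wc": gWc, "bc": gbc}
    return j_cae, ce, grads


class UntrainedModelError(RuntimeError):
    """Raised when prediction is requested before training."""


class CAEClassifier:
    """Patch autoencoder + softmax head trained jointly by SGD."""

    def __init__(self, config: CAEConfig | None = None):
        self.config = config or CAEConfig()
        self.params: CAEParams | None = None
        self.classes_: list | None = None
        self.loss_trace: list[dict] = []

    # -- training ----------------------------------------------------

    def _patchify(self, X: np.ndarray) -> np.ndarray:
        return np.stack([extract_patches(x, self.config.patch_len,
                                         self.config.stride) for x in X])

    def fit(self, X: np.ndarray, labels) -> "CAEClassifier":
        """Minibatch SGD on ``J_cae + lambda * CE``; seeded shuffling.

        Aborts with diagnostics if the loss leaves the finite range.
        """
        cfg = self.config
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = np.asarray(labels)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = sorted(set(labels.tolist()))
        if len(self.classes_) > cfg.num_classes:
            raise ValueError("more classes than configured")
        idx = {c: i for i, c in enumerate(self.classes_)}
        y = np.zeros((X.shape[0], cfg.num_classes))
        for i, lab in enumerate(labels):
            y[i, idx[lab]] = 1.0

        rng = np.random.default_rng(cfg.seed)
        self.params = CAEParams.init(cfg, rng)
        P = self._patchify(X)                         # (n, p, d)
        n = P.shape[0]
        self.loss_trace = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            # overflow in a diverging run is caught by the finite check below
            with np.errstate(over="ignore", invalid="ignore"):
                for s in range(0, n, cfg.batch_size):
                    batch = order[s:s + cfg.batch_size]
                    _, _, grads = _forward_backward(self.params, P[batch],
                                                    y[batch], cfg.lambda_ce)
                    for name, arr in self.params.arrays().items():
                        arr -= cfg.lr * grads[name]
                j_cae, ce, _ = _forward_backward(self.params, P, y,
                                                 cfg.lambda_ce)
            if not (np.isfinite(j_cae) and np.isfinite(ce)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: "
                    f"J_cae={j_cae}, CE={ce} (lr={cfg.lr})")
            acc = float(np.mean(self.predict(X) == labels))
            self.loss_trace.append({"epoch": epoch, "j_cae": j_cae,
                                    "cross_entropy": ce, "accuracy": acc})
        return self

    # -- inference ---------------------------------------------------

    def _require_trained(self) -> CAEParams:
        if self.params is None or self.classes_ is None:
            raise UntrainedModelError("fit() the classifier first")
        return self.params

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Patch-pooled encoder code per sample."""
        params = self._require_trained()
        P = self._patchify(np.atleast_2d(np.asarray(X, dtype=float)))
        return encode(P, params).mean(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax scores; every row sums to one."""
        params = self._require_trained()
        z = self.latent(X)
        return _softmax(z @ params.Wc.T + params.bc)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray(self.classes_)[np.argmax(probs, axis=1)]

    def reconstruction_error(self, X: np.ndarray) -> float:
        params = self._require_trained()
        P = self._patchify(np.atleast_2d(np.asarray(X, dtype=float)))
        return reconstruction_cost(P.reshape(-1, P.shape[-1]), params)


def train_sgd(X: np.ndarray, labels, config: CAEConfig | None = None
              ) -> tuple[CAEClassifier, list[dict]]:
    """Convenience wrapper: fit a classifier, return it with its trace."""
    clf = CAEClassifier(config).fit(X, labels)
    return clf, clf.loss_trace
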