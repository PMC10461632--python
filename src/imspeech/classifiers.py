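"""Classifiers: the multireceptive-field CNN and classical comparators.

The MRF-CNN runs four single-receptive-field (SRF) branches in parallel over
the same 1-D feature vector.  Each branch is two convolution blocks
(conv(1xk) -> batch-norm -> ReLU -> average-pool) followed by one fully
connected layer; the four branch outputs are concatenated and fed to a single
softmax classification head.  The branches differ only in their first-layer
kernel width, so each sees a different receptive field — small kernels pick
up statistic-level patterns, large kernels span several sub-bands.

Stated training protocol: Adam, initial learning rate 0.001, 2000 iterations
(read as optimizer steps), no early stopping.  Constants the protocol leaves
open, with the defaults used here: first kernels (20, 40, 60, 80) — only the
smallest is prescribed, the rest are an arithmetic ladder; second kernel 10;
filter counts (8, 16); pool width 4; 32 fully-connected units per branch;
mini-batches of 32; a 10% held-out validation split for the training curves.

The network is implemented directly in NumPy (forward and backward passes,
Adam) so that training is exactly reproducible for a fixed seed.  Classical
comparators (linear/RBF SVM, LDA, k-NN with k=4) wrap scikit-learn behind the
same fit/predict interface; the RBF bandwidth uses a median pairwise-distance
heuristic on a training subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io import ConfigurationError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv1D:
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, (out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.k = kernel

    def out_length(self, length: int) -> int:
        if length < self.k:
            raise ConfigurationError(
                f"kernel of width {self.k} wider than input of length {length}"
            )
        return length - self.k + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[2] < self.k:
            raise ConfigurationError(
                f"kernel of width {self.k} wider than input of length {x.shape[2]}"
            )
        self._xw = sliding_window_view(x, self.k, axis=2)  # (B, C, L', k)
        return (np.einsum("ock,bclk->bol", self.W, self._xw, optimize=True)
                + self.b[None, :, None])

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bol,bclk->ock", g, self._xw, optimize=True)
        self.db = g.sum(axis=(0, 2))
        gp = np.pad(g, ((0, 0), (0, 0), (self.k - 1, self.k - 1)))
        gw = sliding_window_view(gp, self.k, axis=2)  # (B, O, L, k)
        return np.einsum("ock,bolk->bcl", self.W[:, :, ::-1], gw, optimize=True)

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm1D:
    def __init__(self, channels: int):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)

    def out_length(self, length: int) -> int:
        return length

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = (1 - _BN_MOMENTUM) * self.run_mean + _BN_MOMENTUM * mu
            self.run_var = (1 - _BN_MOMENTUM) * self.run_var + _BN_MOMENTUM * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + _BN_EPS)[None, :, None]
        self._xhat = (x - mu[None, :, None]) / self._std
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0] * g.shape[2]
        self.dgamma = (g * self._xhat).sum(axis=(0, 2))
        self.dbeta = g.sum(axis=(0, 2))
        dxhat = g * self.gamma[None, :, None]
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (dxhat - sum_dxhat / n - self._xhat * sum_dxhat_xhat / n) / self._std

    def params_and_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def out_length(self, length: int) -> int:
        return length

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params_and_grads(self):
        return []


class _AvgPool1D:
    def __init__(self, width: int):
        self.p = width

    def out_length(self, length: int) -> int:
        out = length // self.p
        if out < 1:
            raise ConfigurationError(
                f"average pool of width {self.p} collapses length {length} to zero"
            )
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_len = x.shape[2]
        trunc = (x.shape[2] // self.p) * self.p
        xr = x[:, :, :trunc].reshape(x.shape[0], x.shape[1], trunc // self.p, self.p)
        return xr.mean(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = np.repeat(g, self.p, axis=2) / self.p
        if out.shape[2] < self._in_len:  # truncated tail gets zero gradient
            out = np.pad(out, ((0, 0), (0, 0), (0, self._in_len - out.shape[2])))
        return out

    def params_and_grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)

    def params_and_grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params_and_grads) -> None:
        self.t += 1
        for param, grad in params_and_grads:
            key = id(param)
            m = self._m.setdefault(key, np.zeros_like(param))
            v = self._v.setdefault(key, np.zeros_like(param))
            m += (1 - self.b1) * (grad - m)
            v += (1 - self.b2) * (grad * grad - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class SRFBranchSpec:
    """Architecture constants of one single-receptive-field branch."""

    first_kernel: int = 20
    second_kernel: int = 10
    filters: tuple[int, int] = (8, 16)
    pool: int = 4
    fc_units: int = 32


@dataclass
class MRFNetworkSpec:
    """Four parallel SRF branches, concatenated, one softmax head."""

    branches: list[SRFBranchSpec] = field(
        default_factory=lambda: [SRFBranchSpec(first_kernel=k)
                                 for k in (20, 40, 60, 80)]
    )
    n_classes: int = 6
    input_length: int = 384
    relu_before_pool: bool = True

    def __post_init__(self) -> None:
        kernels = [b.first_kernel for b in self.branches]
        if len(set(kernels)) != len(kernels):
            raise ConfigurationError("branch first kernels must be distinct")
        if kernels[0] != min(kernels):
            raise ConfigurationError("branch 1 must have the smallest kernel")

    @property
    def concat_width(self) -> int:
        return sum(b.fc_units for b in self.branches)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _Branch:
    """conv -> BN -> ReLU -> pool, twice, then flatten -> FC."""

    def __init__(self, spec: SRFBranchSpec, input_length: int,
                 rng: np.random.Generator, relu_before_pool: bool = True):
        f1, f2 = spec.filters
        conv1 = _Conv1D(1, f1, spec.first_kernel, rng)
        conv2 = _Conv1D(f1, f2, spec.second_kernel, rng)
        block1 = [conv1, _BatchNorm1D(f1)]
        block2 = [conv2, _BatchNorm1D(f2)]
        act_pool = lambda p: ([_ReLU(), _AvgPool1D(p)] if relu_before_pool
                              else [_AvgPool1D(p), _ReLU()])
        self.layers = block1 + act_pool(spec.pool) + block2 + act_pool(spec.pool)
        length = input_length
        for layer in self.layers:
            length = layer.out_length(length)
        self.layers.append(_Flatten())
        self.layers.append(_Dense(f2 * length, spec.fc_units, rng))
        self.spec = spec

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out


@dataclass
class TrainingLog:
    steps: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class CNNClassifier:
    """MRF-CNN (or a single SRF branch) with a softmax head.

    ``fit`` runs exactly ``iterations`` Adam steps of softmax cross-entropy
    on shuffled mini-batches; everything is seeded and deterministic.
    """

    def __init__(self, spec: MRFNetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.branches = [
            _Branch(b, spec.input_length, rng, spec.relu_before_pool)
            for b in spec.branches
        ]
        self.head = _Dense(spec.concat_width, spec.n_classes, rng)
        self.log = TrainingLog()

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        if X.shape[1] != self.spec.input_length:
            raise ConfigurationError(
                f"feature length {X.shape[1]} != spec input_length "
                f"{self.spec.input_length}"
            )
        x3 = X[:, None, :]
        outs = [br.forward(x3, training) for br in self.branches]
        concat = np.concatenate(outs, axis=1)
        self._widths = [o.shape[1] for o in outs]
        return self.head.forward(concat, training)

    def _backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits)
        start = 0
        for br, w in zip(self.branches, self._widths):
            br.backward(g[:, start:start + w])
            start += w

    def _params_and_grads(self):
        out = []
        for br in self.branches:
            out.extend(br.params_and_grads())
        out.extend(self.head.params_and_grads())
        return out

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, lr: float = 1e-3,
            iterations: int = 2000, batch_size: int = 32,
            val_fraction: float = 0.1, log_every: int = 50) -> "CNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ConfigurationError("training labels contain a single class")
        if classes.max() >= self.spec.n_classes or classes.min() < 0:
            raise ConfigurationError("label outside [0, n_classes)")
        rng = np.random.default_rng(self.seed + 1)
        n = X.shape[0]
        n_val = int(round(val_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.unique(y[tr_idx]).size < 2:  # tiny sets: fall back to no split
            tr_idx, val_idx = perm, perm[:0]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        opt = _Adam(lr)
        order = rng.permutation(len(Xtr))
        pos = 0
        for step in range(1, iterations + 1):
            if pos + batch_size > len(Xtr):
                order = rng.permutation(len(Xtr))
                pos = 0
            batch = order[pos:pos + batch_size]
            pos += batch_size
            xb, yb = Xtr[batch], ytr[batch]
            logits = self._forward(xb, training=True)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            g = probs.copy()
            g[np.arange(len(yb)), yb] -= 1.0
            self._backward(g / len(yb))
            opt.step(self._params_and_grads())
            if step % log_every == 0 or step == 1 or step == iterations:
                self.log.steps.append(step)
                self.log.loss.append(float(loss))
                if len(Xval):
                    pred = self.predict(Xval)[0]
                    self.log.val_accuracy.append(float(np.mean(pred == yval)))
                else:
                    self.log.val_accuracy.append(float("nan"))
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(X, dtype=float), training=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        probs = self.predict_proba(X)
        return probs.argmax(axis=1), probs


def build_srf_cnn(branch: SRFBranchSpec, input_length: int, n_classes: int = 6,
                  seed: int = 0, relu_before_pool: bool = True) -> CNNClassifier:
    """A single-branch network with its own softmax head."""
    spec = MRFNetworkSpec(branches=[branch], n_classes=n_classes,
                          input_length=input_length,
                          relu_before_pool=relu_before_pool)
    return CNNClassifier(spec, seed=seed)


def build_mrf_cnn(spec: MRFNetworkSpec, seed: int = 0) -> CNNClassifier:
    """The four-branch multireceptive-field network."""
    return CNNClassifier(spec, seed=seed)


def train(model: CNNClassifier, X: np.ndarray, y: np.ndarray, lr: float = 1e-3,
          iterations: int = 2000, batch_size: int = 32) -> CNNClassifier:
    """Run exactly ``iterations`` Adam steps; returns the trained model."""
    return model.fit(X, y, lr=lr, iterations=iterations, batch_size=batch_size)


def predict(model: CNNClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(class ids, probability matrix) for a trained model."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# classical comparators
# ---------------------------------------------------------------------------

class _MedianHeuristicRBFSVC:
    """RBF SVM whose bandwidth comes from a median pairwise-distance
    heuristic on a training subsample: gamma = 1 / (2 * median_dist**2)."""

    def __init__(self, subsample: int = 200, seed: int = 0):
        self.subsample = subsample
        self.seed = seed
        self.est: SVC | None = None

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(len(X))[: self.subsample]
        med = np.median(pdist(X[idx])) if len(idx) > 1 else 1.0
        gamma = 1.0 / (2 * med * med) if med > 0 else "scale"
        self.est = SVC(kernel="rbf", gamma=gamma)
        self.est.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.est.predict(X)


def classical_classifiers(name: str, knn_neighbors: int = 4, seed: int = 0):
    """Comparator by name: ``svm_lin``, ``svm_rbf``, ``lda``, or ``knn``."""
    if name == "svm_lin":
        return SVC(kernel="linear")
    if name == "svm_rbf":
        return _MedianHeuristicRBFSVC(seed=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=knn_neighbors)
    raise ConfigurationError(f"unknown classifier {name!r}")
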