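"""Classifier family and evaluation harness for vocalization images.

Contains declarative specs for the three network architectures used to
decode emitter class from single calls (spectrogram CNN, 9-feature dense
network, semi-convolutional network over the 457-dim extended feature
vector), their staged training protocols, on-the-fly augmentation, class
balancing, the cross-validation schemes (leave-one-subject and random
folds, plus shuffled-label controls), and the ridge/SVM baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# architecture specs


@dataclass(frozen=True)
class ConvNetSpec:
    """Spectrogram CNN: 6 conv layers + 3 fully connected layers.

    Defaults encode the full-size architecture (256 units per conv layer,
    kernels 10/5/3/3/3/3, strides 2,2,1,1,1,1; 120-unit FC layers, 80 for
    the broadband variant).  ``units``/``fc_units`` are configuration so
    reduced (faster) instances can be built.
    """

    kernels: tuple = (10, 5, 3, 3, 3, 3)
    strides: tuple = (2, 2, 1, 1, 1, 1)
    units: int = 256
    fc_units: int = 120
    n_fc: int = 3
    head: str = "sigmoid"   # sigmoid | softmax
    n_out: int = 1
    input_hw: tuple = (100, 100)


@dataclass(frozen=True)
class DenseNetSpec:
    """Feature network: 4 fully connected layers of 70 units, 9 inputs."""

    n_layers: int = 4
    units: int = 70
    n_in: int = 9
    head: str = "sigmoid"
    n_out: int = 1


@dataclass(frozen=True)
class SemiConvNetSpec:
    """Extended-feature network: three parallel 1-D conv stacks for the FF
    line (100), time marginal (100) and frequency marginal (233), whose
    outputs join the 24 scalars in 3 fully connected layers of 90 units."""

    kernels: tuple = (7, 5, 3, 3, 3)
    strides: tuple = (2, 2, 1, 1, 1)
    units: int = 32
    fc_units: int = 90
    n_fc: int = 3
    n_scalars: int = 24
    stream_dims: tuple = (100, 100, 233)
    head: str = "sigmoid"
    n_out: int = 1


def head_for_task(task: str, n_individuals: int = 17):
    """Output head per classification task (binary sex/strain/broadband;
    4-way peaks/breaks; 3-way direction; per-individual softmax)."""
    return {
        "sex": ("sigmoid", 1), "strain": ("sigmoid", 1),
        "broadband": ("sigmoid", 1),
        "peaks": ("softmax", 4), "breaks": ("softmax", 4),
        "direction": ("softmax", 3),
        "individual": ("softmax", n_individuals),
    }[task]


def build_network(spec, seed: int = 0) -> nn.Network:
    """Instantiate a network from its spec (Xavier init, batch-norm on every
    layer, ReLU activations, dropout on fully connected layers)."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, ConvNetSpec):
        layers = []
        in_ch = 1
        h, w = spec.input_hw
        for li, (k, s) in enumerate(zip(spec.kernels, spec.strides)):
            layers += [nn.Conv2D(in_ch, spec.units, k, s, rng,
                                 is_input_layer=(li == 0)),
                       nn.BatchNorm(spec.units), nn.ReLU()]
            h = -(-h // s)
            w = -(-w // s)
            in_ch = spec.units
        layers.append(nn.Flatten())
        dim = h * w * in_ch
        for _ in range(spec.n_fc):
            layers += [nn.Dense(dim, spec.fc_units, rng),
                       nn.BatchNorm(spec.fc_units), nn.ReLU(),
                       nn.Dropout(0.0)]
            dim = spec.fc_units
        layers.append(nn.Dense(dim, spec.n_out, rng))
        return nn.Network(layers, spec.head, spec.n_out)

    if isinstance(spec, DenseNetSpec):
        layers = []
        dim = spec.n_in
        for _ in range(spec.n_layers):
            layers += [nn.Dense(dim, spec.units, rng),
                       nn.BatchNorm(spec.units), nn.ReLU(), nn.Dropout(0.0)]
            dim = spec.units
        layers.append(nn.Dense(dim, spec.n_out, rng))
        return nn.Network(layers, spec.head, spec.n_out)

    if isinstance(spec, SemiConvNetSpec):
        return _build_semiconv(spec, rng)
    raise ValueError(f"unknown spec type {type(spec)!r}")


class _ConvStack:
    def __init__(self, spec: SemiConvNetSpec, length: int, rng):
        self.layers = []
        in_ch = 1
        n = length
        for k, s in zip(spec.kernels, spec.strides):
            self.layers += [nn.Conv1D(in_ch, spec.units, k, s, rng),
                            nn.BatchNorm(spec.units), nn.ReLU()]
            n = -(-n // s)
            in_ch = spec.units
        self.out_dim = n * in_ch

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        d = d.reshape(d.shape[0], -1, self.layers[0].out_ch)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class SemiConvNetwork(nn.Network):
    """Three parallel 1-D conv stacks + scalar inputs -> FC trunk.

    Input is the flat 457-vector; it is split into the 24 scalars and the
    three 1-D streams internally.
    """

    def __init__(self, spec: SemiConvNetSpec, rng):
        self.spec = spec
        self.stacks = [_ConvStack(spec, d, rng) for d in spec.stream_dims]
        trunk = []
        dim = spec.n_scalars + sum(s.out_dim for s in self.stacks)
        for _ in range(spec.n_fc):
            trunk += [nn.Dense(dim, spec.fc_units, rng),
                      nn.BatchNorm(spec.fc_units), nn.ReLU(),
                      nn.Dropout(0.0)]
            dim = spec.fc_units
        trunk.append(nn.Dense(dim, spec.n_out, rng))
        super().__init__(trunk, spec.head, spec.n_out)
        self._splits = np.cumsum(
            [spec.n_scalars] + list(spec.stream_dims))[:-1]

    def params(self):
        ps = [p for st in self.stacks for layer in st.layers
              for p in layer.params()]
        return ps + super().params()

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=nn.DTYPE)
        parts = np.split(x, self._splits, axis=1)
        scalars, streams = parts[0], parts[1:]
        outs = [scalars]
        for st, s in zip(self.stacks, streams):
            outs.append(st.forward(s[:, :, None], train, rng))
        self._dims = [o.shape[1] for o in outs]
        z = np.concatenate(outs, axis=1)
        for layer in self.layers:
            z = layer.forward(z, train=train, rng=rng)
        return z

    def backward(self, dlogits):
        d = dlogits.astype(nn.DTYPE)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        chunks = np.split(d, np.cumsum(self._dims)[:-1], axis=1)
        for st, c in zip(self.stacks, chunks[1:]):
            st.backward(c)
        return chunks[0]


def _build_semiconv(spec, rng):
    return SemiConvNetwork(spec, rng)


# ---------------------------------------------------------------------------
# training protocols


@dataclass(frozen=True)
class Stage:
    epochs: int
    lr: float | tuple  # constant, or ("quadratic", lr0, lr1)
    dropout: float

    def lr_at(self, frac: float) -> float:
        if isinstance(self.lr, tuple):
            kind, lr0, lr1 = self.lr
            if kind != "quadratic":
                raise ValueError(kind)
            return lr1 + (lr0 - lr1) * (1.0 - frac) ** 2
        return float(self.lr)


@dataclass(frozen=True)
class TrainProtocol:
    stages: tuple
    batch_size: int = 64

    def scaled(self, factor: float) -> "TrainProtocol":
        """Proportionally reduce stage lengths (minimum one epoch)."""
        return TrainProtocol(tuple(
            Stage(max(int(round(s.epochs * factor)), 1), s.lr, s.dropout)
            for s in self.stages), self.batch_size)


def protocol_spectrogram() -> TrainProtocol:
    """Spectrogram-to-class networks: 3 stages."""
    return TrainProtocol((Stage(40, 1e-3, 0.0), Stage(25, 1e-4, 0.5),
                          Stage(25, 1e-5, 0.7)))


def protocol_spectrogram_features() -> TrainProtocol:
    """Spectrogram-to-feature networks: 2 stages."""
    return TrainProtocol((Stage(40, 1e-3, 0.0), Stage(25, 1e-4, 0.5)))


def protocol_features() -> TrainProtocol:
    """Feature-to-class dense network: 2 stages, quadratic lr decay in the
    second."""
    return TrainProtocol((Stage(150, 1e-3, 0.0),
                          Stage(200, ("quadratic", 1e-3, 1e-5), 0.5)))


def protocol_extended() -> TrainProtocol:
    """Extended-feature semi-convolutional network: 4 stages."""
    return TrainProtocol((Stage(50, 1e-3, 0.0), Stage(100, 1e-4, 0.3),
                          Stage(100, 1e-5, 0.5), Stage(100, 2e-6, 0.5)))


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly augmentation on [0, 1]-normalized intensities.

    2-D images: time clip up to 10 % of the occupied duration at each end,
    amplitude x U[0.5, 1.5], additive Gaussian noise with variance
    U[0, 0.01].  FF-line / time-marginal streams use clip + noise without
    amplification; the frequency marginal uses amplitude U[0.8, 1.2] +
    noise (no clip: its axis is frequency, not time).
    """

    clip_frac: float = 0.10
    amp_range: tuple = (0.5, 1.5)
    noise_var_range: tuple = (0.0, 0.01)
    freq_amp_range: tuple = (0.8, 1.2)


def augment_image(img: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment one 2-D call image (freq x time, [0,1] scale, left-aligned).

    Pure function; the label is untouched by construction.
    """
    out = np.array(img, dtype=np.float64)
    occupied = np.flatnonzero(out.sum(axis=0) > 0)
    if occupied.size > 0 and cfg.clip_frac > 0:
        n = occupied[-1] + 1
        c0 = int(rng.integers(0, max(int(cfg.clip_frac * n), 0) + 1))
        c1 = int(rng.integers(0, max(int(cfg.clip_frac * n), 0) + 1))
        if c0 + c1 < n:
            kept = out[:, c0:n - c1]
            out[:] = 0.0
            out[:, :kept.shape[1]] = kept  # stay left-aligned
    out *= rng.uniform(*cfg.amp_range)
    var = rng.uniform(*cfg.noise_var_range)
    if var > 0:
        out += rng.normal(0.0, np.sqrt(var), size=out.shape)
    return np.clip(out, 0.0, 1.0)


def augment_vector(vec: np.ndarray, stream: str, cfg: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Augment one 1-D stream ("ff_line"/"time_marginal": clip + noise;
    "freq_marginal": amplitude + noise)."""
    out = np.array(vec, dtype=np.float64)
    if stream in ("ff_line", "time_marginal"):
        occ = np.flatnonzero(out > 0)
        if occ.size > 0 and cfg.clip_frac > 0:
            n = occ[-1] + 1
            c0 = int(rng.integers(0, int(cfg.clip_frac * n) + 1))
            c1 = int(rng.integers(0, int(cfg.clip_frac * n) + 1))
            if c0 + c1 < n:
                kept = out[c0:n - c1]
                out[:] = 0.0
                out[:len(kept)] = kept
    elif stream == "freq_marginal":
        out *= rng.uniform(*cfg.freq_amp_range)
    else:
        raise ValueError(stream)
    var = rng.uniform(*cfg.noise_var_range)
    if var > 0:
        out += rng.normal(0.0, np.sqrt(var), size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# class balance


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class loss weights inversely proportional to class frequency,
    normalized to mean 1 over classes."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if not np.array_equal(classes, np.arange(len(classes))):
        raise ValueError("labels must be 0..k-1 coded")
    w = 1.0 / counts
    return w / w.mean()


def downsample_balance(X, y, rng: np.random.Generator):
    """Equalize class counts by random downsampling of the larger classes
    (the balancing used for the ridge/SVM baselines)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# training


def train(model: nn.Network, X, y, protocol: TrainProtocol, seed: int = 0,
          weights: np.ndarray | None = None,
          augment_fn=None, verbose: bool = False):
    """Run the staged training protocol; returns the per-batch loss trace.

    ``augment_fn(x_batch, rng) -> x_batch`` is applied on the fly.  Raises
    on NaN loss with a stage/epoch diagnostic.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=nn.DTYPE)
    y = np.asarray(y)
    n = len(y)
    opt = nn.Adam()
    trace = []
    params = model.params()
    for si, stage in enumerate(protocol.stages):
        model.set_dropout(stage.dropout)
        for epoch in range(stage.epochs):
            opt.lr = stage.lr_at(epoch / max(stage.epochs - 1, 1))
            order = rng.permutation(n)
            for i in range(0, n, protocol.batch_size):
                idx = order[i:i + protocol.batch_size]
                xb = X[idx]
                if augment_fn is not None:
                    xb = augment_fn(xb, rng)
                logits = model.forward(xb, train=True, rng=rng)
                loss, dz = model.loss_and_grad(logits, y[idx], weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf loss at stage {si + 1}, epoch {epoch + 1}")
                model.backward(dz)
                opt.step(params)
                trace.append(loss)
            if verbose:
                print(f"stage {si + 1} epoch {epoch + 1}: "
                      f"loss {np.mean(trace[-max(n // protocol.batch_size, 1):]):.4f}")
    return trace


# ---------------------------------------------------------------------------
# cross-validation schemes


def split_leave_one_subject(individuals: np.ndarray):
    """One fold per individual; the test fold is exactly that individual's
    calls, so individual signatures cannot leak into training."""
    individuals = np.asarray(individuals)
    folds = []
    for ind in np.unique(individuals):
        test = np.flatnonzero(individuals == ind)
        trainv = np.flatnonzero(individuals != ind)
        folds.append((trainv, test))
    return folds


def split_random_folds(n: int, k: int = 10, seed: int = 0):
    """k disjoint test sets covering all samples (permutation draw)."""
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = []
    for part in np.array_split(perm, k):
        test = np.sort(part)
        trainv = np.sort(np.setdiff1d(perm, part))
        folds.append((trainv, test))
    return folds


def shuffle_labels(y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random permutation of the labels (preserves the label multiset);
    the control that must drive every classifier to chance."""
    rng = np.random.default_rng(seed)
    return np.asarray(y)[rng.permutation(len(y))]


# ---------------------------------------------------------------------------
# baselines


class RidgeClassifier:
    """Regularized linear regression on {0,1} targets, decision at 0.5.

    Solves the normal equations w = (X'X + lam I)^-1 X'y directly when the
    feature dimension allows it, and the mathematically identical dual form
    w = X'(XX' + lam I)^-1 y when d > n.  Training classes are balanced by
    downsampling the larger class.
    """

    def __init__(self, lam: float = 1.0, balance: bool = True, seed: int = 0):
        self.lam = lam
        self.balance = balance
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.balance:
            X, y = downsample_balance(X, y, np.random.default_rng(self.seed))
        n, d = X.shape
        if self.lam == 0 and d > n:
            raise np.linalg.LinAlgError(
                "singular system: d > n requires lam > 0")
        if d <= n:
            A = X.T @ X + self.lam * np.eye(d)
            self.w_ = np.linalg.solve(A, X.T @ y)
        else:
            G = X @ X.T + self.lam * np.eye(n)
            self.w_ = X.T @ np.linalg.solve(G, y)
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=np.float64) @ self.w_

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


def svm_classify(X, y, kernel: str = "quadratic", C: float = 1.0,
                 balance: bool = True, seed: int = 0):
    """Soft-margin SVM baseline; quadratic kernel for image inputs, linear
    for feature inputs.  Returns the fitted classifier."""
    from sklearn.svm import SVC

    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes")
    X = np.asarray(X, dtype=np.float64)
    if balance:
        X, y = downsample_balance(X, y, np.random.default_rng(seed))
    if kernel == "quadratic":
        clf = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=C)
    elif kernel == "linear":
        clf = SVC(kernel="linear", C=C)
    else:
        raise ValueError(kernel)
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    percent_correct: float
    per_class: dict
    n_test: int
    scheme: str = ""
    seed: int | None = None

    def __post_init__(self):
        assert 0.0 <= self.percent_correct <= 100.0


def evaluate(model, X, y, scheme: str = "", seed=None) -> EvalResult:
    """Percent correct overall and per class for any predictor with a
    ``predict`` method."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(X))
    correct = pred == y
    per_class = {}
    for c in np.unique(y):
        m = y == c
        per_class[int(c)] = {"percent": float(100.0 * correct[m].mean()),
                             "n": int(m.sum())}
    assert sum(v["n"] for v in per_class.values()) == len(y)
    return EvalResult(percent_correct=float(100.0 * correct.mean()),
                      per_class=per_class, n_test=len(y), scheme=scheme,
                      seed=seed)


def percent_correct_from_counts(n_correct: int, n_total: int) -> float:
    if n_total <= 0:
        raise ValueError("empty test set")
    return 100.0 * n_correct / n_total


def images_to_input(images: np.ndarray) -> np.ndarray:
    """uint8 call images -> float32 [0,1] with a trailing channel axis."""
    x = np.asarray(images, dtype=nn.DTYPE) / 255.0
    return x[..., None]
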