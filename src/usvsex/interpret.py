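"""Interpretation of trained call classifiers and of call embeddings.

Two families of analyses:

* network structure — per-layer activation sparsity, within- vs across-
  class correlation of activation patterns, and deconvolution (transposed-
  weight back-projection) of conv-layer activations to input space;
* stimulus space — PCA and t-SNE embeddings of call images or feature
  vectors, leave-one-out nearest-neighbour decoding of class from the
  embedding, and per-class kernel density difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# activations


def collect_activations(model: nn.Network, X, kinds=(nn.ReLU,),
                        batch_size: int = 128) -> list[np.ndarray]:
    """Post-ReLU activation tensors per layer (evaluation mode)."""
    X = np.asarray(X, dtype=nn.DTYPE)
    outs = None
    for i in range(0, len(X), batch_size):
        x = X[i:i + batch_size]
        acts = []
        for layer in model.layers:
            x = layer.forward(x, train=False)
            if isinstance(layer, kinds):
                acts.append(x.reshape(x.shape[0], -1).copy())
        if outs is None:
            outs = [[a] for a in acts]
        else:
            for store, a in zip(outs, acts):
                store.append(a)
    return [np.concatenate(store, axis=0) for store in outs]


def sparsity(activation: np.ndarray) -> float:
    """1 - (#active units / #total units); a unit is active when its
    post-ReLU activation is strictly positive.  Invariant to positive
    rescaling of the activations."""
    a = np.asarray(activation)
    if a.size == 0:
        raise ValueError("empty activation tensor")
    return float(1.0 - np.count_nonzero(a > 0) / a.size)


def activation_correlations(act_a: np.ndarray, act_b: np.ndarray):
    """Mean pairwise Pearson correlation of flattened activation vectors
    within class A, within class B, and across classes.

    Pairs involving a constant (zero-variance) vector are excluded.
    """
    a = np.asarray(act_a, dtype=np.float64).reshape(len(act_a), -1)
    b = np.asarray(act_b, dtype=np.float64).reshape(len(act_b), -1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per class")

    def _norm(x):
        xc = x - x.mean(axis=1, keepdims=True)
        sd = np.linalg.norm(xc, axis=1)
        ok = sd > 0
        xc[ok] /= sd[ok, None]
        return xc, ok

    an, aok = _norm(a)
    bn, bok = _norm(b)

    def _within(xn, ok):
        xn = xn[ok]
        if len(xn) < 2:
            return float("nan")
        c = xn @ xn.T
        iu = np.triu_indices(len(xn), k=1)
        return float(c[iu].mean())

    across = float((an[aok] @ bn[bok].T).mean()) \
        if aok.any() and bok.any() else float("nan")
    return _within(an, aok), _within(bn, bok), across


# ---------------------------------------------------------------------------
# deconvolution


@dataclass
class DeconvMap:
    values: np.ndarray  # input-shaped reconstruction
    layer_index: int
    channel: int | None


def conv_stack(model: nn.Network) -> list:
    """The leading Conv2D layers (with their ReLUs) of a network."""
    stack = []
    for layer in model.layers:
        if isinstance(layer, (nn.Conv2D, nn.BatchNorm, nn.ReLU)):
            stack.append(layer)
        else:
            break
    return stack


def deconvolve(model: nn.Network, x: np.ndarray, layer: int,
               channel: int | None = None, guided: bool = False
               ) -> DeconvMap:
    """Back-project a conv layer's response to input space.

    ``layer`` counts Conv2D layers (0-based).  The forward pass is run up
    to (and including) that layer's ReLU; the feature map (optionally
    restricted to one channel) is then mapped back through the transposed
    weights of all preceding convolutions, honoring strides and padding.
    With ``guided`` the back-projection is additionally masked by each
    ReLU's forward activation pattern (the "guided" deconvnet variant).
    Fully connected layers are outside the conv stack and are not part of
    the reconstruction.
    """
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.ndim == 3:
        x = x[None]
    convs = []
    shapes = []
    masks = []
    h = x
    count = -1
    for lyr in model.layers:
        if isinstance(lyr, nn.Conv2D):
            count += 1
            shapes.append(h.shape)
            convs.append(lyr)
            h = lyr.forward(h, train=False)
        elif isinstance(lyr, (nn.BatchNorm, nn.ReLU)):
            h = lyr.forward(h, train=False)
            if isinstance(lyr, nn.ReLU):
                masks.append(h > 0)
                if count == layer:
                    break
        else:
            break
    if count < layer:
        raise ValueError(f"network has only {count + 1} conv layers")

    d = h.copy()
    if channel is not None:
        keep = np.zeros_like(d)
        keep[..., channel] = d[..., channel]
        d = keep
    for i in range(layer, -1, -1):
        if guided:
            d = d * masks[i]
        d = convs[i].input_grad(d, shapes[i])
    return DeconvMap(values=np.asarray(d[0, ..., 0], dtype=np.float64),
                     layer_index=layer, channel=channel)


def representation_correlation(deconv_map: np.ndarray,
                               original: np.ndarray) -> float:
    """Pearson correlation over pixels; NaN for constant images."""
    a = np.asarray(deconv_map, dtype=np.float64).ravel()
    b = np.asarray(original, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# embeddings


@dataclass
class Embedding:
    coords: np.ndarray
    method: str
    params: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


def pca_embed(X: np.ndarray, out_dim: int) -> Embedding:
    """Projection onto the top principal components."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=np.float64)
    if out_dim > min(X.shape):
        raise ValueError("out_dim exceeds the rank bound")
    p = PCA(n_components=out_dim, svd_solver="full")
    coords = p.fit_transform(X)
    return Embedding(coords=coords, method="pca",
                     params={"out_dim": out_dim,
                             "explained_variance_ratio":
                             p.explained_variance_ratio_.tolist()})


def tsne_embed(X: np.ndarray, dim: int = 3, perplexity: float = 30.0,
               pca_pre_dim: int | None = None, seed: int = 0,
               jitter: float = 1e-9) -> Embedding:
    """t-SNE embedding with optional PCA pre-reduction.

    Mirrors the two standard settings (pre-reduction to 9 for feature
    vectors, 100 for spectrogram images).  Deterministic under a fixed
    seed; duplicate rows are disambiguated by a tiny seeded jitter.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=np.float64)
    if len(X) <= 3 * perplexity:
        raise ValueError("need n > 3 * perplexity samples")
    if pca_pre_dim is not None and pca_pre_dim < X.shape[1]:
        X = pca_embed(X, min(pca_pre_dim, min(X.shape))).coords
    if jitter:
        rng = np.random.default_rng(seed)
        X = X + jitter * rng.standard_normal(X.shape)
    ts = TSNE(n_components=dim, perplexity=perplexity, random_state=seed,
              init="pca", method="exact" if dim > 2 else "barnes_hut")
    coords = ts.fit_transform(X)
    return Embedding(coords=coords, method="tsne",
                     params={"dim": dim, "perplexity": perplexity,
                             "pca_pre_dim": pca_pre_dim, "seed": seed})


def knn_loo_decode(coords: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out 1-nearest-neighbour decoding accuracy (percent).

    Each point is classified by its nearest other point (Euclidean);
    distance ties resolve to the lowest index.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two points")
    sq = np.sum(coords ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)  # argmin returns the lowest tied index
    return float(100.0 * np.mean(labels[nearest] == labels))


def density_difference(coords: np.ndarray, labels: np.ndarray,
                       bandwidth: float | str = "scott",
                       grid_size: int = 60, margin: float = 0.05):
    """Signed difference of per-class kernel densities on a common grid.

    Uses the first two embedding dimensions; each class's Gaussian KDE is
    normalized to unit mass before subtraction, so the signed field
    integrates to ~0.  Returns (xx, yy, diff) grid arrays.
    """
    from scipy.stats import gaussian_kde

    coords = np.asarray(coords, dtype=np.float64)[:, :2]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    lo, hi = lo - margin * span, hi + margin * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.vstack([xx.ravel(), yy.ravel()])
    fields = []
    for c in classes:
        kde = gaussian_kde(coords[labels == c].T, bw_method=bandwidth)
        f = kde(pts).reshape(grid_size, grid_size)
        cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
        f /= max(f.sum() * cell, 1e-300)  # renormalize on the finite grid
        fields.append(f)
    return xx, yy, fields[0] - fields[1]
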