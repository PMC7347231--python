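"""Structure of a trained call classifier: per-layer activation sparsity,
within- vs across-class correlation of activation patterns, and the
correlation of deconvolved (back-projected) stimuli with the originals,
plus a 3-D t-SNE embedding of the call images with leave-one-out 1-NN
class decoding and a per-class density-difference map.

Self-contained (trains a small CNN on a 1000-call surrogate); writes
results/interpretation.csv and results/embedding.csv.
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from usvsex import classify as cl
from usvsex import interpret as it
from usvsex import synth as sy

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    t0 = time.time()
    ds = sy.make_labeled_dataset(sy.default_profiles(nonlinear=True),
                                 n_per_individual=150,
                                 n_individuals_per_class=5,
                                 seed=SEED, snr_db=30.0)
    y = ds.y
    X = cl.images_to_input(ds.images)
    n = len(y)
    tr = np.random.default_rng(SEED).permutation(n)[:1000]
    te = np.setdiff1d(np.arange(n), tr)
    model = cl.build_network(cl.ConvNetSpec(units=32, fc_units=120),
                             seed=SEED)
    proto = cl.TrainProtocol(cl.protocol_spectrogram().scaled(1 / 4)
                             .stages[:1])
    cl.train(model, X[tr], y[tr], proto, seed=SEED,
             weights=cl.class_weights(y[tr]))
    acc = cl.evaluate(model, X[te], y[te]).percent_correct
    print(f"surrogate classifier test accuracy: {acc:.1f} %")

    sub = np.random.default_rng(SEED + 1).permutation(te)[:200]
    acts = it.collect_activations(model, X[sub])
    tags = [f"CV{i + 1}" for i in range(6)] + [f"FC{i + 1}"
                                               for i in range(3)]
    rows = []
    for tag, act in zip(tags, acts):
        wa, wb, across = it.activation_correlations(act[y[sub] == 0],
                                                    act[y[sub] == 1])
        row = {"layer": tag, "sparsity": it.sparsity(act),
               "within_corr": 0.5 * (wa + wb), "across_corr": across}
        rows.append(row)
    # deconvolved-stimulus correlation per conv layer (first 20 stimuli)
    for li in range(6):
        vals = []
        for i in sub[:20]:
            m = it.deconvolve(model, X[i], layer=li)
            c = it.representation_correlation(m.values, X[i][..., 0])
            if np.isfinite(c):
                vals.append(c)
        rows[li]["deconv_corr"] = float(np.mean(vals))
    rep = pd.DataFrame(rows)
    rep.to_csv(ROOT / "interpretation.csv", index=False,
               float_format="%.4f")
    print(rep.round(3).to_string(index=False))

    flat = ds.images.reshape(n, -1) / 255.0
    emb = it.tsne_embed(flat, dim=3, perplexity=30, pca_pre_dim=100,
                        seed=SEED)
    knn = it.knn_loo_decode(emb.coords, y)
    pd.DataFrame({"x": emb.coords[:, 0], "y": emb.coords[:, 1],
                  "z": emb.coords[:, 2], "label": y}).to_csv(
        ROOT / "embedding.csv", index=False, float_format="%.4f")
    _, _, diff = it.density_difference(emb.coords, y)
    print(f"t-SNE 1-NN decoding: {knn:.1f} % "
          f"(density-difference range {diff.min():.2g}..{diff.max():.2g})")
    print(f"done in {time.time() - t0:.0f} s")


if __name__ == "__main__":
    main()
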