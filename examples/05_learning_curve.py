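"""AUC versus labeled-training-set size for several observers.

Reproduces the learning-curve protocol at a reduced 16x16 scale: a fixed
shared test set, fresh training subsets per (observer, size, repeat), and
the known-covariance Hotelling observer as the constant reference line.
"""

import numpy as np

from taskmo import (
    BackgroundSpec,
    CDAEConfig,
    CNNConfig,
    PixelGrid,
    SignalSpecSKE,
    build_detection_dataset,
    learning_curve_experiment,
    mann_whitney_auc,
    ske_profile,
    train_val_test_split,
)
from taskmo.observers import make_cdae_svm, make_cnn, make_known_cov_ho, make_slnn

grid = PixelGrid(16, 16, 0.7)
bg = BackgroundSpec(noise_sd=42.0)
sig = SignalSpecSKE(amplitude=-60.0, radius=2.5)

pool = build_detection_dataset(grid, bg, sig, n_pairs=1500, seed=1, paired=False)
aux = build_detection_dataset(grid, bg, sig, n_pairs=400, seed=2, paired=False)
val, test, _ = train_val_test_split(aux, (400, 400, 0), seed=0)
y = np.asarray(test.labels)

ref = make_known_cov_ho(grid, bg, ske_profile(grid, sig) / 1500.0)()
t = ref.score(test.images)
ref_auc = mann_whitney_auc(t[y == 0], t[y == 1])

observers = {
    "cnn": make_cnn(CNNConfig(depth=2, filters=8), epochs=20),
    "slnn": make_slnn(epochs=20),
    "cdae-svm": make_cdae_svm(
        CDAEConfig(latent_units=16, filters=8, corruption_rate=0.05),
        C_grid=(1.0, 10.0), sigma_grid=(1.0, 2.0, 5.0), max_epochs=15,
        pretext_images=pool.images,  # encoder pretrains on the unlabeled pool
    ),
}
curve = learning_curve_experiment(
    observers, pool, test, val, sizes=(100, 400, 1600), repeats=2, seed=0,
    reference_auc=ref_auc,
)
print(f"known-covariance HO reference AUC: {ref_auc:.3f}")
print(curve.table.groupby(["observer", "size"])["auc"]
      .agg(["mean", "std"]).round(3))
print("each row: mean/sd of test AUC over repeats at that labeled set size; "
      "the HO line is constant by construction")
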