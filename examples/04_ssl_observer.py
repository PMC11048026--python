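"""The self-supervised observer: CDAE features + RBF-SVM classifier.

The denoising autoencoder pretrains on an unlabeled image pool (no labels
consumed); the RBF-SVM stage then needs only a modest labeled set.  A PCA
feature extractor with the same latent dimension serves as the linear
baseline.  Reduced 16x16 task for speed.
"""

import numpy as np

from taskmo import (
    BackgroundSpec,
    CDAEConfig,
    PixelGrid,
    SignalSpecSKE,
    build_detection_dataset,
    mann_whitney_auc,
    train_val_test_split,
)
from taskmo.selfsup import fit_ssl_observer

grid = PixelGrid(16, 16, 0.7)
bg = BackgroundSpec(noise_sd=42.0)
sig = SignalSpecSKE(amplitude=-60.0, radius=2.5)

pool = build_detection_dataset(grid, bg, sig, n_pairs=2000, seed=10, paired=False)  # unlabeled
labeled = build_detection_dataset(grid, bg, sig, n_pairs=500, seed=11, paired=False)
train, val, test = train_val_test_split(labeled, (600, 200, 200), seed=0)
y = np.asarray(test.labels)

cfg = CDAEConfig(latent_units=16, filters=8, corruption_rate=0.05)
for extractor in ("cdae", "pca"):
    obs = fit_ssl_observer(
        train, val, config=cfg, extractor=extractor,
        pretext_images=pool.images,
        C_grid=(1.0, 10.0, 100.0), sigma_grid=(1.0, 2.0, 5.0),
        max_epochs=15, patience=4, seed=0,
    )
    t = obs.score(test.images)
    auc = mann_whitney_auc(t[y == 0], t[y == 1])
    print(f"{extractor.upper():4s}+SVM: test AUC = {auc:.3f}  "
          f"(selected C = {obs.svm_config.C:g}, sigma = {obs.svm_config.sigma:g})")
print("the pretext stage never reads labels; only the SVM stage is supervised")
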