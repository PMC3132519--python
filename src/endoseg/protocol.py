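"""The standard phantom evaluation protocol.

Bundles the study conditions used for method comparison: a suite of
128 x 128 monolayer phantoms at the standard difficulty (generator
defaults), an SVM trained per phantom on a 62 x 62 sample patch at the
published operating point (RBF, C = 1, gamma = 0.14), and the classical
methods at their automatic operating points (Otsu and Kittler thresholds;
Canny at sigma = 1 with strong-edge hysteresis quantiles 0.7 / 0.9).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import PhantomConfig, generate_monolayer_phantom, sample_training_patch
from .classify import PixelBoundarySVM
from .baselines import otsu_threshold, kittler_threshold, canny_edges
from .evaluate import mask_accuracy

#: Canny operating point used in comparison reports (sigma, low, high quantiles).
CANNY_OPERATING_POINT = (1.0, 0.7, 0.9)

#: Phantom size and mosaic density of the comparison suite; cells are the
#: same ~32 px across as the 256 x 256 / 50-cell generator default.
SUITE_SIZE = 128
SUITE_N_CELLS = 16


def suite_config(seed: int, **overrides) -> PhantomConfig:
    """Standard-difficulty phantom config for one suite member."""
    params = dict(width=SUITE_SIZE, height=SUITE_SIZE, n_cells=SUITE_N_CELLS, seed=seed)
    params.update(overrides)
    return PhantomConfig(**params)


def run_standard_comparison(
    base_seed: int = 0,
    n_seeds: int = 10,
    train_patch: int = 62,
) -> pd.DataFrame:
    """Accuracy of SVM-RBF, Otsu, Kittler and Canny over the phantom suite.

    One phantom per seed ``base_seed .. base_seed + n_seeds - 1``; the SVM is
    trained on a 62 x 62 patch of each phantom and applied to the whole
    image, mirroring the train-on-a-sample-region protocol.  Returns a
    DataFrame (rows: methods; columns: one per phantom plus ``mean``).
    """
    sigma, low, high = CANNY_OPERATING_POINT
    cols = [f"phantom_{s}" for s in range(base_seed, base_seed + n_seeds)]
    table = pd.DataFrame(
        index=["svm_rbf", "otsu", "kittler", "canny"], columns=cols, dtype=float
    )
    table.index.name = "method"
    for i, seed in enumerate(range(base_seed, base_seed + n_seeds)):
        image, mask = generate_monolayer_phantom(suite_config(seed))
        patch_img, patch_mask = sample_training_patch(
            image, mask, train_patch, seed=seed + 1
        )
        model = PixelBoundarySVM().fit_image(patch_img, patch_mask)
        table.iloc[0, i] = mask_accuracy(model.predict_image(image), mask)
        table.iloc[1, i] = mask_accuracy(otsu_threshold(image).mask, mask)
        table.iloc[2, i] = mask_accuracy(kittler_threshold(image).mask, mask)
        table.iloc[3, i] = mask_accuracy(canny_edges(image, sigma, low, high), mask)
    table["mean"] = table[cols].mean(axis=1)
    return table
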