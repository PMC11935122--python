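"""Fit the prediction-to-ground-truth rescaling on training pairs.

Denoising networks output normalized intensities; quality metrics need
them back on the photon-count scale of the ground truth.  The affine map
is fitted by least squares over pooled training pixels only, then applied
to a held-out test prediction.
"""

import dataclasses

from stedqc.phantom import (GROUND_TRUTH_ACQUISITION, PhantomParams,
                            generate_phantom, simulate_acquisition,
                            simulate_prediction)
from stedqc.rescale import apply_rescale, fit_rescale

train_preds, train_truths = [], []
for seed in range(3):
    ph = generate_phantom(PhantomParams(rng_seed=seed))
    train_truths.append(simulate_acquisition(
        ph, dataclasses.replace(GROUND_TRUTH_ACQUISITION, rng_seed=seed + 10)))
    train_preds.append(simulate_prediction(ph, rng_seed=seed + 10))

params = fit_rescale(train_preds, train_truths)
print(f"fitted scale  = {params.scale:.2f}")
print(f"fitted offset = {params.offset:.2f}")
print(f"clip band     = [{params.clip_low:.2f}, {params.clip_high:.2f}] "
      f"(1st/99th percentile of pooled ground truth)")

test_ph = generate_phantom(PhantomParams(rng_seed=99))
test_pred = simulate_prediction(test_ph, rng_seed=99)
rescaled = apply_rescale(test_pred, params)
print(f"test prediction range before: [{test_pred.min():.2f}, {test_pred.max():.2f}]")
print(f"test prediction range after:  [{rescaled.min():.2f}, {rescaled.max():.2f}]")
# After rescaling the prediction spans photon-count units comparable to a
# high-dose acquisition, so MAE/PSNR and resolution metrics are meaningful.
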