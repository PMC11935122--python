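"""Quantify ER structure frame by frame over a remodelling movie.

Each frame is background-subtracted, segmented into tubes and sheets by
local width, skeletonized into a junction graph, and summarized: class
fractions, junction-order histogram, instance counts (tubes, sheets and
enclosed gaps), foreground fraction and adjacent-frame SSIM.
"""

from stedqc.phantom import (AcquisitionParams, DynamicsParams, PhantomParams,
                            simulate_timeseries)
from stedqc.structure import (rolling_ball_subtract, segment_er,
                              summaries_to_frame, summarize_timeseries)

params = PhantomParams(rng_seed=6)
dyn = DynamicsParams(n_frames=6, rearrangement_rate=0.1, rng_seed=7)
movie, truth_labels = simulate_timeseries(
    params, dyn, AcquisitionParams(dose_per_unit_density=100, rng_seed=8))

labels = [segment_er(rolling_ball_subtract(f.astype(float), radius_px=15),
                     pixel_size_nm=20.0) for f in movie]
summaries = summarize_timeseries(movie.astype(float), labels)
df = summaries_to_frame(summaries)
print(df.round(3).to_string(index=False))

hist: dict[int, int] = {}
for s in summaries:
    for order, n in s.junction_order_counts.items():
        hist[order] = hist.get(order, 0) + n
print(f"\ntime-averaged junction orders: {dict(sorted(hist.items()))}")
# Tube/sheet fractions fluctuate around their structural balance; the
# junction histogram is dominated by order 3, and adjacent-frame SSIM
# tracks how fast the network remodels between frames.
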