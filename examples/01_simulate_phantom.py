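"""Generate an ER-like phantom and image it at two illumination doses.

The phantom is a network of 100 nm tubules (mostly 3-way junctions) with a
few sheets, on a 256 x 256 grid of 20 nm pixels.  It is imaged once at the
high-dose regime used for ground-truth acquisition and once at the ~70x
lower dose used for gentle long-term time series.
"""

from collections import Counter

from stedqc.phantom import (GROUND_TRUTH_ACQUISITION, LOW_INTENSITY_ACQUISITION,
                            PhantomParams, generate_phantom, simulate_pair)

phantom = generate_phantom(PhantomParams(rng_seed=1))
degrees = Counter(d for *_, d in phantom.skeleton_graph_truth if d >= 3)

high, low = simulate_pair(phantom, GROUND_TRUTH_ACQUISITION,
                          LOW_INTENSITY_ACQUISITION)

print(f"foreground pixels: {int((phantom.density_map > 0).sum())}")
print(f"junction orders (order: count): {dict(sorted(degrees.items()))}")
print(f"mean photon count, high dose: {high.mean():.2f}")
print(f"mean photon count, low dose:  {low.mean():.2f}")
print(f"empirical dose ratio: {high.mean() / low.mean():.1f} "
      f"(photon budget ratio {GROUND_TRUTH_ACQUISITION.total_dose / LOW_INTENSITY_ACQUISITION.total_dose:.3f})")
# The ratio of mean counts recovers the ~70x illumination-dose gap between
# the two acquisition regimes; junctions are dominated by order 3, as in
# healthy ER networks.
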