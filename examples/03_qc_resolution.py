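"""Full-reference QC metrics and a local resolution map for one image pair.

Two independent high-dose acquisitions of the same phantom (100 nm PSF)
are compared by Fourier ring correlation: the global FRC resolution, then
a rolling (blockwise) FRC map whose mean/min summarize local resolution.
"""

import dataclasses

from stedqc.metrics import frc_curve, frc_resolution, qc_report, rfrc_map
from stedqc.phantom import (AcquisitionParams, PhantomParams,
                            generate_phantom, simulate_acquisition)

phantom = generate_phantom(PhantomParams(rng_seed=11))
acq = AcquisitionParams(dose_per_unit_density=300, psf_fwhm_nm=100.0)
a = simulate_acquisition(phantom, dataclasses.replace(acq, rng_seed=1))
b = simulate_acquisition(phantom, dataclasses.replace(acq, rng_seed=2))

res, at_nyquist = frc_resolution(frc_curve(a, b, pixel_size_nm=20.0))
print(f"global FRC resolution: {res:.1f} nm (Nyquist-limited: {at_nyquist})")

m = rfrc_map(a, b, pixel_size_nm=20.0, block_size_px=64, stride_px=16,
             background_intensity=20.0)
print(f"rFRC map: {int(m.valid.sum())} valid blocks, "
      f"mean {m.mean_resolution_nm:.1f} nm, min {m.min_resolution_nm:.1f} nm")

report = qc_report(a, b, pixel_size_nm=20.0, with_resolution=False)
print(f"SSIM {report.ssim:.3f}  MAE {report.mae:.2f}  "
      f"PSNR {report.psnr:.1f} dB  Pearson {report.pearson:.3f}")
# With a 100 nm PSF the estimated resolution lands near 100 nm; blocks of
# pure background (mean intensity <= 20) are excluded from the map.
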