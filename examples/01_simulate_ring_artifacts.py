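"""Simulate detector-bin failures and look at the ring artifact they cause.

Builds study case 1 at desk scale (64² chest-like phantom, five isolated
bad detector bins with angle-constant offsets), reconstructs the clean and
corrupted sinograms with plain FBP, and reports how much the rings degrade
the image.
"""

import numpy as np

from ringsparse import fbp_reconstruct, make_study_case, rrmse, ssim

case = make_study_case(1, n=64, seed=0)
bad = np.where(np.any(case.true_lambda != 0, axis=1))[0]
print(f"bad detector bins: {[int(b) for b in bad]}")
print(f"injected offsets:  {np.round(case.true_lambda[bad, 0], 3)}  (log-sinogram units)")

fbp_clean = fbp_reconstruct(case.clean, case.geometry)
fbp_corr = fbp_reconstruct(case.corrupted, case.geometry)
print(f"FBP of clean sinogram:     RRMSE = {rrmse(fbp_clean, case.phantom):.4f}")
print(f"FBP of corrupted sinogram: RRMSE = {rrmse(fbp_corr, case.phantom):.4f}, "
      f"SSIM = {ssim(fbp_corr, case.phantom):.4f}")
print("The RRMSE increase over the clean FBP is the ring artifact: each bad")
print("bin back-projects to a circle at radius |s_bin| around the rotation axis.")
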