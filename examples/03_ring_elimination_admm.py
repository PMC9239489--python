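"""Eliminate rings during reconstruction with the constrained ℓ1 solver.

Solves  min S(λ) s.t. Ax − b = λ  by ADMM on study case 1, with λ forced
constant over the view angle (the right model when rings come purely from
detector-bin sensitivity).  The recovered λ localises the bad bins and the
reconstruction drops well below the corrupted-FBP error.
"""

import numpy as np

from ringsparse import (
    fbp_reconstruct,
    make_study_case,
    rrmse,
    solve_ring,
    study_solver_config,
)

case = make_study_case(1, n=64, seed=0)
cfg = study_solver_config(case.geometry, "l1", constrained=True, outer_iters=300)
res = solve_ring(case.corrupted, case.geometry, cfg, reference=case.phantom)

bad = np.sort(np.where(np.any(case.true_lambda != 0, axis=1))[0])
top = np.sort(np.argsort(np.abs(res.imperfect[:, 0]))[-len(bad):])
print(f"injected bad bins:  {[int(b) for b in bad]}")
print(f"largest |lambda_r|: {[int(b) for b in top]}")
print(f"corrupted FBP RRMSE: {rrmse(fbp_reconstruct(case.corrupted, case.geometry), case.phantom):.4f}")
print(f"cstr-l1-ring RRMSE:  {res.history[-1].rrmse:.4f}  "
      f"(SSIM {res.history[-1].ssim:.4f})")
print(f"final relative primal residual ||lambda - Ax + b||/||b|| = "
      f"{res.residuals[-1] / np.linalg.norm(case.corrupted.values):.2e}")
print("The five largest per-bin error estimates sit exactly on the injected")
print("bins, so the sinogram is repaired in-reconstruction, not filtered.")
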