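"""Why an ℓ2 data fit cannot remove rings, and ℓ0 + smoothing can.

Quadratic penalties spread the bad-bin error over the whole image instead
of isolating it; a sparsity penalty concentrates it into λ.  Compared via
the mean absolute reconstruction error on the circles where the rings lie.
"""

import numpy as np

from ringsparse import (
    make_study_case,
    rrmse,
    solve_l2_baseline,
    solve_ring,
    study_solver_config,
)
from ringsparse.metrics import bin_radius, radial_error_profile

case = make_study_case(1, n=64, seed=0)
geom = case.geometry
bad = np.where(np.any(case.true_lambda != 0, axis=1))[0]
radii = [int(round(bin_radius(geom, b))) for b in bad]


def ring_error(image):
    prof = radial_error_profile(image, case.phantom)
    return max(prof[r] for r in radii if 0 <= r < len(prof))


l2 = solve_l2_baseline(case.corrupted, geom,
                       study_solver_config(geom, "l2", outer_iters=300),
                       reference=case.phantom)
l0s = solve_ring(case.corrupted, geom,
                 study_solver_config(geom, "l0", smooth=True, outer_iters=300,
                                     sinogram=case.corrupted),
                 reference=case.phantom)

print(f"l2 baseline:   RRMSE {rrmse(l2.image, case.phantom):.4f}, "
      f"ring-radius error {ring_error(l2.image):.4f}")
print(f"l0-smth-ring:  RRMSE {rrmse(l0s.image, case.phantom):.4f}, "
      f"ring-radius error {ring_error(l0s.image):.4f}")
print(f"ring suppression factor: {ring_error(l2.image) / ring_error(l0s.image):.0f}x")
print("The l2 fit keeps the rings (error concentrated at the bad-bin radii);")
print("the sparse model plus edge-preserving smoothing removes them.")
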