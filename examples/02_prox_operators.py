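"""The four sparsity proxes that distinguish the solver variants.

Each ADMM iteration updates the imperfect component elementwise by
prox_{μS}(d) with μ = 1/ρ; the choice of S is the only difference between
the ℓ1-, ℓ0-, Huber-ℓ1- and Huber-ℓ0-ring algorithms.
"""

import numpy as np

from ringsparse import NormSpec, prox

y = np.array([-3.0, -0.5, -0.05, 0.0, 0.05, 0.5, 3.0])
mu = 0.5
print(f"input d:        {y}")
print(f"l1  (soft thr.) {np.round(prox(y, mu, NormSpec('l1')), 3)}")
print(f"l0  (hard thr.) {np.round(prox(y, mu, NormSpec('l0')), 3)}")
print(f"hl1 (delta=0.2) {np.round(prox(y, mu, NormSpec('hl1', 0.2)), 3)}")
print(f"hl0 (delta=0.2) {np.round(prox(y, mu, NormSpec('hl0', 0.2)), 3)}")
print("Soft thresholding shrinks everything by mu; hard thresholding keeps a")
print("value only when y^2/2 > mu; the Huber variants treat small values")
print("quadratically (shrink towards zero) and large ones like l1/l0 —")
print("that is what makes them robust when noise and bin errors coexist.")
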