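"""Recommended solver settings for the simulation study protocol.

The prox of each sparsity penalty imposes its own threshold scale on the
sinogram-domain error it can capture, and those scales respond differently
to the augmented-Lagrangian weight ρ:

* ℓ1 — soft threshold μ = 1/ρ (linear in μ);
* ℓ0 — hard threshold √(2μ) (square-root in μ);
* Huber-ℓ1 / Huber-ℓ0 — band and shrinkage set by δ, nearly independent
  of μ.

A single ρ therefore cannot place all four thresholds sensibly for a given
data scale; the protocol fixes, per penalty, the ρ (and δ) that put the
induced threshold just below the smallest plausible bad-bin offset (2% of
the sinogram maximum ≈ 0.12 for the study cases, whose line integrals
reach ≈ 6).  The GD step size is always taken from the power-iteration
Lipschitz estimate, near the stability limit.

The ℓ0-family solvers are warm-started from the FBP of the measured
sinogram: from a zero image the hard threshold sees the whole sinogram as
"error", captures it into λ, and stalls (the identity branch of the prox
satisfies the constraint exactly and zeroes the dual update); starting
near the solution keeps the residual below the threshold except at the
truly bad bins.
"""

from __future__ import annotations

from typing import Optional

from .geometry import ProjectionGeometry, Sinogram, fbp_reconstruct
from .priors import NormKind, NormSpec, SmoothingSpec
from .solvers import SolverConfig, suggest_alpha

__all__ = ["STUDY_RHO", "STUDY_DELTA", "study_solver_config"]

# augmented-Lagrangian weight per penalty (see module docstring)
STUDY_RHO = {
    NormKind.L1: 12.0,
    NormKind.L0: 130.0,
    NormKind.HUBER_L1: 2.0,
    NormKind.HUBER_L0: 2.0,
    NormKind.L2: 1.0,
}

# Huber transition points, in sinogram (log-attenuation) units
STUDY_DELTA = {
    NormKind.HUBER_L1: 0.088,
    NormKind.HUBER_L0: 0.18,
}

STUDY_BETA_PRIME = 0.005
STUDY_ETA = 0.001

_WARM_START_KINDS = (NormKind.L0, NormKind.HUBER_L0)


def study_solver_config(
    geometry: ProjectionGeometry,
    norm: str | NormKind = "l1",
    smooth: bool = False,
    constrained: bool = False,
    outer_iters: int = 500,
    inner_iters: int = 2,
    sinogram: Optional[Sinogram] = None,
) -> SolverConfig:
    """Build the protocol :class:`SolverConfig` for one algorithm variant.

    Pass the measured ``sinogram`` to enable the FBP warm start for the
    ℓ0-family penalties (required for them to behave; see module
    docstring).
    """
    kind = NormKind(norm)
    rho = STUDY_RHO[kind]
    spec = NormSpec(kind, STUDY_DELTA.get(kind))
    smoothing = (
        SmoothingSpec(beta_prime=STUDY_BETA_PRIME, eta=STUDY_ETA) if smooth else None
    )
    init = None
    if kind in _WARM_START_KINDS and sinogram is not None:
        init = fbp_reconstruct(sinogram, geometry).values
    return SolverConfig(
        norm=spec,
        rho=rho,
        alpha=suggest_alpha(geometry, rho),
        outer_iters=outer_iters,
        inner_iters=inner_iters,
        smoothing=smoothing,
        angular_constrained=constrained,
        init_image=init,
    )
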