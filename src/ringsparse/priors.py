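"""Sparsity-inducing penalties, their proximity operators, and the
edge-preserving Huber-MRF smoothing penalty.

The ring-elimination solvers differ only in which penalty ``S(λ)`` they put
on the imperfect sinogram component λ; everything here is elementwise and
closed-form.  The five penalties:

* ``L1``        — S(λ) = Σ|λᵢ| ; prox = soft thresholding.
* ``L0``        — S(λ) = #{λᵢ ≠ 0} ; prox = hard thresholding
  (keep y iff y²/2 > μ, prefer 0 on the tie).
* ``HUBER_L1``  — elementwise continuous Huber: λ²/2 for |λ| < δ,
  δ|λ| − δ²/2 above; prox shrinks by μδ outside the band |y| ≤ (μ+1)δ and
  scales by 1/(μ+1) inside.
* ``HUBER_L0``  — truncated quadratic min(λ²/2, δ²/2): quadratic near zero
  like the Huber, but flat (ℓ0-like) beyond δ.  Its exact prox scales by
  1/(μ+1) for |y| ≤ δ√(μ+1) and is the identity outside.
* ``L2``        — S(λ) = ½Σλᵢ²; prox = y/(μ+1).  Provided for the
  baseline that cannot separate a sparse error.

All proxes satisfy prox(0) = 0, are odd in y, and (for the convex
penalties) firmly nonexpansive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geometry import Image

__all__ = [
    "NormKind",
    "NormSpec",
    "SmoothingSpec",
    "norm_value",
    "prox",
    "smoothing_value",
    "smoothing_gradient",
]


class NormKind(str, Enum):
    L1 = "l1"
    L0 = "l0"
    HUBER_L1 = "hl1"
    HUBER_L0 = "hl0"
    L2 = "l2"


_HUBER_KINDS = (NormKind.HUBER_L1, NormKind.HUBER_L0)


@dataclass(frozen=True)
class NormSpec:
    """A sparsity penalty choice: the kind and (for Huber kinds) the
    transition point delta at which the quadratic branch hands over."""

    kind: NormKind
    delta: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", NormKind(self.kind))
        if self.kind in _HUBER_KINDS:
            if self.delta is None or self.delta <= 0:
                raise ValueError(f"{self.kind.value} requires delta > 0")


def norm_value(v: np.ndarray, spec: NormSpec) -> float:
    """Evaluate the penalty S(v) (sum of the elementwise penalty)."""
    v = np.asarray(v, dtype=float)
    k = spec.kind
    if k is NormKind.L1:
        return float(np.sum(np.abs(v)))
    if k is NormKind.L0:
        return float(np.count_nonzero(v))
    if k is NormKind.L2:
        return float(0.5 * np.sum(v * v))
    d = spec.delta
    a = np.abs(v)
    if k is NormKind.HUBER_L1:
        return float(np.sum(np.where(a < d, v * v / 2.0, d * a - d * d / 2.0)))
    # HUBER_L0: truncated quadratic
    return float(np.sum(np.minimum(v * v / 2.0, d * d / 2.0)))


def prox(y, mu: float, spec: NormSpec):
    """prox_{μS}(y) = argmin_x μ·s(x) + ½(x − y)², applied elementwise.

    Accepts a scalar or an array; returns the same shape (a float for
    scalar input).
    """
    if mu <= 0:
        raise ValueError("prox requires mu > 0")
    y_arr = np.asarray(y, dtype=float)
    k = spec.kind
    if k is NormKind.L1:
        out = np.sign(y_arr) * np.maximum(np.abs(y_arr) - mu, 0.0)
    elif k is NormKind.L0:
        # keep y iff y²/2 > μ; the tie has two global minimisers, prefer 0
        out = np.where(y_arr * y_arr > 2.0 * mu, y_arr, 0.0)
    elif k is NormKind.L2:
        out = y_arr / (mu + 1.0)
    elif k is NormKind.HUBER_L1:
        d = spec.delta
        band = np.abs(y_arr) <= (mu + 1.0) * d
        out = np.where(band, y_arr / (mu + 1.0), y_arr - np.sign(y_arr) * mu * d)
    else:  # HUBER_L0
        # exact prox of the truncated quadratic: compare the shrunk
        # candidate against the identity; crossover at |y| = δ√(μ+1)
        d = spec.delta
        band = np.abs(y_arr) <= d * np.sqrt(mu + 1.0)
        out = np.where(band, y_arr / (mu + 1.0), y_arr)
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Huber-MRF smoothing penalty
# ---------------------------------------------------------------------------

# 8-neighbour offsets (row, col) with their Euclidean distances
_OFFSETS = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if not (dr == 0 and dc == 0)
]


@dataclass(frozen=True)
class SmoothingSpec:
    """Edge-preserving Markov-random-field smoothing penalty
    H(x) = Σ_j Σ_{j̃ ∈ U_j} w_jj̃ h(x_j − x_j̃) over the 8-neighbourhood,
    with h quadratic below the edge threshold eta and linear above.

    ``beta_prime`` is the strength β′ = αβ used directly in the gradient
    step.  ``weights`` selects the per-neighbour weight convention:
    ``inverse_distance`` (1 axial, 1/√2 diagonal — the standard MRF choice)
    or ``distance`` (the literal opposite).
    """

    beta_prime: float = 0.0
    eta: float = 1e-3
    weights: str = "inverse_distance"

    def __post_init__(self) -> None:
        if self.beta_prime < 0:
            raise ValueError("beta_prime must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.weights not in ("inverse_distance", "distance"):
            raise ValueError("weights must be 'inverse_distance' or 'distance'")

    def weight(self, dr: int, dc: int) -> float:
        dist = float(np.hypot(dr, dc))
        return 1.0 / dist if self.weights == "inverse_distance" else dist


def _pair_slices(n0: int, n1: int, dr: int, dc: int):
    """Slices selecting (pixel j, neighbour j+offset) overlap regions."""
    rj = slice(0, n0 - dr) if dr >= 0 else slice(-dr, n0)
    rn = slice(dr, n0) if dr >= 0 else slice(0, n0 + dr)
    cj = slice(0, n1 - dc) if dc >= 0 else slice(-dc, n1)
    cn = slice(dc, n1) if dc >= 0 else slice(0, n1 + dc)
    return (rj, cj), (rn, cn)


def _values_of(image) -> np.ndarray:
    return image.values if isinstance(image, Image) else np.asarray(image, dtype=float)


def smoothing_value(image, spec: SmoothingSpec) -> float:
    """H(x): the literal double sum, so each unordered neighbour pair is
    counted once from each of its two pixels."""
    x = _values_of(image)
    eta = spec.eta
    total = 0.0
    for dr, dc in _OFFSETS:
        (rj, cj), (rn, cn) = _pair_slices(x.shape[0], x.shape[1], dr, dc)
        d = x[rj, cj] - x[rn, cn]
        a = np.abs(d)
        h = np.where(a < eta, d * d / 2.0, eta * a - eta * eta / 2.0)
        total += spec.weight(dr, dc) * float(h.sum())
    return total


def smoothing_gradient_array(x: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """∇H as an array; factor 2 because each pair appears in both pixels'
    neighbour sets (the gradient is the exact gradient of
    :func:`smoothing_value`)."""
    eta = spec.eta
    g = np.zeros_like(x)
    for dr, dc in _OFFSETS:
        (rj, cj), (rn, cn) = _pair_slices(x.shape[0], x.shape[1], dr, dc)
        d = x[rj, cj] - x[rn, cn]
        g[rj, cj] += spec.weight(dr, dc) * np.clip(d, -eta, eta)
    return 2.0 * g


def smoothing_gradient(image, spec: SmoothingSpec) -> Image:
    """∇H(x) as an Image (see :func:`smoothing_gradient_array`)."""
    return Image(smoothing_gradient_array(_values_of(image), spec))
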