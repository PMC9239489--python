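"""Image-quality metrics: relative RMSE and global SSIM.

RRMSE defaults to the standard reference-normalised form
``‖x − z‖₂ / ‖z‖₂`` so the metric scale is fixed by the ground truth; a
``printed`` variant normalising by Σxᵢ is available for comparison.

SSIM is computed *globally* — one window covering the whole image, with
population (1/N) moment normalisation — rather than the windowed
mean-SSIM, with c₁ = (k₁s)² , c₂ = (k₂s)² and dynamic range s taken from
the reference image by default (optionally pooled over both images, which
makes the index symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Image, ProjectionGeometry

__all__ = ["QualityReport", "rrmse", "ssim", "radial_error_profile", "bin_radius"]


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, Image) else np.asarray(img, dtype=float)


@dataclass(frozen=True)
class QualityReport:
    rrmse: float
    ssim: float
    reference_id: str = "reference"
    test_id: str = "test"


def rrmse(test, reference, variant: str = "reference") -> float:
    """Relative root-mean-square error of ``test`` against ``reference``."""
    x = _values(test)
    z = _values(reference)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z.shape}")
    err = np.sqrt(np.sum((x - z) ** 2))
    if variant == "reference":
        denom = np.sqrt(np.sum(z * z))
        if denom == 0.0:
            raise ValueError("reference image is identically zero")
    elif variant == "printed":
        denom = np.sum(x)
        if denom == 0.0:
            raise ValueError("test image sums to zero; printed variant undefined")
    else:
        raise ValueError("variant must be 'reference' or 'printed'")
    return float(err / denom)


def ssim(
    test,
    reference,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float | None = None,
    pooled_range: bool = False,
) -> float:
    """Single global SSIM index between two images.

    ``dynamic_range`` overrides the stabilising constant scale s; by
    default s = max − min of the reference (or of both images pooled when
    ``pooled_range`` is set, making the index symmetric in its arguments).
    """
    x = _values(test)
    z = _values(reference)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z.shape}")
    if dynamic_range is not None:
        s = float(dynamic_range)
    elif pooled_range:
        s = float(max(x.max(), z.max()) - min(x.min(), z.min()))
    else:
        s = float(z.max() - z.min())
    if s == 0.0:
        s = 1.0  # degenerate (constant) reference: fall back to unit range
    c1 = (k1 * s) ** 2
    c2 = (k2 * s) ** 2
    mx, mz = x.mean(), z.mean()
    dx, dz = x - mx, z - mz
    vx = (dx * dx).mean()  # population (1/N) moments throughout
    vz = (dz * dz).mean()
    cov = (dx * dz).mean()
    return float(
        (2 * mx * mz + c1) * (2 * cov + c2) / ((mx**2 + mz**2 + c1) * (vx + vz + c2))
    )


def radial_error_profile(test, reference, n_radii: int | None = None) -> np.ndarray:
    """Mean absolute error per integer radius from the image centre.

    Returns an array ``profile`` where ``profile[r]`` is the mean of
    |test − reference| over pixels at radius ∈ [r, r+1).  Ring artifacts
    from a bad detector bin at signed coordinate s show up as a spike at
    radius |s|.
    """
    x = _values(test)
    z = _values(reference)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z.shape}")
    n = x.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0 : x.shape[0], 0 : x.shape[1]]
    rad = np.sqrt((xx - c) ** 2 + (yy - c) ** 2).ravel()
    err = np.abs(x - z).ravel()
    if n_radii is None:
        n_radii = int(np.floor(n / 2.0))
    idx = np.floor(rad).astype(int)
    keep = idx < n_radii
    counts = np.bincount(idx[keep], minlength=n_radii)
    sums = np.bincount(idx[keep], weights=err[keep], minlength=n_radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return prof


def bin_radius(geometry: ProjectionGeometry, bin_index: int) -> float:
    """Image-domain ring radius produced by detector bin ``bin_index``."""
    return float(abs(geometry.bin_coordinates()[bin_index]))
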