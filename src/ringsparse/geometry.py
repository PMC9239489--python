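"""Parallel-beam projection geometry, matched projector pair, and FBP.

The forward projector is a ray-driven Joseph-type operator: each ray is
traversed along its dominant axis, sampling the image by linear
interpolation in the transverse direction; sample weights carry the
path-length factor 1/max(|cos θ|, |sin θ|).  The projector is materialised
once per geometry as a sparse matrix ``A`` so that the backprojector is the
*exact* algebraic transpose ``Aᵀ`` — the gradient of the data-fit term in
the ring-elimination solvers uses ``Aᵀ`` literally, and an unmatched pair
would break gradient-descent convergence.

Conventions (fixed, documented, not configurable):

* view angles measured counter-clockwise from the x-axis, placed at the
  left edge of each uniform interval, ``angle_k = k · range / Θ``;
* detector centered on the rotation axis, spacing in pixel units
  (default 1.0); bin ``r`` sits at signed coordinate
  ``s_r = (r − (R−1)/2) · spacing``;
* a ray is the line ``x cos θ + y sin θ = s`` (x → columns, y → rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ProjectionGeometry",
    "Image",
    "Sinogram",
    "build_geometry",
    "forward_project",
    "back_project",
    "fbp_reconstruct",
]


@dataclass(eq=False)
class ProjectionGeometry:
    """Parallel-beam acquisition geometry for an n×n image.

    Attributes
    ----------
    n_pixels_side:
        Image side length n (the image has N = n² pixels).
    n_bins:
        Number of detector bins R per view.
    n_angles:
        Number of views Θ.
    angular_range_deg:
        Angular coverage, 180 or 360 degrees.
    detector_spacing:
        Detector pitch in pixel units (> 0).
    angles:
        The Θ view angles in radians, uniformly spaced over
        [0, angular_range).
    """

    n_pixels_side: int
    n_bins: int
    n_angles: int
    angular_range_deg: float = 360.0
    detector_spacing: float = 1.0
    angles: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_pixels_side <= 0 or self.n_bins <= 0 or self.n_angles <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.angular_range_deg not in (180.0, 180, 360.0, 360):
            raise ValueError("angular_range_deg must be 180 or 360")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")
        if self.angles is None:
            rng = np.deg2rad(float(self.angular_range_deg))
            self.angles = rng * np.arange(self.n_angles) / self.n_angles
        self.angles = np.asarray(self.angles, dtype=float)
        self._A = None
        self._AT = None
        self._opnorm = None

    # -- derived quantities -------------------------------------------------

    @property
    def n_rays(self) -> int:
        """Total number of measurements M = R × Θ."""
        return self.n_bins * self.n_angles

    def bin_coordinates(self) -> np.ndarray:
        """Signed detector coordinate of every bin (pixel units)."""
        r = np.arange(self.n_bins, dtype=float)
        return (r - (self.n_bins - 1) / 2.0) * self.detector_spacing

    def system_matrix(self) -> sp.csr_matrix:
        """The (M × N) Joseph system matrix, built lazily and cached."""
        if self._A is None:
            self._A = _joseph_matrix(self)
        return self._A

    def system_matrix_t(self) -> sp.csr_matrix:
        """The exact transpose Aᵀ as a CSR matrix (cached)."""
        if self._AT is None:
            self._AT = self.system_matrix().T.tocsr()
        return self._AT

    def operator_norm(self, n_iter: int = 30, seed: int = 0) -> float:
        """Power-iteration estimate of ‖A‖₂ (largest singular value)."""
        if self._opnorm is None:
            A = self.system_matrix()
            AT = self.system_matrix_t()
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(A.shape[1])
            v /= np.linalg.norm(v)
            for _ in range(n_iter):
                w = AT @ (A @ v)
                nw = np.linalg.norm(w)
                if nw == 0.0:
                    return 0.0
                v = w / nw
            self._opnorm = float(np.sqrt(v @ (AT @ (A @ v))))
        return self._opnorm


@dataclass
class Image:
    """A square 2-D attenuation map (the solver's vector x of length N)."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Image.values must be a square 2-D array")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Sinogram:
    """Projection data b, an (R × Θ) grid of log-attenuation line integrals."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_bins, self.geometry.n_angles)
        if self.values.shape != expected:
            raise ValueError(
                f"Sinogram shape {self.values.shape} does not match geometry {expected}"
            )


def build_geometry(
    n_pixels_side: int,
    n_bins: int,
    n_angles: int,
    angular_range_deg: float = 360.0,
    detector_spacing: float = 1.0,
) -> ProjectionGeometry:
    """Create a parallel-beam geometry with uniformly spaced view angles."""
    return ProjectionGeometry(
        n_pixels_side=int(n_pixels_side),
        n_bins=int(n_bins),
        n_angles=int(n_angles),
        angular_range_deg=float(angular_range_deg),
        detector_spacing=float(detector_spacing),
    )


def _joseph_matrix(geom: ProjectionGeometry) -> sp.csr_matrix:
    """Build the sparse Joseph projector for ``geom``.

    Rays are indexed m = r·Θ + t so that a flattened (R, Θ) sinogram in C
    order matches A @ x.ravel().
    """
    n = geom.n_pixels_side
    R = geom.n_bins
    T = geom.n_angles
    s = geom.bin_coordinates()
    pix = np.arange(n, dtype=float) - (n - 1) / 2.0

    rows_all, cols_all, vals_all = [], [], []
    bin_idx = np.arange(R)
    for t, theta in enumerate(geom.angles):
        c, sn = np.cos(theta), np.sin(theta)
        ray_rows = bin_idx * T + t  # (R,)
        if abs(c) >= abs(sn):
            # traverse image rows (y); interpolate across columns (x)
            # x = (s - y sinθ) / cosθ
            X = (s[:, None] - pix[None, :] * sn) / c  # (R, n)
            frac_col = X + (n - 1) / 2.0
            weight = 1.0 / abs(c)
            i0 = np.floor(frac_col).astype(np.int64)
            w = frac_col - i0
            rr = np.broadcast_to(ray_rows[:, None], (R, n))
            img_row = np.broadcast_to(np.arange(n)[None, :], (R, n))
            for icol, wv in ((i0, (1.0 - w) * weight), (i0 + 1, w * weight)):
                m = (icol >= 0) & (icol < n) & (wv != 0.0)
                rows_all.append(rr[m])
                cols_all.append(img_row[m] * n + icol[m])
                vals_all.append(wv[m])
        else:
            # traverse image columns (x); interpolate across rows (y)
            # y = (s - x cosθ) / sinθ
            Y = (s[:, None] - pix[None, :] * c) / sn  # (R, n)
            frac_row = Y + (n - 1) / 2.0
            weight = 1.0 / abs(sn)
            i0 = np.floor(frac_row).astype(np.int64)
            w = frac_row - i0
            rr = np.broadcast_to(ray_rows[:, None], (R, n))
            img_col = np.broadcast_to(np.arange(n)[None, :], (R, n))
            for irow, wv in ((i0, (1.0 - w) * weight), (i0 + 1, w * weight)):
                m = (irow >= 0) & (irow < n) & (wv != 0.0)
                rows_all.append(rr[m])
                cols_all.append(irow[m] * n + img_col[m])
                vals_all.append(wv[m])

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(R * T, n * n))
    return A.tocsr()


def forward_project(image: Image, geometry: ProjectionGeometry) -> Sinogram:
    """Apply the system matrix: returns A x as an (R × Θ) sinogram."""
    if image.n != geometry.n_pixels_side:
        raise ValueError(
            f"image side {image.n} does not match geometry {geometry.n_pixels_side}"
        )
    A = geometry.system_matrix()
    p = A @ image.values.ravel()
    return Sinogram(p.reshape(geometry.n_bins, geometry.n_angles), geometry)


def back_project(sinogram: Sinogram, geometry: ProjectionGeometry) -> Image:
    """Apply the exact transpose: returns Aᵀ b as an n × n image."""
    if sinogram.values.shape != (geometry.n_bins, geometry.n_angles):
        raise ValueError("sinogram shape does not match geometry")
    AT = geometry.system_matrix_t()
    x = AT @ sinogram.values.ravel()
    n = geometry.n_pixels_side
    return Image(x.reshape(n, n))


def _ramp_filter_sinogram(values: np.ndarray, spacing: float) -> np.ndarray:
    """Ram-Lak filter each view (column) in the frequency domain."""
    R = values.shape[0]
    pad = 1 << max(6, int(np.ceil(np.log2(2 * R))))
    freqs = np.fft.rfftfreq(pad, d=spacing)
    P = np.fft.rfft(values, n=pad, axis=0)
    q = np.fft.irfft(P * freqs[:, None], n=pad, axis=0)
    return q[:R]


def inscribed_circle_mask(n: int) -> np.ndarray:
    """Boolean mask of the inscribed disk (the reconstructable support)."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= (n / 2.0) ** 2


def fbp_reconstruct(sinogram: Sinogram, geometry: ProjectionGeometry) -> Image:
    """Filtered back-projection baseline (Ram-Lak filter, matched Aᵀ).

    The reconstruction is scaled by π/Θ, which makes full-view noise-free
    reconstructions approximate the phantom for both 180° and 360° ranges
    (over 360° opposing views average). Pixels outside the inscribed circle
    are zeroed.
    """
    if sinogram.values.shape != (geometry.n_bins, geometry.n_angles):
        raise ValueError("sinogram shape does not match geometry")
    if geometry.n_angles < 2:
        raise ValueError("FBP needs at least 2 views")
    q = _ramp_filter_sinogram(sinogram.values, geometry.detector_spacing)
    rec = back_project(Sinogram(q, geometry), geometry).values
    rec *= np.pi / geometry.n_angles
    rec[~inscribed_circle_mask(geometry.n_pixels_side)] = 0.0
    return Image(rec)
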