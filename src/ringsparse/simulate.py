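"""Synthetic-data generator: phantoms, ring-artifact corruption, and
Poisson counting noise.

The corruption model writes the measured sinogram as
``b = A x_true − λ_true`` (equivalently ``A x_true = b + λ_true``), i.e.
the sparse imperfect component λ acts additively in the log-attenuation
domain.  Bad bins come in two adjacency flavours — isolated bins (thin
rings) or runs up to 3 bins wide (thick rings) — and the per-bin offset is
either constant over the view angle or modulated by a smooth sinusoidal
law.  A multiplicative-gain option (gain applied to the photon counts
before the log) is also provided, since a detector-sensitivity error is
physically multiplicative; the additive model is the default because it is
exactly the decomposition the solvers assume.

Counting noise follows the standard CT model: expected counts
``b_i = b0 · exp(−p_i)`` for line integral ``p_i``, observed counts
Poisson-distributed, and the noisy measurement is ``g_i = −log(b̃_i/b0)``
(counts clamped to ≥ 1 before the log).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize

from .geometry import Image, ProjectionGeometry, Sinogram, build_geometry, forward_project

__all__ = [
    "RingErrorModel",
    "NoiseModel",
    "make_phantom",
    "corrupt_sinogram",
    "add_poisson_noise",
    "make_study_case",
    "StudyCase",
]

# default per-bin offset magnitude, as a fraction of the clean sinogram max
_MAG_LO, _MAG_HI = 0.02, 0.10


@dataclass
class RingErrorModel:
    """Generative model for the sparse imperfect component λ.

    ``bad_bins`` is either an explicit list of detector-bin indices (for
    ``adjacent_runs``, the *starting* bins of the runs) or an integer count
    of bins/runs to place pseudo-randomly from ``seed``.  ``magnitude`` is
    a scalar or per-bin array of offsets in log-sinogram units; if omitted,
    magnitudes are drawn uniformly in [2%, 10%] of the clean sinogram's
    maximum, with random sign.
    """

    bad_bins: Sequence[int] | int = 5
    adjacency: str = "non_adjacent"  # or "adjacent_runs"
    max_run_width: int = 3
    angular_mode: str = "constant"  # or "varying"
    magnitude: float | Sequence[float] | None = None
    varying_law: Callable[[np.ndarray], np.ndarray] | None = None
    mode: str = "additive"  # or "multiplicative" (gain on counts)
    placement_halfwidth: float | None = None  # max |s| for auto-placed bins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adjacency not in ("non_adjacent", "adjacent_runs"):
            raise ValueError("adjacency must be 'non_adjacent' or 'adjacent_runs'")
        if self.angular_mode not in ("constant", "varying"):
            raise ValueError("angular_mode must be 'constant' or 'varying'")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")
        if self.max_run_width < 1:
            raise ValueError("max_run_width must be >= 1")


@dataclass
class NoiseModel:
    """Poisson counting-noise model with mean source flux b0 (counts/bin)."""

    b0: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


def _grid(n: int):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) / n, (yy - c) / n  # coordinates in units of image side


def _ellipse(u, v, cx, cy, a, b, angle_deg=0.0):
    t = np.deg2rad(angle_deg)
    ur = (u - cx) * np.cos(t) + (v - cy) * np.sin(t)
    vr = -(u - cx) * np.sin(t) + (v - cy) * np.cos(t)
    return (ur / a) ** 2 + (vr / b) ** 2 <= 1.0


def make_phantom(n: int, kind: str = "chest_like") -> Image:
    """Deterministic test phantom with attenuation values in [0, 1].

    Kinds: ``disk`` (unit disk of radius 0.4 n), ``shepp_logan`` (the
    standard ellipse set, resampled to n×n), ``chest_like`` (soft-tissue
    body ellipse, two low-attenuation lung ellipses, rib-like arcs and a
    spine blob — a stand-in for a thoracic CT slice).
    """
    if n < 16:
        raise ValueError("phantom size must be >= 16")
    if kind == "disk":
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        vals = (((xx - c) ** 2 + (yy - c) ** 2) <= (0.4 * n) ** 2).astype(float)
        return Image(vals)
    if kind == "shepp_logan":
        from skimage.data import shepp_logan_phantom

        base = shepp_logan_phantom()  # 400 × 400, values in [0, 1]
        vals = resize(base, (n, n), order=1, anti_aliasing=True, mode="reflect")
        return Image(np.clip(vals, 0.0, 1.0))
    if kind == "chest_like":
        u, v = _grid(n)
        vals = np.zeros((n, n))
        body = _ellipse(u, v, 0.0, 0.0, 0.42, 0.30)
        vals[body] = 0.30
        # lungs: two low-attenuation ellipses
        for sx in (-1.0, 1.0):
            lung = _ellipse(u, v, sx * 0.17, -0.02, 0.14, 0.20, angle_deg=sx * 8)
            vals[lung & body] = 0.05
        # heart-ish blob between the lungs, slightly denser than tissue
        heart = _ellipse(u, v, -0.03, 0.08, 0.09, 0.11, angle_deg=-20)
        vals[heart & body] = 0.40
        # spine: small dense ellipse at the back
        spine = _ellipse(u, v, 0.0, 0.24, 0.045, 0.05)
        vals[spine & body] = 0.80
        # rib-like arcs: a thin high-attenuation shell just inside the body
        shell_out = _ellipse(u, v, 0.0, 0.0, 0.41, 0.29)
        shell_in = _ellipse(u, v, 0.0, 0.0, 0.385, 0.265)
        ribs = shell_out & ~shell_in
        # break the shell into arc segments for texture
        ang = np.arctan2(v, u)
        segs = (np.floor((ang + np.pi) / (np.pi / 6)).astype(int) % 2) == 0
        vals[ribs & segs] = 0.80
        return Image(vals)
    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# Ring corruption
# ---------------------------------------------------------------------------


def _place_bins(model: RingErrorModel, R: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Return a list of (start_bin, width) runs."""
    if model.placement_halfwidth is not None:
        centre = (R - 1) / 2.0
        lo = int(np.ceil(centre - model.placement_halfwidth))
        hi = int(np.floor(centre + model.placement_halfwidth))
    else:
        margin = max(1, int(round(0.05 * R)))  # exclude outermost 5% of bins
        lo, hi = margin, R - 1 - margin
    if isinstance(model.bad_bins, (int, np.integer)):
        count = int(model.bad_bins)
        if model.adjacency == "non_adjacent":
            widths = [1] * count
        else:
            widths = list(rng.integers(1, model.max_run_width + 1, size=count))
        starts: list[int] = []
        attempts = 0
        while len(starts) < count:
            cand = int(rng.integers(lo, hi + 1))
            w = widths[len(starts)]
            # keep a one-bin guard band between runs (non-adjacent by construction)
            if all(cand + w < s or s + widths[i] < cand for i, s in enumerate(starts)):
                starts.append(cand)
            attempts += 1
            if attempts > 10000:
                raise RuntimeError("could not place bad bins; too many requested")
        runs = sorted(zip(starts, widths))
    else:
        bins = sorted(int(b) for b in model.bad_bins)
        if any(b < 0 or b >= R for b in bins):
            raise ValueError("bad bin index outside [0, R)")
        if model.adjacency == "non_adjacent":
            runs = [(b, 1) for b in bins]
        else:
            widths = list(rng.integers(1, model.max_run_width + 1, size=len(bins)))
            runs = [(b, min(w, R - b)) for b, w in zip(bins, widths)]
    # merge overlapping runs, warning as we go
    merged: list[tuple[int, int]] = []
    for b, w in runs:
        if merged and b <= merged[-1][0] + merged[-1][1] - 1:
            pb, pw = merged[-1]
            newend = max(pb + pw, b + w)
            warnings.warn(f"overlapping bad-bin runs at bin {b}; merging")
            merged[-1] = (pb, newend - pb)
        else:
            merged.append((b, w))
    return merged


def default_varying_law(theta_index: np.ndarray) -> np.ndarray:
    """Default angular modulation: factor 1 + 0.5·sin(2πθ/Θ) ∈ [0.5, 1.5]."""
    n = len(theta_index)
    return 1.0 + 0.5 * np.sin(2.0 * np.pi * theta_index / n)


def corrupt_sinogram(clean: Sinogram, model: RingErrorModel):
    """Inject the ring-artifact component; returns (corrupted, λ_true).

    ``corrupted = clean − λ_true`` so that ``A x_true = corrupted + λ_true``
    — the solvers' recovered λ estimates ``λ_true`` directly.  λ_true is an
    (R × Θ) array, zero outside the bad bins, constant per bin across
    angles in ``constant`` mode and modulated by the varying law otherwise.
    """
    R, T = clean.values.shape
    rng = np.random.default_rng(model.seed)
    runs = _place_bins(model, R, rng)
    bins = np.concatenate([np.arange(b, min(b + w, R)) for b, w in runs]) if runs else np.array([], int)
    bins = np.unique(bins)

    if model.magnitude is None:
        base = np.abs(clean.values).max()
        mags = rng.uniform(_MAG_LO * base, _MAG_HI * base, size=len(bins))
        mags *= rng.choice([-1.0, 1.0], size=len(bins))
    elif np.ndim(model.magnitude) == 0:
        mags = np.full(len(bins), float(model.magnitude))
    else:
        mags = np.asarray(model.magnitude, dtype=float)
        if len(mags) != len(bins):
            raise ValueError("per-bin magnitude length does not match number of bad bins")

    lam = np.zeros((R, T))
    if model.angular_mode == "constant":
        lam[bins, :] = mags[:, None]
    else:
        law = model.varying_law or default_varying_law
        lam[bins, :] = mags[:, None] * law(np.arange(T))[None, :]

    if model.mode == "additive":
        corrupted = clean.values - lam
    else:
        # multiplicative detector gain g on the counts: log domain offset
        # becomes −log(g); the returned λ_true is the equivalent additive one
        gain = np.exp(lam)
        corrupted = clean.values - np.log(gain)
    return Sinogram(corrupted, clean.geometry), lam


def add_poisson_noise(sinogram: Sinogram, model: NoiseModel) -> Sinogram:
    """Poisson counting noise: g = −log(max(Poisson(b0 e^{−p}), 1)/b0)."""
    p = sinogram.values
    # mildly negative log-attenuation (e.g. a positive detector offset in a
    # corrupted air region) simply means expected counts above b0
    rng = np.random.default_rng(model.seed)
    expected = model.b0 * np.exp(-p)
    counts = rng.poisson(expected).astype(float)
    counts = np.maximum(counts, 1.0)  # avoid log(0); negligible at b0 = 1e6
    g = -np.log(counts / model.b0)
    return Sinogram(g, sinogram.geometry)


# ---------------------------------------------------------------------------
# Study cases
# ---------------------------------------------------------------------------


@dataclass
class StudyCase:
    phantom: Image
    clean: Sinogram
    corrupted: Sinogram
    true_lambda: np.ndarray
    geometry: ProjectionGeometry = field(init=False)

    def __post_init__(self) -> None:
        self.geometry = self.clean.geometry

    def __iter__(self):
        return iter((self.phantom, self.clean, self.corrupted, self.true_lambda))


@lru_cache(maxsize=8)
def scaled_geometry(n: int, n_bins: int | None = None) -> ProjectionGeometry:
    """Geometry scaled from the full-size 512-pixel / 1000-view / 360°
    acquisition proportionally to n.  The detector spans the image
    diagonal by default (an odd bin count, ceil(n√2) rounded odd, plus a
    2-bin margin → 185 bins at n = 128); pass ``n_bins`` to override
    (e.g. 512 for the width-matched full-size layout)."""
    if n_bins is None:
        bins = int(np.ceil(n * np.sqrt(2.0)))
        if bins % 2 == 0:
            bins += 1
        n_bins = bins + 2
    n_angles = max(2, int(round(1000 * n / 512)))
    return build_geometry(n, n_bins, n_angles, 360.0)


def make_study_case(
    case_id,
    n: int = 128,
    scale: float = 1.0,
    seed: int = 0,
    kind: str = "chest_like",
    n_bins: int | None = None,
) -> StudyCase:
    """Build one of the simulation study conditions at image size n.

    * case 1 — 5 isolated (non-adjacent) bad bins, angular-constant offsets;
    * case 2 — 3 adjacent runs up to 3 bins wide, angular-constant;
    * case 3 — as case 2 but angular-varying (sinusoidal modulation);
    * "noisy" — case 1 plus Poisson noise at b0 = 10⁶ counts/bin.

    ``scale`` multiplies the drawn offset magnitudes (default magnitudes
    are 2–10% of the clean sinogram maximum, random sign).

    The [0, 1] display phantom is rescaled to a physically plausible
    attenuation-per-pixel (factor 22.5/n, giving line integrals up to
    about 6, i.e. minimum transmission around 0.25% — typical for a
    thorax) so that the Poisson counting model at b0 = 10⁶ behaves
    realistically; the returned phantom carries the same scaling and is
    the reference for the metrics.
    """
    if n < 64:
        raise ValueError("study cases need n >= 64")
    case = str(case_id)
    if case not in {"1", "2", "3", "noisy"}:
        raise ValueError("case_id must be 1, 2, 3 or 'noisy'")
    geom = scaled_geometry(n, n_bins)
    phantom = Image(make_phantom(n, kind).values * (22.5 / n))
    clean = forward_project(phantom, geom)

    halfwidth = 0.85 * (n / 2.0)
    if case in ("1", "noisy"):
        model = RingErrorModel(
            bad_bins=5, adjacency="non_adjacent", angular_mode="constant",
            placement_halfwidth=halfwidth, seed=seed,
        )
    elif case == "2":
        model = RingErrorModel(
            bad_bins=3, adjacency="adjacent_runs", max_run_width=3,
            angular_mode="constant", placement_halfwidth=halfwidth, seed=seed,
        )
    else:
        model = RingErrorModel(
            bad_bins=3, adjacency="adjacent_runs", max_run_width=3,
            angular_mode="varying", placement_halfwidth=halfwidth, seed=seed,
        )
    corrupted, lam = corrupt_sinogram(clean, model)
    if scale != 1.0:
        lam = lam * scale
        corrupted = Sinogram(clean.values - lam, geom)
    if case == "noisy":
        corrupted = add_poisson_noise(corrupted, NoiseModel(b0=1e6, seed=seed + 1))
    return StudyCase(phantom, clean, corrupted, lam)
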