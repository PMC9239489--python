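"""File round-tripping and flat key-value configuration.

Formats (all plain, lossless for float32):

* images — TIFF (float32) via :mod:`tifffile`, or raw little-endian
  float32 with a sidecar text header ``<path>.hdr`` carrying
  ``width``/``height``;
* sinograms and λ arrays — raw float32 + header with ``n_bins``,
  ``n_angles``, ``angular_range_deg`` (and ``n_pixels_side`` so the
  geometry can be rebuilt);
* solver history — CSV with header
  ``k,datafit,S_lambda,H_x,residual,rrmse,ssim``;
* configuration — flat ``key = value`` lines, ``#`` comments.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from .geometry import Image, ProjectionGeometry, Sinogram, build_geometry

__all__ = [
    "write_image_tiff",
    "read_image_tiff",
    "write_image_raw",
    "read_image_raw",
    "write_sinogram_raw",
    "read_sinogram_raw",
    "write_history_csv",
    "read_config",
    "write_config",
]


def write_image_tiff(path, image: Image) -> None:
    tifffile.imwrite(str(path), image.values.astype(np.float32))


def read_image_tiff(path) -> Image:
    return Image(tifffile.imread(str(path)).astype(float))


def _write_header(path: Path, fields: dict) -> None:
    lines = [f"{k} {v}" for k, v in fields.items()]
    path.write_text("\n".join(lines) + "\n")


def _read_header(path: Path) -> dict:
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        k, v = line.split(None, 1)
        out[k] = v
    return out


def write_image_raw(path, image: Image) -> None:
    path = Path(path)
    image.values.astype("<f4").tofile(path)
    _write_header(
        path.with_suffix(path.suffix + ".hdr"),
        {"width": image.n, "height": image.n},
    )


def read_image_raw(path) -> Image:
    path = Path(path)
    hdr = _read_header(path.with_suffix(path.suffix + ".hdr"))
    w, h = int(hdr["width"]), int(hdr["height"])
    vals = np.fromfile(path, dtype="<f4").reshape(h, w)
    return Image(vals.astype(float))


def write_sinogram_raw(path, sinogram: Sinogram) -> None:
    path = Path(path)
    g = sinogram.geometry
    sinogram.values.astype("<f4").tofile(path)
    _write_header(
        path.with_suffix(path.suffix + ".hdr"),
        {
            "n_bins": g.n_bins,
            "n_angles": g.n_angles,
            "angular_range_deg": float(g.angular_range_deg),
            "n_pixels_side": g.n_pixels_side,
            "detector_spacing": g.detector_spacing,
        },
    )


def read_sinogram_raw(path) -> Sinogram:
    path = Path(path)
    hdr = _read_header(path.with_suffix(path.suffix + ".hdr"))
    geom = build_geometry(
        int(hdr["n_pixels_side"]),
        int(hdr["n_bins"]),
        int(hdr["n_angles"]),
        float(hdr["angular_range_deg"]),
        float(hdr.get("detector_spacing", 1.0)),
    )
    vals = np.fromfile(path, dtype="<f4").reshape(geom.n_bins, geom.n_angles)
    return Sinogram(vals.astype(float), geom)


def write_lambda_raw(path, lam: np.ndarray, geometry: ProjectionGeometry) -> None:
    write_sinogram_raw(path, Sinogram(np.asarray(lam, float), geometry))


def write_history_csv(path, history) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "datafit", "S_lambda", "H_x", "residual", "rrmse", "ssim"])
        for rec in history:
            w.writerow(
                [
                    rec.k,
                    repr(rec.data_fit),
                    repr(rec.s_lambda),
                    repr(rec.h_smooth),
                    repr(rec.residual),
                    "" if rec.rrmse is None else repr(rec.rrmse),
                    "" if rec.ssim is None else repr(rec.ssim),
                ]
            )


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file (``#`` starts a comment)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_config(path, config: dict) -> None:
    Path(path).write_text(
        "\n".join(f"{k} = {v}" for k, v in config.items()) + "\n"
    )
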