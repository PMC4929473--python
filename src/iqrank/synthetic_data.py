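"""Synthetic microscopy-like images and Gaussian-blur focus series.

Every validation input is generated here: filament images emulating
intermediate-filament (vimentin) stains, bead images emulating
fluorescent nanoparticles, intensity ramps, and white noise.  Blurring a
base image with an increasing Gaussian radius emulates a through-focus
series; a "mixed" dataset blurs several different bases with small radii,
emulating a dataset of distinct photographs with blurred duplicates; and
an HCS-like time course emulates a screening well in which the amount of
content ramps up over time while the autofocus occasionally fails.

"Radius" means the Gaussian σ in pixels (ImageJ-style convention); only
the monotone radius → blur relation matters for any property tested.
Series are written as 8-bit TIFFs clipped to [0, 255], matching typical
photograph and screening exports, with a ground-truth sidecar CSV.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import GrayImage, save_image

BASE_KINDS = ("filaments", "beads", "ramp", "white_noise")
GROUND_TRUTH_NAME = "ground_truth.csv"


@dataclass(frozen=True)
class BlurSeriesSpec:
    """Recipe for a Gaussian-blur focus series.

    ``radii`` must be sorted ascending and include 0 (the unblurred
    original).  ``mixed`` blurs several distinct bases (see
    :func:`make_blur_series`).
    """

    base_image_kind: str
    radii: tuple[float, ...]
    seed: int = 0
    image_size: tuple[int, int] = (256, 256)
    n_bases: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_image_kind not in BASE_KINDS + ("mixed",):
            raise ParameterError(f"unknown base image kind {self.base_image_kind!r}")
        radii = tuple(float(r) for r in self.radii)
        if any(r < 0 for r in radii):
            raise ParameterError("blur radii must be ≥ 0")
        if list(radii) != sorted(radii) or (radii and radii[0] != 0.0):
            raise ParameterError("radii must be sorted ascending and start at 0")
        object.__setattr__(self, "radii", radii)


def _filaments(rng: np.random.Generator, h: int, w: int, params: dict) -> np.ndarray:
    """Random anti-aliased line segments with Gaussian cross-section."""
    n_lines = params.get("n_lines", 20)
    sigma = params.get("line_sigma", 1.5)
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(n_lines):
        p0 = rng.uniform([0, 0], [h, w])
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 1.0) * min(h, w)
        p1 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
        amp = rng.uniform(120, 255)
        d = p1 - p0
        seg_len2 = d @ d
        t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2
        img += amp * np.exp(-dist2 / (2 * sigma**2))
    return img


def _beads(rng: np.random.Generator, h: int, w: int, params: dict) -> np.ndarray:
    """Gaussian spots at random positions (fluorescent nanoparticles)."""
    n_beads = params.get("n_beads", 50)
    sigma = params.get("bead_sigma", 2.0)
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if "positions" in params:
        centers = np.atleast_2d(np.asarray(params["positions"], dtype=np.float64))
        amps = np.full(len(centers), params.get("amplitude", 200.0))
    else:
        centers = rng.uniform([0, 0], [h, w], size=(n_beads, 2))
        amps = rng.uniform(100, 255, size=n_beads)
    for (cy, cx), amp in zip(centers, amps):
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return img


def make_base_image(
    kind: str, size: tuple[int, int] = (256, 256), seed: int = 0,
    params: dict | None = None,
) -> GrayImage:
    """Deterministic synthetic base image of the given kind.

    filaments: random line segments of Gaussian cross-section;
    beads: Gaussian spots at random positions; ramp: linear horizontal
    intensity gradient; white_noise: i.i.d. uniform pixels.  A small
    constant background (``params["background"]``, default 10) keeps the
    mean gray level away from zero, and filament/bead images carry
    additive Gaussian detector noise (``params["noise_sigma"]``, default
    2 gray levels) as real fluorescence images do; pass 0 for an ideal
    noise-free object image.
    """
    params = dict(params or {})
    h, w = size
    if h < 64 or w < 64:
        raise ParameterError(f"base images must be at least 64x64, got {size}")
    rng = np.random.default_rng(seed)
    noise_sigma = params.get("noise_sigma", 2.0)
    if kind == "filaments":
        img = _filaments(rng, h, w, params)
    elif kind == "beads":
        img = _beads(rng, h, w, params)
    elif kind == "ramp":
        lo, hi = params.get("lo", 0.0), params.get("hi", 255.0)
        img = np.tile(np.linspace(lo, hi, w), (h, 1))
        noise_sigma = params.get("noise_sigma", 0.0)
    elif kind == "white_noise":
        lo, hi = params.get("lo", 0.0), params.get("hi", 255.0)
        img = rng.uniform(lo, hi, size=(h, w))
        noise_sigma = 0.0
    else:
        raise ParameterError(f"unknown base image kind {kind!r}; choose from {BASE_KINDS}")
    img = img + params.get("background", 10.0)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=(h, w))
    return GrayImage(np.clip(img, 0, None))


def gaussian_blur(img: GrayImage, radius: float) -> GrayImage:
    """Gaussian convolution with σ = radius; radius 0 is the identity.

    The convolution is circular (wrap boundary), so blurring is exactly
    diagonal in the discrete Fourier basis the spectral measures use:
    every non-zero frequency is attenuated strictly monotonically in σ.
    A non-periodic boundary rule would instead inject border artifacts
    into the spectrum tail that dominate it once genuine content is
    attenuated.  The normalized kernel conserves total intensity.
    """
    if radius < 0:
        raise ParameterError(f"blur radius must be ≥ 0, got {radius}")
    if radius == 0:
        return GrayImage(img.pixels.copy(), source_path=img.source_path)
    blurred = ndimage.gaussian_filter(img.pixels, sigma=radius, mode="wrap")
    return GrayImage(np.clip(blurred, 0, None), source_path=img.source_path)


def _mixed_bases(spec: BlurSeriesSpec) -> list[tuple[str, int, GrayImage]]:
    """Distinct bases for a mixed dataset: kinds cycled, seeds varied."""
    n = spec.n_bases if spec.n_bases > 1 else 12
    out = []
    for i in range(n):
        kind = BASE_KINDS[i % len(BASE_KINDS)]
        seed = spec.seed + i
        out.append((f"{kind}{i:02d}", seed, make_base_image(kind, spec.image_size, seed, spec.params)))
    return out


def make_blur_series(spec: BlurSeriesSpec, out_dir: str | os.PathLike) -> list[Path]:
    """Write a Gaussian-blur series as 8-bit TIFFs plus a ground-truth CSV.

    One file per (base, radius), named ``<kind>_s<seed>_r<radius>.tif`` so
    lexicographic order equals radius order within a base.  The sidecar
    ``ground_truth.csv`` records image_id, kind, seed and radius.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec.base_image_kind == "mixed":
        bases = _mixed_bases(spec)
    else:
        bases = [(
            spec.base_image_kind, spec.seed,
            make_base_image(spec.base_image_kind, spec.image_size, spec.seed, spec.params),
        )]
    paths: list[Path] = []
    truth_rows = []
    for kind_tag, seed, base in bases:
        for radius in spec.radii:
            name = f"{kind_tag}_s{seed}_r{radius:04.1f}.tif"
            path = out_dir / name
            save_image(gaussian_blur(base, radius), path)
            paths.append(path)
            truth_rows.append({"image_id": name, "kind": kind_tag, "seed": seed, "radius": radius})
    with open(out_dir / GROUND_TRUTH_NAME, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_id", "kind", "seed", "radius"])
        writer.writeheader()
        writer.writerows(truth_rows)
    return paths


# Frame indices of the simulated autofocus failures in the HCS-like
# time course; everything else is sharp.
_HCS_HEAVY_FRAMES = (5, 13, 21, 28)
_HCS_MEDIUM_FRAMES = (8, 17, 25)
HCS_MEDIUM_RADIUS = 2.0
HCS_HEAVY_RADIUS = 8.0


def make_hcs_like_series(
    seed: int, out_dir: str | os.PathLike,
    n_frames: int = 30, size: tuple[int, int] = (192, 192),
) -> list[Path]:
    """Screening-well-like time course with ground-truth blur labels.

    Content density ramps from near-empty to detail-packed over the
    frames (beads plus a few filaments over a constant background, as a
    fluorescence channel would show growing cell culture); designated
    frames are blurred at medium (σ=2) or heavy (σ=8) level, emulating
    autofocus failures.  Labels (in_focus / blurred / out_of_focus) go to
    the sidecar ``ground_truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    truth_rows = []
    for t in range(n_frames):
        frac = t / max(n_frames - 1, 1)
        n_beads = int(round(3 + frac * 37))
        n_lines = int(round(1 + frac * 7))
        img = make_base_image(
            "beads", size, seed=seed * 1000 + t,
            params={"n_beads": n_beads, "background": 20.0},
        )
        fil = make_base_image(
            "filaments", size, seed=seed * 1000 + 500 + t,
            params={"n_lines": n_lines, "background": 0.0},
        )
        frame = GrayImage(img.pixels + fil.pixels)
        if t in _HCS_HEAVY_FRAMES:
            radius, label = HCS_HEAVY_RADIUS, "out_of_focus"
        elif t in _HCS_MEDIUM_FRAMES:
            radius, label = HCS_MEDIUM_RADIUS, "blurred"
        else:
            radius, label = 0.0, "in_focus"
        name = f"hcs_t{t:03d}.tif"
        save_image(gaussian_blur(frame, radius), out_dir / name)
        paths.append(out_dir / name)
        truth_rows.append({
            "image_id": name, "frame": t, "radius": radius,
            "label": label, "n_objects": n_beads + n_lines,
        })
    with open(out_dir / GROUND_TRUTH_NAME, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_id", "frame", "radius", "label", "n_objects"]
        )
        writer.writeheader()
        writer.writerows(truth_rows)
    return paths
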