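"""Deterministic generator of colposcopy-like test images with ground truth.

Each image is a roughly central, randomly rotated ellipse of a pink-ish
foreground colour (the "cervix" region) over a darker red-brown background
(vaginal wall), both textured with Gaussian noise, plus a few near-white
discs emulating specular glare from the light source.  The paired boolean
mask marks the ellipse interior.  Highlights are painted *after* the mask is
drawn and are deliberately not excluded from it — like real glare sitting
inside the cervix region — so they act as outlier pixels the segmentation
losses must tolerate.

Everything is a pure function of the seed in :class:`SyntheticSpec`, down
to byte-identical PNG output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SyntheticSpec", "generate_image", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic colposcopy-like image distribution.

    ``ellipse_axes_range`` and ``ellipse_center_jitter`` are fractions of
    ``min(H, W)``; their defaults keep the ellipse fully inside the frame.
    ``min_channel_separation`` is the guaranteed per-channel gap between the
    default foreground and background colour means.
    """

    size: tuple[int, int] = (64, 64)
    ellipse_center_jitter: float = 0.04
    ellipse_axes_range: tuple[float, float] = (0.25, 0.45)
    fg_color_mean: tuple[float, float, float] = (0.85, 0.55, 0.62)
    bg_color_mean: tuple[float, float, float] = (0.42, 0.22, 0.25)
    color_jitter: float = 0.04
    min_channel_separation: float = 0.3
    texture_noise_sd: float = 0.05
    n_highlights: int = 3
    highlight_radius_range: tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.ellipse_axes_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ellipse_axes_range must lie within (0, 0.5]")
        if self.min_channel_separation <= 0:
            raise ValueError("min_channel_separation must be positive")
        gap = np.abs(np.array(self.fg_color_mean) - np.array(self.bg_color_mean))
        if np.any(gap < self.min_channel_separation):
            raise ValueError(
                f"fg/bg colour means must differ by >= {self.min_channel_separation} "
                f"per channel; got gaps {gap.round(3).tolist()}")


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair; image float32 (H,W,3) in [0,1], mask bool (H,W)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    m = min(h, w)

    cy = h / 2 + rng.uniform(-1, 1) * spec.ellipse_center_jitter * m
    cx = w / 2 + rng.uniform(-1, 1) * spec.ellipse_center_jitter * m
    a = rng.uniform(*spec.ellipse_axes_range) * m
    b = rng.uniform(*spec.ellipse_axes_range) * m
    theta = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    mask = rho <= 1.0
    # anti-aliased edge roughly 1.5 px wide
    alpha = np.clip((1.0 - rho) / (1.5 / min(a, b)) + 0.5, 0.0, 1.0)

    fg = np.clip(np.array(spec.fg_color_mean) + rng.uniform(-1, 1, 3) * spec.color_jitter, 0, 1)
    bg = np.clip(np.array(spec.bg_color_mean) + rng.uniform(-1, 1, 3) * spec.color_jitter, 0, 1)
    img = alpha[..., None] * fg + (1 - alpha[..., None]) * bg
    img += rng.normal(0, spec.texture_noise_sd, img.shape)

    for _ in range(spec.n_highlights):
        hy = rng.uniform(0, h)
        hx = rng.uniform(0, w)
        r = rng.uniform(*spec.highlight_radius_range)
        d = np.sqrt((yy - hy) ** 2 + (xx - hx) ** 2)
        glare = np.clip((r - d) / 1.0 + 0.5, 0.0, 1.0)
        white = np.clip(0.97 + rng.uniform(-0.02, 0.02, 3), 0, 1)
        img = glare[..., None] * white + (1 - glare[..., None]) * img

    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


def generate_dataset(spec: SyntheticSpec, n: int, out_dir=None):
    """``n`` image/mask pairs with seeds ``spec.seed + 0 .. n-1``.

    When ``out_dir`` is given, writes 8-bit RGB image PNGs, {0,255} grayscale
    mask PNGs and a ``manifest.csv`` (id, image_path, mask_path, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = [generate_image(replace(spec, seed=spec.seed + k)) for k in range(n)]
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            rows = []
            for k, (img, mask) in enumerate(pairs):
                img_path = out / f"synth_{k:04d}.png"
                mask_path = out / f"synth_{k:04d}_mask.png"
                Image.fromarray((img * 255).round().astype(np.uint8)).save(img_path)
                Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(mask_path)
                rows.append((f"synth_{k:04d}", img_path.name, mask_path.name, spec.seed + k))
            with open(out / "manifest.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["id", "image_path", "mask_path", "seed"])
                writer.writerows(rows)
        except OSError as exc:
            raise OSError(f"cannot write dataset to {out_dir}: {exc}") from exc
    return pairs
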