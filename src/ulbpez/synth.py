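"""Seeded synthetic fundus-like image generator.

Emulates the gross photometric structure of a retinal photograph — a bright
elliptical field of view (FOV) on a black field (hence black corners), a
green-dominant background with a radial illumination falloff and
choroidal-mottle texture, dark curvilinear vessels — plus a graded lesion
burden: microaneurysms (small dark discs, ~5 px diameter at 512x512 scale),
haemorrhages (larger dark blobs) and exudates (bright irregular blobs),
with counts increasing with the DR grade.  Grade 0 renders no lesions.

The generator is a controlled phantom: the anatomy (vignette shape, mottle
texture, vascular tree) is a fixed template drawn from ``anatomy_seed``,
shared by every image, the way a screening series from one camera shares
gross retinal architecture.  Per-image randomness — illumination tilt,
sensor noise, lesion counts/sizes/placement — comes from the per-image
seed, so grade is the only systematic factor separating the classes.
Everything is a pure function of (grade, seed, config) and regenerates
bit-identically.

This is test plumbing, not a photorealistic simulator: it has no optic
disc, no defocus/exposure artefacts, and lesion textures are scaled discs
rather than clinical morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .preprocessing import FundusImage

__all__ = ["SynthConfig", "Lesion", "SynthImage", "generate", "generate_dataset", "save_dataset"]


@dataclass
class SynthConfig:
    """Generator geometry and photometry.

    Lesion counts per grade g: microaneurysms 3g (+0/1 jitter) for g >= 1,
    haemorrhages and exudates max(0, 2(g-1)) each.  Sizes are stated at
    512x512 scale and rescaled to ``side``.  Contrasts: dark lesions ~35%
    darker than the local background, exudates ~40% brighter.

    ``anatomy_seed`` fixes the phantom anatomy (mottle texture + vascular
    tree); ``mottle_*`` set the background texture (amplitude in grey
    levels, correlation scale in rendered pixels); ``tilt_fraction`` is the
    per-image random illumination tilt relative to ``gradient_amplitude``;
    ``noise_sigma`` is additive sensor noise in grey levels.
    """

    side: int = 768
    fov_axes: tuple[float, float] = (0.48, 0.46)  # (x, y) semi-axes / side
    vessel_count: int = 9
    vessel_width: tuple[float, float] = (2.0, 6.0)  # at 512 scale
    base_green: float = 120.0
    gradient_amplitude: float = 20.0
    tilt_fraction: float = 0.02
    mottle_amplitude: float = 25.0
    mottle_scale: float = 4.0
    noise_sigma: float = 0.5
    anatomy_seed: int = 777
    ma_diameter: float = 5.0  # at 512 scale
    hem_size: tuple[float, float] = (10.0, 25.0)  # at 512 scale
    ex_size: tuple[float, float] = (8.0, 30.0)  # at 512 scale
    dark_contrast: float = 0.35
    bright_contrast: float = 0.40
    max_place_tries: int = 200

    def lesion_counts(self, grade: int, rng: np.random.Generator) -> dict[str, int]:
        if grade not in range(5):
            raise ValueError(f"grade must be in 0..4, got {grade}")
        if grade == 0:
            return {"microaneurysm": 0, "haemorrhage": 0, "exudate": 0}
        return {
            "microaneurysm": 3 * grade + int(rng.integers(0, 2)),
            "haemorrhage": max(0, 2 * (grade - 1)),
            "exudate": max(0, 2 * (grade - 1)),
        }

    def _anatomy_key(self) -> tuple:
        return (
            self.side,
            self.fov_axes,
            self.vessel_count,
            self.vessel_width,
            self.mottle_amplitude,
            self.mottle_scale,
            self.anatomy_seed,
        )


@dataclass
class Lesion:
    kind: str
    centre: tuple[int, int]  # (row, col)
    size: float  # diameter in pixels at the rendered scale


@dataclass
class SynthImage:
    image: FundusImage
    fov_mask: np.ndarray
    lesions: list[Lesion]

    @property
    def grade(self) -> int:
        assert self.image.label is not None
        return self.image.label


def _fov_mask(side: int, axes: tuple[float, float]) -> np.ndarray:
    rows, cols = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    ax, ay = axes[0] * side, axes[1] * side
    return ((cols - c) / ax) ** 2 + ((rows - c) / ay) ** 2 <= 1.0


def _draw_vessels(field: np.ndarray, mask: np.ndarray, cfg: SynthConfig, rng) -> None:
    """Dark random-walk curves radiating outward across the FOV.

    Darkening is applied through a factor map clipped at 0.55, so vessel
    crossings do not compound into unrealistically black pixels.
    """
    side = field.shape[0]
    scale = side / 512.0
    rows, cols = np.mgrid[0:side, 0:side]
    factor = np.ones_like(field)
    for _ in range(cfg.vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        start = side * rng.uniform(0.04, 0.12)  # clear of the exact centre
        r = side / 2.0 + start * math.sin(ang)
        c = side / 2.0 + start * math.cos(ang)
        heading = ang + np.pi * rng.uniform(-0.15, 0.15)
        width = rng.uniform(*cfg.vessel_width) * scale
        length = int(side * rng.uniform(0.45, 0.85))
        step = max(1.0, width / 2.0)
        for _i in range(int(length / step)):
            heading += rng.normal(0.0, 0.18)
            r += step * math.sin(heading)
            c += step * math.cos(heading)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < side and 0 <= ci < side) or not mask[ri, ci]:
                break
            rad = width / 2.0
            r0, r1 = max(0, ri - int(rad) - 1), min(side, ri + int(rad) + 2)
            c0, c1 = max(0, ci - int(rad) - 1), min(side, ci + int(rad) + 2)
            patch = (rows[r0:r1, c0:c1] - r) ** 2 + (cols[r0:r1, c0:c1] - c) ** 2 <= rad**2
            sub = factor[r0:r1, c0:c1]
            sub[patch] = 0.55
    field *= factor


_ANATOMY_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _anatomy(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """(mottle field, multiplicative vessel map) of the phantom anatomy.

    Deterministic in ``anatomy_seed``; cached because it is shared by every
    generated image.
    """
    key = cfg._anatomy_key()
    if key not in _ANATOMY_CACHE:
        rng = np.random.default_rng(cfg.anatomy_seed)
        side = cfg.side
        mottle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (side, side)), cfg.mottle_scale)
        sd = mottle.std()
        if sd > 0:
            mottle *= cfg.mottle_amplitude / sd
        mask = _fov_mask(side, cfg.fov_axes)
        flat = np.full((side, side), cfg.base_green)
        _draw_vessels(flat, mask, cfg, rng)
        vessel_map = flat / cfg.base_green
        _ANATOMY_CACHE[key] = (mottle, vessel_map)
    mottle, vessel_map = _ANATOMY_CACHE[key]
    return mottle, vessel_map


def _illumination(side: int, amplitude: float, tilt_fraction: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Radial vignette (fixed shape) plus a small random tilt plane."""
    rows, cols = np.mgrid[0:side, 0:side]
    theta = rng.uniform(0, 2 * np.pi)
    plane = (np.cos(theta) * (cols - side / 2) + np.sin(theta) * (rows - side / 2)) / side
    r2 = ((rows - side / 2) ** 2 + (cols - side / 2) ** 2) / (side / 2) ** 2
    return tilt_fraction * amplitude * plane - amplitude * r2


def _blob_mask(side: int, centre: tuple[float, float], diameter: float,
               rng, irregular: bool) -> np.ndarray:
    """Disc, or a union of jittered discs for irregular (exudate) shapes."""
    rows, cols = np.mgrid[0:side, 0:side]
    r0, c0 = centre
    rad = diameter / 2.0
    blob = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
    if irregular:
        for _ in range(3):
            jr = r0 + rng.normal(0, rad * 0.5)
            jc = c0 + rng.normal(0, rad * 0.5)
            jrad = rad * rng.uniform(0.4, 0.8)
            blob |= (rows - jr) ** 2 + (cols - jc) ** 2 <= jrad**2
    return blob


def generate(grade: int, seed: int, cfg: Optional[SynthConfig] = None) -> SynthImage:
    """Render one synthetic fundus image of the given DR grade."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    side = cfg.side
    scale = side / 512.0
    mask = _fov_mask(side, cfg.fov_axes)
    mottle, vessel_map = _anatomy(cfg)

    green = np.full((side, side), cfg.base_green, dtype=np.float64)
    green += _illumination(side, cfg.gradient_amplitude, cfg.tilt_fraction, rng)
    green += mottle
    green *= vessel_map

    # place lesions inside the FOV with a margin, away from the rim
    counts = cfg.lesion_counts(grade, rng)
    lesions: list[Lesion] = []
    c = (side - 1) / 2.0
    ax, ay = cfg.fov_axes[0] * side, cfg.fov_axes[1] * side
    for kind, n in counts.items():
        for _ in range(n):
            if kind == "microaneurysm":
                diameter = cfg.ma_diameter * scale * rng.uniform(0.9, 1.1)
            elif kind == "haemorrhage":
                diameter = rng.uniform(*cfg.hem_size) * scale
            else:
                diameter = rng.uniform(*cfg.ex_size) * scale
            for _attempt in range(cfg.max_place_tries):
                rr = rng.uniform(-1, 1)
                cc = rng.uniform(-1, 1)
                if rr**2 + cc**2 > 0.85**2:  # stay clear of the FOV rim
                    continue
                row = c + rr * ay
                col = c + cc * ax
                margin = diameter / 2.0 + 2
                if (
                    ((col - c) / (ax - margin)) ** 2 + ((row - c) / (ay - margin)) ** 2
                    <= 1.0
                ):
                    break
            else:
                raise RuntimeError(f"could not place a {kind} inside the FOV")
            blob = _blob_mask(side, (row, col), diameter, rng, irregular=kind == "exudate")
            if kind == "exudate":
                green[blob] = np.clip(green[blob] * (1.0 + cfg.bright_contrast), 0, 255)
            else:
                green[blob] = green[blob] * (1.0 - cfg.dark_contrast)
            lesions.append(
                Lesion(kind=kind, centre=(int(round(row)), int(round(col))), size=diameter)
            )

    if cfg.noise_sigma > 0:
        green += rng.normal(0.0, cfg.noise_sigma, size=green.shape)
    green = np.clip(green, 1.0, 255.0)  # FOV interior stays strictly above black

    red = np.clip(green * 0.80 + 12.0, 1.0, 255.0)
    blue = np.clip(green * 0.35, 1.0, 255.0)
    rgb = np.stack([red, green, blue], axis=-1)
    rgb[~mask] = 0.0
    pixels = np.rint(rgb).astype(np.uint8)
    return SynthImage(
        image=FundusImage(pixels=pixels, label=grade), fov_mask=mask, lesions=lesions
    )


def generate_dataset(
    n_per_grade: int,
    seed: int,
    cfg: Optional[SynthConfig] = None,
    grades: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> list[SynthImage]:
    """n images per grade with per-image seeds derived from ``seed``."""
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grades) * n_per_grade)
    out: list[SynthImage] = []
    i = 0
    for grade in grades:
        for _ in range(n_per_grade):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            out.append(generate(grade, child_seed, cfg))
            i += 1
    return out


def save_dataset(images: list[SynthImage], out_dir: str | Path) -> None:
    """Write PNGs, mask PNGs and an inventory/label CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(images):
        stem = f"synth_{i:04d}_g{s.grade}"
        Image.fromarray(s.image.pixels).save(out_dir / f"{stem}.png")
        Image.fromarray((s.fov_mask * np.uint8(255))).save(out_dir / f"{stem}_mask.png")
        for lesion in s.lesions:
            rows.append(
                {
                    "image": f"{stem}.png",
                    "grade": s.grade,
                    "kind": lesion.kind,
                    "row": lesion.centre[0],
                    "col": lesion.centre[1],
                    "size_px": lesion.size,
                }
            )
        if not s.lesions:
            rows.append(
                {"image": f"{stem}.png", "grade": s.grade, "kind": "none",
                 "row": -1, "col": -1, "size_px": 0.0}
            )
    pd.DataFrame(rows).to_csv(out_dir / "inventory.csv", index=False)
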