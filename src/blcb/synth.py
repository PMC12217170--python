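"""Synthetic fundus images with exact vessel ground truth.

Real fundus photographs show a bright circular field of view (FOV) on a
black surround, crossed by a branching vascular tree whose branches
thin out toward the periphery. The generator emulates exactly those
features: an illuminated disk with a radial gradient and Gaussian
noise, and vessel trees grown by a seeded branching random walk whose
stroke width shrinks at every bifurcation. Because vessels are stroked
programmatically, the ground truth, the thick/thin decomposition (by
stroked width) and the FOV mask are known exactly — every pipeline
stage is testable without external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw

__all__ = ["SynthConfig", "SyntheticSample", "generate_image", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Widths are in pixels; intensities on the [0, 1] scale. A branch
    whose width decays below 1 px (or that leaves the FOV) terminates;
    pixels stroked at width > ``thin_max_width`` form the thick class.
    """

    height: int = 256
    width: int = 256
    fov_radius_frac: float = 0.45
    n_trees: int = 2
    root_width_min: float = 5.0
    root_width_max: float = 7.0
    branch_decay: float = 0.7
    thin_max_width: float = 2.0
    vessel_contrast: float = 0.35
    noise_sd: float = 0.03
    illumination_slope: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin_max_width >= self.root_width_min:
            raise ValueError("thin_max_width must be below root_width_min")
        if not (0.0 < self.fov_radius_frac <= 0.5):
            raise ValueError("fov_radius_frac must lie in (0, 0.5]")


@dataclass
class SyntheticSample:
    """One generated image with its exact ground truth."""

    rgb: np.ndarray            # (H, W, 3) uint8
    gt: np.ndarray             # binary vessel mask
    thick_gt: np.ndarray       # stroked width > thin_max_width
    thin_gt: np.ndarray        # gt minus thick_gt
    fov: np.ndarray            # binary field-of-view disk
    branch_widths: list[float]  # stroke width of every branch segment
    config: SynthConfig


def _grow_tree(
    rng: np.random.Generator,
    width_map: np.ndarray,
    fov: np.ndarray,
    center: tuple[float, float],
    fov_radius: float,
    config: SynthConfig,
    widths_out: list[float],
) -> None:
    """Recursive branching random walk, stroking disks into width_map."""
    cy, cx = center
    angle = rng.uniform(0, 2 * np.pi)
    r0 = 0.85 * fov_radius
    pos = np.array([cy + r0 * np.sin(angle), cx + r0 * np.cos(angle)])
    heading = angle + np.pi + rng.uniform(-0.4, 0.4)  # point inward
    width = rng.uniform(config.root_width_min, config.root_width_max)
    stack = [(pos, heading, width, 0)]
    max_depth = 12
    while stack:
        pos, heading, width, depth = stack.pop()
        if width < 1.0 or depth > max_depth:
            continue
        widths_out.append(width)
        n_steps = int(rng.integers(12, 28))
        alive = True
        for _ in range(n_steps):
            rr = int(round(pos[0]))
            cc = int(round(pos[1]))
            if (pos[0] - cy) ** 2 + (pos[1] - cx) ** 2 > (fov_radius - 1.0) ** 2:
                alive = False
                break
            dd, dc = draw.disk((rr, cc), max(width / 2.0, 0.5), shape=width_map.shape)
            width_map[dd, dc] = np.maximum(width_map[dd, dc], width)
            heading += rng.normal(0.0, 0.12)
            pos = pos + 1.5 * np.array([np.sin(heading), np.cos(heading)])
        if alive:
            child = width * config.branch_decay
            split = rng.uniform(0.35, 0.7)
            stack.append((pos.copy(), heading - split, child, depth + 1))
            stack.append((pos.copy(), heading + split, child, depth + 1))


def generate_image(config: SynthConfig = SynthConfig()) -> SyntheticSample:
    """One synthetic fundus sample, bit-deterministic in ``config.seed``."""
    h, w = config.height, config.width
    fov_radius = config.fov_radius_frac * min(h, w)
    if fov_radius < 16:
        raise ValueError(
            f"FOV radius {fov_radius:.1f}px too small to host a vessel tree"
        )
    rng = np.random.default_rng(config.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    fov = dist2 <= fov_radius ** 2

    width_map = np.zeros((h, w), dtype=np.float64)
    widths: list[float] = []
    for _ in range(config.n_trees):
        _grow_tree(rng, width_map, fov, (cy, cx), fov_radius, config, widths)
    width_map[~fov] = 0.0
    gt = width_map > 0
    thick = width_map > config.thin_max_width
    thin = gt & ~thick

    # scene: radial illumination inside the FOV, near-black surround
    base = 0.45 + config.illumination_slope * (1.0 - dist2 / fov_radius ** 2)
    scene = np.where(fov, base, 0.02)
    vessel_soft = ndimage.gaussian_filter(gt.astype(np.float64), 0.7)
    scene = scene - config.vessel_contrast * np.minimum(vessel_soft * 1.5, 1.0) * fov
    scene = scene + rng.normal(0.0, config.noise_sd, size=scene.shape) * np.where(fov, 1.0, 0.3)
    scene = np.clip(scene, 0.0, 1.0)

    rgb = np.stack(
        [
            np.clip(scene * 1.15 + 0.05 * fov, 0, 1),
            scene,
            np.clip(scene * 0.55, 0, 1),
        ],
        axis=-1,
    )
    rgb8 = np.round(rgb * 255).astype(np.uint8)
    return SyntheticSample(
        rgb=rgb8,
        gt=gt.astype(np.uint8),
        thick_gt=thick.astype(np.uint8),
        thin_gt=thin.astype(np.uint8),
        fov=fov.astype(np.uint8),
        branch_widths=widths,
        config=config,
    )


def generate_dataset(
    n: int,
    out_dir,
    config: SynthConfig = SynthConfig(),
    seed: int = 0,
) -> list[Path]:
    """Write ``n`` samples in a DRIVE-style directory layout.

    Creates ``images/``, ``1st_manual/``, ``mask/`` plus ``thick/`` and
    ``thin/`` truth folders and an ``index.csv`` recording each sample's
    seed, so the dataset can be regenerated bit-identically.
    """
    import imageio.v3 as iio

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    subdirs = ["images", "1st_manual", "mask", "thick", "thin"]
    for sub in subdirs:
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, 2 ** 31 - 1, size=n)
    written = []
    with open(out_dir / "index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stem", "seed", "height", "width"])
        for i, s in enumerate(sample_seeds):
            sample = generate_image(replace(config, seed=int(s)))
            stem = f"{i:02d}"
            iio.imwrite(out_dir / "images" / f"{stem}.png", sample.rgb)
            iio.imwrite(out_dir / "1st_manual" / f"{stem}.png", sample.gt * 255)
            iio.imwrite(out_dir / "mask" / f"{stem}.png", sample.fov * 255)
            iio.imwrite(out_dir / "thick" / f"{stem}.png", sample.thick_gt * 255)
            iio.imwrite(out_dir / "thin" / f"{stem}.png", sample.thin_gt * 255)
            writer.writerow([stem, int(s), config.height, config.width])
            written.append(out_dir / "images" / f"{stem}.png")
    return written
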