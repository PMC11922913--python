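"""Synthetic mammogram-like phantoms with benign/malignant lesion morphology.

Each phantom is an 8-bit grayscale image: an elliptical breast region filled
with a smoothed-noise fibroglandular texture, one bright lesion, and additive
acquisition noise.  Benign lesions are radially smooth Gaussian blobs with a
near-circular boundary; malignant lesions are spiculated star shapes whose
boundary radius varies with angle (a low-order random Fourier perturbation
scaled by ``irregularity`` plus narrow spicule rays), emulating the irregular,
spiculated masses that mark malignancy on real mammograms.  The ground-truth
boundary-roughness score (circumferential std/mean of the boundary radius)
separates the classes by construction and gives the training loop a
known-learnable signal.

All randomness flows from a single seed; phantoms are bit-reproducible.
These are geometric stand-ins, not anatomically realistic breast simulations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .enhancement import GrayImage
from .errors import InvalidConfigError
from .trainer import LabeledDataset

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomImage",
    "PAPER_CLASS_RATIO",
    "generate_phantom",
    "generate_dataset",
    "imbalanced_counts",
]

# benign : malignant image counts of the source hospital collection
PAPER_CLASS_RATIO = (6200, 1005)


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters for the synthetic mammogram phantoms.

    ``benign_radius_range`` and all other pixel quantities are expressed at
    ``image_size`` = 128 and scale linearly with the actual image size.
    ``contrast`` is the lesion-to-background intensity gap in gray levels;
    ``irregularity`` (0..1) scales the malignant boundary perturbation.
    """

    image_size: int = 128
    n_benign: int = 100
    n_malignant: int = 100
    benign_radius_range: Tuple[float, float] = (10.0, 18.0)
    spicule_count_range: Tuple[int, int] = (6, 12)
    irregularity: float = 0.4
    background_texture_scale: float = 6.0
    noise_sigma: float = 6.0
    contrast: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise InvalidConfigError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_benign < 0 or self.n_malignant < 0:
            raise InvalidConfigError("phantom counts must be non-negative")
        if not 0.0 <= self.irregularity <= 1.0:
            raise InvalidConfigError(f"irregularity must be in [0, 1], got {self.irregularity}")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth lesion parameters of one phantom."""

    center: Tuple[float, float]
    radius: float
    spicule_count: int
    roughness: float


@dataclass(frozen=True)
class PhantomImage:
    image: GrayImage
    label: int  # 0 = benign, 1 = malignant
    truth: PhantomTruth


def _boundary_radius(theta: np.ndarray, base_radius: float, label: int,
                     irregularity: float, n_spicules: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Lesion boundary radius r(theta) for one phantom."""
    r = np.full_like(theta, base_radius, dtype=float)
    if label == 1 and irregularity > 0:
        # low-order lobulation
        for order in (2, 3, 5):
            amp = irregularity * base_radius * 0.18 * rng.uniform(0.5, 1.0)
            r += amp * np.cos(order * theta + rng.uniform(0, 2 * np.pi))
        # narrow spicule rays
        phases = rng.uniform(0, 2 * np.pi, size=n_spicules)
        widths = rng.uniform(0.05, 0.12, size=n_spicules)
        lengths = rng.uniform(0.6, 1.2, size=n_spicules) * irregularity * base_radius
        for phase, width, length in zip(phases, widths, lengths):
            d = np.angle(np.exp(1j * (theta - phase)))
            r += length * np.exp(-0.5 * (d / width) ** 2)
    return np.maximum(r, 1.0)


def generate_phantom(cfg: PhantomConfig, label: int,
                     seed: Optional[int] = None) -> PhantomImage:
    """One synthetic phantom, fully deterministic per (cfg, label, seed)."""
    if label not in (0, 1):
        raise InvalidConfigError(f"label must be 0 (benign) or 1 (malignant), got {label}")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, label, int(seed)]))
    S = cfg.image_size
    scale = S / 128.0
    yy, xx = np.mgrid[0:S, 0:S].astype(float)

    # elliptical breast region against a dark background
    cy, cx = S * 0.5, S * 0.42
    ay, ax = S * 0.46, S * 0.40
    breast = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    # fibroglandular texture: smoothed white noise, mid-gray base
    texture = rng.normal(0.0, 1.0, size=(S, S))
    texture = gaussian_filter(texture, sigma=cfg.background_texture_scale * scale,
                              mode="reflect")
    std = texture.std()
    if std > 0:
        texture = texture / std
    base = 90.0 + 18.0 * texture

    # lesion placement well inside the breast region
    margin = cfg.benign_radius_range[1] * 2.2 * scale
    while True:
        ly = rng.uniform(cy - ay + margin, cy + ay - margin)
        lx = rng.uniform(cx - ax + margin, cx + ax - margin)
        if ((ly - cy) / ay) ** 2 + ((lx - cx) / ax) ** 2 <= 0.55:
            break

    radius = rng.uniform(*cfg.benign_radius_range) * scale
    n_spicules = int(rng.integers(cfg.spicule_count_range[0],
                                  cfg.spicule_count_range[1] + 1))
    theta_grid = np.arctan2(yy - ly, xx - lx)
    rho = np.hypot(yy - ly, xx - lx)

    theta_samples = np.linspace(-np.pi, np.pi, 720, endpoint=False)
    spic_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, label, int(seed), 7]))
    r_samples = _boundary_radius(theta_samples, radius, label, cfg.irregularity,
                                 n_spicules, spic_rng)
    # evaluate the same boundary at every pixel angle by lookup
    idx = np.clip(((theta_grid + np.pi) / (2 * np.pi) * 720).astype(int), 0, 719)
    r_at_pixel = r_samples[idx]

    # soft radial intensity profile ending at the (angle-dependent) boundary
    profile = np.exp(-0.5 * (rho / (0.6 * r_at_pixel)) ** 2)
    lesion = cfg.contrast * profile

    img = np.where(breast, base + lesion, 12.0)
    img = img + rng.normal(0.0, cfg.noise_sigma, size=(S, S))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    roughness = float(r_samples.std() / r_samples.mean())
    truth = PhantomTruth(center=(float(ly), float(lx)), radius=float(radius),
                         spicule_count=n_spicules if label == 1 else 0,
                         roughness=roughness)
    return PhantomImage(image=GrayImage(img), label=label, truth=truth)


def imbalanced_counts(total: int,
                      ratio: Tuple[int, int] = PAPER_CLASS_RATIO) -> Tuple[int, int]:
    """Split ``total`` into (benign, malignant) at the source-data proportions."""
    if total < 1:
        raise InvalidConfigError("total must be >= 1")
    frac_benign = ratio[0] / (ratio[0] + ratio[1])
    n_benign = int(round(total * frac_benign))
    n_benign = min(max(n_benign, 0), total)
    return n_benign, total - n_benign


def generate_dataset(
    cfg: PhantomConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> LabeledDataset:
    """Generate ``n_benign`` + ``n_malignant`` phantoms as a labeled dataset.

    With ``out_dir`` the images are additionally written as PNGs into
    ``benign/`` and ``malignant/`` subfolders (loadable by
    :func:`mammofusion.trainer.load_dataset`) together with a ``truth.csv``
    sidecar of ground-truth lesion parameters.
    """
    if cfg.n_benign + cfg.n_malignant < 1:
        raise InvalidConfigError("at least one phantom must be requested")
    items = []
    truths: List[Tuple[str, int, PhantomTruth]] = []
    for label, count in ((0, cfg.n_benign), (1, cfg.n_malignant)):
        for k in range(count):
            ph = generate_phantom(cfg, label=label, seed=k)
            name = f"{'benign' if label == 0 else 'malignant'}/{k:05d}.png"
            items.append((name, ph.image.pixels.astype(np.uint8), label))
            truths.append((name, label, ph.truth))

    if out_dir is not None:
        out_dir = Path(out_dir)
        for name, arr, _ in items:
            path = out_dir / name
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(arr).save(path)
        with open(out_dir / "truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["path", "label", "center_y", "center_x", "radius",
                 "spicule_count", "roughness"]
            )
            for name, label, t in truths:
                writer.writerow(
                    [name, "benign" if label == 0 else "malignant",
                     f"{t.center[0]:.3f}", f"{t.center[1]:.3f}", f"{t.radius:.3f}",
                     t.spicule_count, f"{t.roughness:.5f}"]
                )
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            for name, label, _ in truths:
                writer.writerow([name, "benign" if label == 0 else "malignant"])

    return LabeledDataset(items=items)
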