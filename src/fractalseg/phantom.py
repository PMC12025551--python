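"""Synthetic axial T2-weighted cervical-cord slice generator.

Each phantom slice emulates the salient features of an axial T2-w MR
slice of the cervical spine at the cord level: a dark-ish tissue
background, a bright cerebrospinal-fluid (CSF) annulus, a darker
elliptical cord inside it (whose interior is the cross-sectional-area
ground truth), and zero or more small hyperintense lesion blobs fully
inside the cord (the lesion ground truth).  A smooth multiplicative
bias field and additive noise model scanner imperfections.

Default geometry mirrors the imaging series the model family was
developed on: 320 x 250 pixel frames in which the cord occupies a small
fraction of the field of view, with cervical-cord-scale semi-axes
(anteroposterior ~3-5 mm, transverse ~4-6.5 mm at 1 mm isotropic
spacing) and lesions of 1-3 mm radius.  All draws are deterministic in
(seed, index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .data_io import ImageSlice, SamplePair, save_pair, write_manifest
from .metrics import BinaryMask

__all__ = ["PhantomParams", "generate_slice", "generate_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of the slice generator.

    Intensities follow T2-w contrast ordering: background < cord < CSF
    and cord < lesion (CSF bright, lesions hyperintense relative to
    cord parenchyma).
    """

    image_size: tuple[int, int] = (320, 250)
    spacing: tuple[float, float] = (1.0, 1.0)
    # cord ellipse semi-axes in mm (row = anteroposterior, col = transverse)
    cord_semi_axis_row_mm: tuple[float, float] = (3.0, 5.0)
    cord_semi_axis_col_mm: tuple[float, float] = (4.0, 6.5)
    center_jitter_px: int = 12
    csf_ring_mm: tuple[float, float] = (2.0, 4.0)
    lesion_poisson_mean: float = 1.5
    lesion_radius_mm: tuple[float, float] = (0.8, 2.5)
    lesion_eccentricity: float = 0.5
    lesion_margin_px: int = 1
    intensity_background: float = 0.20
    intensity_csf: float = 0.85
    intensity_cord: float = 0.45
    intensity_lesion: float = 0.70
    noise_sigma: float = 0.03
    noise_model: str = "gaussian"
    bias_amplitude: float = 0.10
    seed: int = 7

    def __post_init__(self):
        if not (self.intensity_background < self.intensity_cord < self.intensity_csf):
            raise ValueError("T2-w ordering requires background < cord < CSF")
        if not self.intensity_cord < self.intensity_lesion:
            raise ValueError("lesions must be hyperintense relative to cord")
        if self.lesion_radius_mm[1] >= self.cord_semi_axis_row_mm[0]:
            raise ValueError("max lesion radius must stay below the cord minor semi-axis")
        for rng_pair in (self.cord_semi_axis_row_mm, self.cord_semi_axis_col_mm,
                         self.csf_ring_mm, self.lesion_radius_mm):
            if rng_pair[0] <= 0 or rng_pair[1] < rng_pair[0]:
                raise ValueError(f"invalid range {rng_pair}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def _ellipse_mask(shape, center, semi_axes, angle, spacing) -> np.ndarray:
    rows, cols = np.mgrid[: shape[0], : shape[1]].astype(float)
    dr = (rows - center[0]) * spacing[0]
    dc = (cols - center[1]) * spacing[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    """Multiplicative bias: a random coarse grid, bilinearly upsampled."""
    coarse = rng.uniform(-1.0, 1.0, size=(4, 4))
    smooth = resize(coarse, shape, order=1, mode="edge", anti_aliasing=False)
    return 1.0 + amplitude * smooth


def generate_slice(p: PhantomParams, index: int = 0) -> SamplePair:
    """Render one phantom slice; deterministic in (p.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), int(index)]))
    h, w = p.image_size
    sp = p.spacing

    center = (
        h / 2 + rng.integers(-p.center_jitter_px, p.center_jitter_px + 1),
        w / 2 + rng.integers(-p.center_jitter_px, p.center_jitter_px + 1),
    )
    a = rng.uniform(*p.cord_semi_axis_row_mm)
    b = rng.uniform(*p.cord_semi_axis_col_mm)
    angle = rng.uniform(-np.pi / 8, np.pi / 8)
    cord = _ellipse_mask((h, w), center, (a, b), angle, sp)
    ring = rng.uniform(*p.csf_ring_mm)
    csf = _ellipse_mask((h, w), center, (a + ring, b + ring), angle, sp) & ~cord

    # lesions must sit fully inside the cord with a safety margin
    margin_mm = p.lesion_margin_px * max(sp)
    lesion = np.zeros((h, w), dtype=bool)
    n_lesions = int(rng.poisson(p.lesion_poisson_mean))
    lesion_failed = False
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(25):
            r1 = rng.uniform(*p.lesion_radius_mm)
            ecc = rng.uniform(0, p.lesion_eccentricity)
            r2 = r1 * (1 - ecc)
            lang = rng.uniform(0, np.pi)
            # candidate center inside the shrunken cord ellipse
            t = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1))
            lr = center[0] + rho * max(a - r1 - margin_mm, 0.1) * np.cos(t) / sp[0]
            lc = center[1] + rho * max(b - r1 - margin_mm, 0.1) * np.sin(t) / sp[1]
            cand = _ellipse_mask((h, w), (lr, lc), (r1, r2), lang, sp)
            inner = _ellipse_mask((h, w), center, (a - margin_mm, b - margin_mm), angle, sp)
            if cand.any() and not (cand & ~inner).any():
                lesion |= cand
                placed = True
                break
        if not placed:
            lesion_failed = True

    img = np.full((h, w), p.intensity_background, dtype=np.float64)
    img[csf] = p.intensity_csf
    img[cord] = p.intensity_cord
    img[lesion] = p.intensity_lesion
    if p.bias_amplitude > 0:
        img *= _smooth_field(rng, (h, w), p.bias_amplitude)
    if p.noise_sigma > 0:
        if p.noise_model == "gaussian":
            img = img + rng.normal(0, p.noise_sigma, size=(h, w))
        else:  # Rician: magnitude of a complex signal with Gaussian noise
            re = img + rng.normal(0, p.noise_sigma, size=(h, w))
            im = rng.normal(0, p.noise_sigma, size=(h, w))
            img = np.hypot(re, im)

    sid = f"phantom_{index:04d}"
    return SamplePair(
        image=ImageSlice(img.astype(np.float32), sp, sid, "synthetic"),
        csa_mask=BinaryMask(cord.astype(np.uint8), sp),
        lesion_mask=BinaryMask(lesion.astype(np.uint8), sp),
        meta={"n_lesions_drawn": n_lesions, "lesion_placement_failed": lesion_failed,
              "cord_semi_axes_mm": (a, b)},
    )


def generate_dataset(
    p: PhantomParams,
    n: int = 231,
    out_dir: str | Path | None = None,
    fmt: str = "png",
) -> tuple[list[SamplePair], "pd.DataFrame"]:
    """Generate ``n`` phantom pairs with independent geometry draws.

    When ``out_dir`` is given, images and masks are written there along
    with a ``manifest.csv`` (id + file paths).  Returns the pairs and
    the manifest frame.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = [generate_slice(p, i) for i in range(n)]
    rows = []
    if out_dir is not None:
        for pair in pairs:
            rows.append(save_pair(pair, out_dir, fmt=fmt))
        manifest = write_manifest(rows, Path(out_dir) / "manifest.csv")
    else:
        manifest = pd.DataFrame(
            {"id": [pair.identifier for pair in pairs],
             "has_lesion": [bool(pair.lesion_mask.volume) for pair in pairs],
             "csa_px": [pair.csa_mask.volume for pair in pairs]}
        )
    return pairs, manifest
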