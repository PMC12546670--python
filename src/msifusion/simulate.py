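"""Synthetic paired spectral/image data with the statistical structure of a
multi-variety NIR seed-phenotyping study.

The generators emulate three acquisition products:

* per-grain NIR reflectance spectra (886-1735.34 nm, 512 bands) built from a
  smooth baseline minus class-specific Gaussian absorption dips near
  920/980/1030/1130/1230/1480 nm, with inflated noise on the first 9 and
  last 32 bands;
* RGB microscope grain images: one elliptical grain with class-dependent
  hue, shape and speckle on a textured non-black background, with optional
  dark-spot defects, plus a ground-truth foreground mask;
* raw-intensity hypercubes of a 5 x 5 grain layout together with the
  white/dark reference frames, constructed so that black/white correction
  followed by ROI extraction recovers the generating spectra.

A "complementary" multimodal design splits class identity across the two
modalities (spectral identity = label // 2, visual identity = label % 2), so
neither branch alone can separate all classes but their fusion can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .hsi import DEFAULT_END_NM, DEFAULT_START_NM, WavelengthGrid

__all__ = [
    "EDGE_HEAD_BANDS", "EDGE_TAIL_BANDS", "DIP_SIGMA_NM",
    "SpectralSimConfig", "ImageSimConfig", "CubeSimConfig",
    "HypercubeSim", "MultiModalDataset",
    "generate_spectra", "class_mean_spectra", "generate_grain_image",
    "generate_hypercube", "generate_multimodal_dataset",
    "write_spectra_csv",
]

# Low-SNR detector regions whose noise is inflated by the generator; they
# motivate screening the first 9 and last 32 bands downstream.
EDGE_HEAD_BANDS = 9
EDGE_TAIL_BANDS = 32
# Absorption dips are Gaussian in wavelength with a fixed 15 nm width.
DIP_SIGMA_NM = 15.0

DEFAULT_PEAKS_NM = (920.0, 980.0, 1030.0, 1130.0, 1230.0, 1480.0)
# Relative dip-depth template (moisture / starch / carbohydrate-fat / protein
# bands); per-class profiles rescale it with Dirichlet weights so varieties
# share the overall trend but differ regionally.
DEPTH_TEMPLATE = (0.12, 0.10, 0.15, 0.08, 0.10, 0.18)


@dataclass
class SpectralSimConfig:
    n_classes: int = 12
    n_per_class: int = 300
    n_bands: int = 512
    wavelength_start: float = DEFAULT_START_NM
    wavelength_end: float = DEFAULT_END_NM
    peak_centers: tuple = DEFAULT_PEAKS_NM
    class_peak_depths: np.ndarray | None = None  # (n_classes, n_peaks)
    baseline_level: float = 0.55
    noise_sd: float = 0.01
    edge_noise_sd: float | None = None           # default 10 x noise_sd
    seed: int = 0

    def __post_init__(self):
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength_end must exceed wavelength_start")
        if self.n_bands < EDGE_HEAD_BANDS + EDGE_TAIL_BANDS:
            raise ValueError(
                f"n_bands must be at least {EDGE_HEAD_BANDS + EDGE_TAIL_BANDS} "
                "to place the noisy edge-band regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.edge_noise_sd is None:
            self.edge_noise_sd = 10.0 * self.noise_sd
        if self.edge_noise_sd < 0:
            raise ValueError("edge_noise_sd must be non-negative")
        for c in self.peak_centers:
            if not (self.wavelength_start <= c <= self.wavelength_end):
                raise ValueError(f"peak center {c} nm outside wavelength range")
        if self.class_peak_depths is None:
            self.class_peak_depths = self._default_depths()
        self.class_peak_depths = np.asarray(self.class_peak_depths, float)
        if self.class_peak_depths.shape != (self.n_classes, len(self.peak_centers)):
            raise ValueError("class_peak_depths must be (n_classes, n_peaks)")
        if (self.class_peak_depths < 0).any():
            raise ValueError("dip depths must be non-negative")

    def _default_depths(self):
        n_peaks = len(self.peak_centers)
        template = np.asarray(DEPTH_TEMPLATE[:n_peaks] if n_peaks <= len(DEPTH_TEMPLATE)
                              else (0.12,) * n_peaks, float)
        rng = np.random.default_rng(self.seed)
        w = rng.dirichlet(np.full(n_peaks, 1.5), size=self.n_classes)
        return template * w * n_peaks  # mean scale 1 per peak

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.wavelength_start, self.wavelength_end,
                              self.n_bands)


def _baseline(cfg: SpectralSimConfig) -> np.ndarray:
    wl = cfg.grid.wavelengths
    frac = (wl - cfg.wavelength_start) / (cfg.wavelength_end - cfg.wavelength_start)
    return cfg.baseline_level + 0.05 * np.sin(np.pi * frac)


def class_mean_spectra(cfg: SpectralSimConfig) -> np.ndarray:
    """Noiseless class prototypes, shape (n_classes, n_bands)."""
    wl = cfg.grid.wavelengths
    dips = np.zeros((cfg.n_classes, cfg.n_bands))
    for p, center in enumerate(cfg.peak_centers):
        shape = np.exp(-0.5 * ((wl - center) / DIP_SIGMA_NM) ** 2)
        dips += cfg.class_peak_depths[:, p:p + 1] * shape[None, :]
    return _baseline(cfg)[None, :] - dips


def _add_noise(spectra, cfg, rng):
    noise = rng.standard_normal(spectra.shape) * cfg.noise_sd
    edge = rng.standard_normal(spectra.shape)
    noise[..., :EDGE_HEAD_BANDS] += edge[..., :EDGE_HEAD_BANDS] * cfg.edge_noise_sd
    noise[..., -EDGE_TAIL_BANDS:] += edge[..., -EDGE_TAIL_BANDS:] * cfg.edge_noise_sd
    return spectra + noise


def generate_spectra(cfg: SpectralSimConfig):
    """Balanced labeled spectra: ``(X, y)`` with X of shape (N, n_bands).

    Samples are grouped by class: exactly ``n_per_class`` per class, in label
    order.  Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    means = class_mean_spectra(cfg)
    y = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    X = _add_noise(means[y], cfg, rng)
    return X.astype(np.float32), y


# -- microscope images -----------------------------------------------------

@dataclass
class ImageSimConfig:
    n_classes: int = 12
    canvas_size: int = 64
    class_hue: np.ndarray | None = None
    class_axis_ratio: np.ndarray | None = None
    class_speckle_density: np.ndarray | None = None
    defect_probability: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.canvas_size < 64:
            raise ValueError("canvas_size must be at least 64 pixels")
        if not 0.0 <= self.defect_probability <= 1.0:
            raise ValueError("defect_probability must be in [0, 1]")
        n = self.n_classes
        if self.class_hue is None:
            self.class_hue = np.linspace(0.0, 0.32, n)
        if self.class_axis_ratio is None:
            self.class_axis_ratio = np.linspace(0.55, 0.88, n)
        if self.class_speckle_density is None:
            self.class_speckle_density = np.linspace(0.02, 0.14, n)
        for name in ("class_hue", "class_axis_ratio", "class_speckle_density"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per class")
            setattr(self, name, arr)
        if ((self.class_speckle_density < 0) | (self.class_speckle_density > 1)).any():
            raise ValueError("speckle densities are probabilities in [0, 1]")


def generate_grain_image(label: int, cfg: ImageSimConfig, seed: int,
                         return_geometry: bool = False):
    """One grain image plus its ground-truth foreground mask.

    Returns ``(image, mask)``: uint8 H x W x 3 and bool H x W.  The grain is
    an ellipse with class-dependent hue/aspect/speckle on a textured gray
    background; with probability ``defect_probability`` one or two dark
    spots are stamped inside the grain.  With ``return_geometry=True`` a
    third element carries the generating ellipse parameters
    (center, semi-axes, angle).
    """
    if not 0 <= label < cfg.n_classes:
        raise ValueError(f"label {label} outside 0..{cfg.n_classes - 1}")
    rng = np.random.default_rng((cfg.seed, int(label), int(seed)))
    s = cfg.canvas_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)

    # textured, clearly non-black background
    bg = 58.0 + 10.0 * np.sin(2 * np.pi * xx / 23.0) * np.cos(2 * np.pi * yy / 31.0)
    bg = bg + rng.standard_normal((s, s)) * 5.0
    img = np.repeat(bg[:, :, None], 3, axis=2)
    img[:, :, 2] += 6.0  # slight blue cast so background is not pure gray

    # ellipse geometry
    cy = s / 2 + rng.uniform(-3, 3)
    cx = s / 2 + rng.uniform(-3, 3)
    a = 0.30 * s * rng.uniform(0.95, 1.05)
    b = a * cfg.class_axis_ratio[label]
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    r2 = (xr / a) ** 2 + (yr / b) ** 2
    mask = r2 <= 1.0

    # grain shading: class hue, radial value falloff, per-pixel texture
    val = 0.72 - 0.25 * r2
    val = val + rng.standard_normal((s, s)) * 0.02
    hsv = np.stack([np.full((s, s), cfg.class_hue[label]),
                    np.full((s, s), 0.55),
                    np.clip(val, 0.05, 1.0)], axis=2)
    grain_rgb = hsv2rgb(hsv) * 255.0

    speckle = rng.random((s, s)) < cfg.class_speckle_density[label]
    grain_rgb[speckle] *= 0.45

    img[mask] = grain_rgb[mask]

    if rng.random() < cfg.defect_probability:
        inside = np.argwhere(r2 <= 0.5)  # keep defects well inside the grain
        for _ in range(rng.integers(1, 3)):
            py, px = inside[rng.integers(len(inside))]
            rad = max(2.0, 0.04 * s)
            spot = (yy - py) ** 2 + (xx - px) ** 2 <= rad ** 2
            img[spot & mask] = 18.0

    img = np.clip(img, 0, 255).astype(np.uint8)
    if return_geometry:
        return img, mask, {"center": (cy, cx), "semi_axes": (a, b),
                           "angle": theta}
    return img, mask


# -- hypercubes ------------------------------------------------------------

@dataclass
class CubeSimConfig:
    grid_rows: int = 5
    grid_cols: int = 5
    grain_radius_px: int = 10
    row_jitter_px: int = 2
    col_jitter_px: int = 2
    speck_count: int = 0
    speck_area_px: int = 20
    background_level: float = 0.04
    cell_px: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_px is None:
            self.cell_px = 2 * self.grain_radius_px + 16
        min_sep = self.cell_px - 2 * max(self.row_jitter_px, self.col_jitter_px)
        if min_sep <= 2 * self.grain_radius_px:
            raise ValueError(
                "grains may overlap: cell pitch minus jitter does not exceed "
                "the grain diameter")


@dataclass
class HypercubeSim:
    """A simulated acquisition: raw cube, references, and ground truth."""

    raw: np.ndarray                 # (H, W, B) raw intensity
    white: np.ndarray               # (W, B) per-column white reference
    dark: np.ndarray                # (W, B) per-column dark current
    reflectance: np.ndarray         # (H, W, B) generating reflectance
    labels: np.ndarray              # (H, W) int map: 0 bg, 1..N grains, -1 specks
    truth: pd.DataFrame             # per-grain geometry and class
    grid: WavelengthGrid
    spectral_cfg: SpectralSimConfig
    cube_cfg: CubeSimConfig


def generate_hypercube(cube_cfg: CubeSimConfig, classes,
                       spectral_cfg: SpectralSimConfig) -> HypercubeSim:
    """Simulate one raw hypercube of a grain grid plus reference frames.

    ``classes`` assigns a spectral class to each grid cell in raster order
    (row-major, length grid_rows * grid_cols).  Grain disks carry their
    class prototype scaled into raw-intensity space as
    ``raw = dark + R * (white - dark)``, so correction is exactly invertible
    on noiseless data.  ``speck_count`` sub-threshold specks with grain-like
    reflectance are embedded between grains.
    """
    classes = np.asarray(classes, int)
    n_cells = cube_cfg.grid_rows * cube_cfg.grid_cols
    if classes.shape != (n_cells,):
        raise ValueError(f"need one class per grid cell ({n_cells})")
    if classes.max() >= spectral_cfg.n_classes or classes.min() < 0:
        raise ValueError("cell class outside the spectral config's class set")

    rng = np.random.default_rng(cube_cfg.seed)
    cell, r = cube_cfg.cell_px, cube_cfg.grain_radius_px
    H = cube_cfg.grid_rows * cell
    W = cube_cfg.grid_cols * cell
    B = spectral_cfg.n_bands

    centers = []
    for i in range(cube_cfg.grid_rows):
        for j in range(cube_cfg.grid_cols):
            cy = i * cell + cell // 2 + rng.integers(-cube_cfg.row_jitter_px,
                                                     cube_cfg.row_jitter_px + 1)
            cx = j * cell + cell // 2 + rng.integers(-cube_cfg.col_jitter_px,
                                                     cube_cfg.col_jitter_px + 1)
            centers.append((cy, cx))
    centers = np.array(centers, float)
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if (d2 < (2 * r) ** 2).any():
        raise ValueError("grain placements overlap after jitter; reject config")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    labels = np.zeros((H, W), int)
    rows = []
    for gid, ((cy, cx), cls) in enumerate(zip(centers, classes), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        labels[disk] = gid
        i, j = divmod(gid - 1, cube_cfg.grid_cols)
        rows.append({
            "grain_id": gid, "row": i, "col": j, "raster_index": gid - 1,
            "class": int(cls), "centroid_y": float(yy[disk].mean()),
            "centroid_x": float(xx[disk].mean()), "area": int(disk.sum()),
        })
    truth = pd.DataFrame(rows)

    means = class_mean_spectra(spectral_cfg)
    speck_profile = means.mean(axis=0)
    speck_r = max(1.0, np.sqrt(cube_cfg.speck_area_px / np.pi))
    placed = 0
    attempts = 0
    while placed < cube_cfg.speck_count and attempts < 1000:
        attempts += 1
        sy = rng.uniform(speck_r + 1, H - speck_r - 1)
        sx = rng.uniform(speck_r + 1, W - speck_r - 1)
        dist = np.sqrt(((centers - [sy, sx]) ** 2).sum(axis=1))
        if (dist < r + speck_r + 3).any():
            continue
        spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= speck_r ** 2
        if (labels[spot] != 0).any():
            continue
        labels[spot] = -1
        placed += 1
    if placed < cube_cfg.speck_count:
        raise ValueError("could not place all specks without touching grains")

    refl = np.full((H, W, B), cube_cfg.background_level, np.float32)
    for row in rows:
        refl[labels == row["grain_id"]] = means[row["class"]].astype(np.float32)
    refl[labels == -1] = speck_profile.astype(np.float32)
    refl = _add_noise(refl, spectral_cfg, rng).astype(np.float32)
    np.clip(refl, 0.0, None, out=refl)

    cols = np.arange(W)
    dark = (100.0 + 3.0 * np.sin(2 * np.pi * cols / W))[:, None] \
        + np.zeros((1, B))
    white = (3000.0 + 80.0 * np.sin(2 * np.pi * cols / W))[:, None] \
        + 40.0 * np.linspace(0, 1, B)[None, :]
    raw = dark[None, :, :] + refl * (white - dark)[None, :, :]

    return HypercubeSim(raw=raw.astype(np.float32),
                        white=white.astype(np.float32),
                        dark=dark.astype(np.float32),
                        reflectance=refl, labels=labels, truth=truth,
                        grid=spectral_cfg.grid, spectral_cfg=spectral_cfg,
                        cube_cfg=cube_cfg)


# -- paired multimodal datasets -------------------------------------------

@dataclass
class MultiModalDataset:
    spectra: np.ndarray             # (N, n_bands) float32 reflectance
    images: np.ndarray              # (N, H, W, 3) uint8
    masks: np.ndarray               # (N, H, W) bool ground-truth foreground
    labels: np.ndarray              # (N,) int class ids
    spectral_groups: np.ndarray     # per-sample spectral identity
    visual_groups: np.ndarray       # per-sample visual identity
    grid: WavelengthGrid

    def __len__(self):
        return len(self.labels)


def generate_multimodal_dataset(n_classes=12, n_per_class=300,
                                design="complementary", n_bands=512,
                                canvas_size=64, noise_sd=0.0,
                                defect_probability=0.0, seed=0):
    """Paired (spectrum, image, label) records.

    ``design='complementary'`` splits class identity across modalities:
    spectra follow ``label // 2`` (half as many spectral prototypes as
    classes) and images follow ``label % 2`` (two visual prototypes), so a
    fused model can reach perfect accuracy while either branch alone is
    capped (1/2 spectrally, 2/n_classes visually).  ``design='redundant'``
    gives every class its own prototype in both modalities.
    """
    if design not in ("complementary", "redundant"):
        raise ValueError("design must be 'complementary' or 'redundant'")
    labels = np.repeat(np.arange(n_classes), n_per_class)
    if design == "complementary":
        if n_classes % 2:
            raise ValueError("complementary design needs an even class count")
        spectral_groups = labels // 2
        visual_groups = labels % 2
        n_spec, n_vis = n_classes // 2, 2
        hues = np.array([0.02, 0.15])           # red-brown vs. yellow
        ratios = np.array([0.55, 0.85])
        speckle = np.array([0.03, 0.12])
    else:
        spectral_groups = labels.copy()
        visual_groups = labels.copy()
        n_spec, n_vis = n_classes, n_classes
        hues = ratios = speckle = None

    spec_cfg = SpectralSimConfig(n_classes=n_spec, n_per_class=1,
                                 n_bands=n_bands, noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    means = class_mean_spectra(spec_cfg)
    spectra = _add_noise(means[spectral_groups], spec_cfg, rng).astype(np.float32)

    img_cfg = ImageSimConfig(n_classes=n_vis, canvas_size=canvas_size,
                             class_hue=hues, class_axis_ratio=ratios,
                             class_speckle_density=speckle,
                             defect_probability=defect_probability, seed=seed)
    images = np.empty((len(labels), canvas_size, canvas_size, 3), np.uint8)
    masks = np.empty((len(labels), canvas_size, canvas_size), bool)
    for i, v in enumerate(visual_groups):
        images[i], masks[i] = generate_grain_image(int(v), img_cfg, seed=i)

    return MultiModalDataset(spectra=spectra, images=images, masks=masks,
                             labels=labels, spectral_groups=spectral_groups,
                             visual_groups=visual_groups, grid=spec_cfg.grid)


def write_spectra_csv(path, X, y, grid: WavelengthGrid | None = None):
    """Spectra table: label column followed by band_0..band_{B-1} columns."""
    X = np.asarray(X)
    cols = [f"band_{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", np.asarray(y))
    if grid is not None:
        header = ",".join(["# wavelengths_nm"]
                          + [f"{w:.4f}" for w in grid.wavelengths])
        with open(path, "w") as fh:
            fh.write(header + "\n")
        df.to_csv(path, mode="a", index=False)
    else:
        df.to_csv(path, index=False)
    return path
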