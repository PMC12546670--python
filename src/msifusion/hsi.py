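"""Hyperspectral preprocessing: reflectance correction, wavelength
bookkeeping, band screening, and ENVI-style cube I/O.

The instrument model is a push-broom NIR line scanner covering
886-1735.34 nm in 512 bands.  Raw intensity cubes are converted to
reflectance with dark-current and white-reference frames; the low-SNR head
and tail of the spectral axis (first 9 and last 32 bands by default) are
screened out before modeling, leaving 471 effective bands.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid", "ReflectanceCube", "BandScreen",
    "black_white_correct", "select_effective_bands",
    "band_index_for_wavelength", "write_envi", "read_envi",
    "write_cube_npz", "read_cube_npz", "export_band_pngs",
]

DEFAULT_START_NM = 886.0
DEFAULT_END_NM = 1735.34
DEFAULT_N_BANDS = 512


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis over ``[start, end]`` nm with ``n_bands`` samples."""

    start: float = DEFAULT_START_NM
    end: float = DEFAULT_END_NM
    n_bands: int = DEFAULT_N_BANDS

    def __post_init__(self):
        if self.n_bands < 2:
            raise ValueError("a wavelength grid needs at least 2 bands")
        if self.end <= self.start:
            raise ValueError("wavelength end must exceed start")

    @property
    def step(self) -> float:
        return (self.end - self.start) / (self.n_bands - 1)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_bands)

    def index_of(self, target_nm: float) -> int:
        """Nearest 0-based band index; ties break toward the lower index."""
        if not (self.start <= target_nm <= self.end):
            raise ValueError(
                f"wavelength {target_nm} nm outside grid "
                f"[{self.start}, {self.end}] nm")
        dist = np.abs(self.wavelengths - target_nm)
        return int(np.argmin(dist))  # argmin returns the first (lower) tie

    def slice(self, lo: int, hi: int) -> "WavelengthGrid":
        w = self.wavelengths[lo:hi]
        return WavelengthGrid(float(w[0]), float(w[-1]), len(w))


@dataclass
class ReflectanceCube:
    """H x W x B reflectance array with its wavelength axis.

    ``provenance`` records correction metadata (clip counts, epsilon, the
    number of white<dark violations).
    """

    values: np.ndarray
    grid: WavelengthGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("cube must be H x W x B")
        if self.values.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.values.shape[2]} bands but the grid has "
                f"{self.grid.n_bands}")
        if not np.isfinite(self.values).all():
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def band(self, index: int) -> np.ndarray:
        return self.values[:, :, index]

    def band_at(self, wavelength_nm: float) -> np.ndarray:
        return self.band(self.grid.index_of(wavelength_nm))


@dataclass(frozen=True)
class BandScreen:
    """Drop noisy head/tail bands (default: first 9 and last 32)."""

    drop_head: int = 9
    drop_tail: int = 32

    def __post_init__(self):
        if self.drop_head < 0 or self.drop_tail < 0:
            raise ValueError("band drops must be non-negative")

    def retained(self, n_bands: int) -> int:
        n = n_bands - self.drop_head - self.drop_tail
        if n <= 0:
            raise ValueError(
                f"screen ({self.drop_head}/{self.drop_tail}) removes all "
                f"{n_bands} bands")
        return n


def _broadcast_frame(frame, shape):
    """Accept full-frame (H,W,B), per-column (W,B), or per-band (B,) references."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape == shape:
        return frame
    if frame.ndim == 2 and frame.shape == shape[1:]:
        return np.broadcast_to(frame[None, :, :], shape)
    if frame.ndim == 1 and frame.shape[0] == shape[2]:
        return np.broadcast_to(frame[None, None, :], shape)
    raise ValueError(
        f"reference frame of shape {frame.shape} is incompatible with cube "
        f"shape {shape}")


def black_white_correct(raw, white, dark, grid=None, epsilon=1e-8):
    """Convert raw intensities to reflectance: R = (raw-dark)/(white-dark+eps).

    ``white``/``dark`` may be full cubes, per-column line-scan frames
    ``(W, B)``, or per-band vectors ``(B,)``.  Negative reflectances are
    clipped to 0 (count recorded); values above 1 are kept, since specular
    highlights are informative for masking.  Pixels where ``white < dark``
    are counted but not fatal.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError("raw cube must be H x W x B")
    white = _broadcast_frame(white, raw.shape)
    dark = _broadcast_frame(dark, raw.shape)
    if grid is None:
        grid = WavelengthGrid(n_bands=raw.shape[2])

    denom = white - dark
    dead = np.all(denom == 0, axis=(0, 1))
    if dead.any():
        raise ValueError(
            f"white and dark references coincide on entire band(s) "
            f"{np.flatnonzero(dead).tolist()}: zero denominator plane")
    inverted = int((denom < 0).sum())

    refl = (raw - dark) / (denom + epsilon)
    n_neg = int((refl < 0).sum())
    n_above_one = int((refl > 1).sum())
    refl = np.clip(refl, 0.0, None)
    return ReflectanceCube(
        refl.astype(np.float32), grid,
        provenance={
            "epsilon": epsilon,
            "clipped_negative": n_neg,
            "above_one": n_above_one,
            "white_below_dark": inverted,
        })


def select_effective_bands(cube: ReflectanceCube, screen: BandScreen) -> ReflectanceCube:
    """Slice out the screened head/tail bands, keeping the grid consistent."""
    n = cube.grid.n_bands
    screen.retained(n)  # validates
    lo, hi = screen.drop_head, n - screen.drop_tail
    prov = dict(cube.provenance)
    prov["band_screen"] = (screen.drop_head, screen.drop_tail)
    return ReflectanceCube(cube.values[:, :, lo:hi], cube.grid.slice(lo, hi), prov)


def band_index_for_wavelength(grid: WavelengthGrid, target_nm: float) -> int:
    return grid.index_of(target_nm)


# -- I/O -------------------------------------------------------------------

def write_envi(path_base: str, cube: ReflectanceCube) -> None:
    """Write ``path_base + '.hdr'`` / ``'.img'`` (BSQ, float32, little-endian)."""
    H, W, B = cube.values.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path_base + ".hdr", "w") as fh:
        fh.write(hdr)
    bsq = np.ascontiguousarray(cube.values.transpose(2, 0, 1).astype("<f4"))
    bsq.tofile(path_base + ".img")


def read_envi(path_base: str) -> ReflectanceCube:
    """Read a header+binary pair written by :func:`write_envi`."""
    with open(path_base + ".hdr") as fh:
        text = fh.read()

    def field_(name, cast=int):
        m = re.search(rf"^{name}\s*=\s*(\S+)", text, re.M)
        if m is None:
            raise ValueError(f"ENVI header missing field {name!r}")
        return cast(m.group(1))

    W, H, B = field_("samples"), field_("lines"), field_("bands")
    if field_("data type") != 4:
        raise ValueError("only float32 (data type 4) ENVI files are supported")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, re.S)
    if m is None:
        raise ValueError("ENVI header missing wavelength block")
    wl = np.array([float(v) for v in m.group(1).replace("\n", " ").split(",")])
    img = os.path.exists(path_base + ".img") and path_base + ".img" or path_base + ".raw"
    data = np.fromfile(img, dtype="<f4").reshape(B, H, W).transpose(1, 2, 0)
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), B)
    return ReflectanceCube(data, grid)


def write_cube_npz(path: str, cube: ReflectanceCube) -> None:
    np.savez_compressed(path, values=cube.values,
                        wavelengths=cube.grid.wavelengths)


def read_cube_npz(path: str) -> ReflectanceCube:
    with np.load(path) as z:
        wl, values = z["wavelengths"], z["values"]
    return ReflectanceCube(values, WavelengthGrid(float(wl[0]), float(wl[-1]), len(wl)))


def export_band_pngs(cube: ReflectanceCube, out_dir: str, bands=None) -> list:
    """Write selected band planes as 8-bit PNGs for visual inspection."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    bands = range(cube.grid.n_bands) if bands is None else bands
    paths = []
    for b in bands:
        plane = cube.band(b)
        lo, hi = plane.min(), plane.max()
        scaled = np.zeros_like(plane) if hi == lo else (plane - lo) / (hi - lo)
        path = os.path.join(out_dir, f"band_{b:04d}.png")
        iio.imwrite(path, (scaled * 255).astype(np.uint8))
        paths.append(path)
    return paths
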