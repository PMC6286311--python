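"""Synthetic hiPSC colony imagery with ground-truth differentiation masks.

Emulates the raw material of a label-free purification run: paired
phase-contrast / fluorescence frames of induced pluripotent stem-cell
colonies in which contiguous patches of cells have spontaneously
differentiated.  The fluorescence channel mimics an rBC2LCN-FITC stain
(bright on undifferentiated pixels, dark on differentiated cells and
background) and is used only to derive training labels; the phase channel
carries the morphological texture signal a classifier must learn.

Coordinate convention (shared by every module): origin at the top-left
pixel center, x rightward, y downward, physical position in µm equals
pixel index times ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

# mask palette
BACKGROUND = 0
UNDIFF = 1
DIFF = 2

# classifier label convention (patch labels / class indices)
LABEL_UNDIFF = 0
LABEL_DIFF = 1

UINT16_MAX = 65535


@dataclass(frozen=True)
class ColonySimParams:
    """Parameters of a synthetic culture field.

    Intensities are on the 16-bit camera scale (0..65535).  The default
    frame geometry is the native 1920x1200 camera raster; the physical
    scale is a configuration choice (default 1 µm/px, i.e. a roughly
    1.9 x 1.2 mm tile of the dish).
    """

    field_width_px: int = 1920
    field_height_px: int = 1200
    pixel_size_um: float = 1.0
    n_colonies: int = 4
    colony_radius_um: tuple[float, float] = (220.0, 420.0)
    differentiated_fraction: float = 0.2
    texture_noise_sd: float = 800.0
    fluor_pos_level: float = 30000.0
    fluor_neg_level: float = 4000.0
    cell_diameter_um: float = 10.0
    cell_density_per_mm2: float = 1500.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.differentiated_fraction <= 1.0:
            raise ValueError("differentiated_fraction must lie in [0, 1]")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be nonnegative")
        lo, hi = self.colony_radius_um
        if not (0 < lo <= hi):
            raise ValueError("colony_radius_um must be a positive (lo, hi) range")
        for level in (self.fluor_pos_level, self.fluor_neg_level):
            if not 0 <= level <= UINT16_MAX:
                raise ValueError("intensity levels must be representable in 16 bits")
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be positive")


@dataclass
class ImageFrame:
    """A single-channel intensity raster with physical pixel size."""

    pixels: np.ndarray  # (H, W) float
    channel: str  # "phase" | "fluorescence"
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.channel not in ("phase", "fluorescence"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Per-pixel ground-truth class: 0 background, 1 undifferentiated, 2 differentiated."""

    labels: np.ndarray  # (H, W) uint8
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.isin(self.labels, [BACKGROUND, UNDIFF, DIFF]).all():
            raise ValueError("labels must be in {0, 1, 2}")


@dataclass
class CellPopulation:
    """Point cells: physical position, diameter, type and viability."""

    x_um: np.ndarray
    y_um: np.ndarray
    diameter_um: np.ndarray
    type: np.ndarray  # "differentiated" | "undifferentiated"
    alive: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.x_um)

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            self.x_um.copy(), self.y_um.copy(), self.diameter_um.copy(),
            self.type.copy(), self.alive.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x_um,
                "y_um": self.y_um,
                "diameter_um": self.diameter_um,
                "type": self.type,
                "alive": self.alive,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellPopulation":
        return cls(
            df["x_um"].to_numpy(float),
            df["y_um"].to_numpy(float),
            df["diameter_um"].to_numpy(float),
            df["type"].to_numpy(str),
            df["alive"].to_numpy(bool),
        )


@dataclass
class PatchSet:
    """Labeled 70x70 crops from the phase channel.

    ``images`` is (n, p, p) float, ``labels`` is (n,) int with
    0 = undifferentiated, 1 = differentiated; ``origins`` holds the
    (row, col) of each crop's top-left pixel in the source frame.
    """

    images: np.ndarray
    labels: np.ndarray
    origins: np.ndarray
    patch_px: int = 70

    def __len__(self) -> int:
        return len(self.labels)

    def concat(self, other: "PatchSet") -> "PatchSet":
        if other.patch_px != self.patch_px:
            raise ValueError("patch sizes differ")
        return PatchSet(
            np.concatenate([self.images, other.images]),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.origins, other.origins]),
            self.patch_px,
        )


# ---------------------------------------------------------------------------
# field generation


def _blob_mask(shape: tuple[int, int], cx: float, cy: float, radius_px: float,
               rng: np.random.Generator, wobble: float = 0.18,
               n_harmonics: int = 5) -> np.ndarray:
    """Rasterize a smooth blob: a circle whose radius is modulated by a
    low-order random Fourier series in polar angle."""
    h, w = shape
    amp = rng.uniform(-wobble, wobble, n_harmonics)
    phase = rng.uniform(0, 2 * np.pi, n_harmonics)
    pad = int(np.ceil(radius_px * (1 + wobble) + 2))
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    mod = np.ones_like(theta)
    for k in range(n_harmonics):
        mod += amp[k] * np.cos((k + 1) * theta + phase[k])
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = r <= radius_px * mod
    return mask


def _diff_subregion(colony: np.ndarray, fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Contiguous differentiated patch covering ``fraction`` of the colony.

    Picks a seed pixel inside the colony and takes the colony pixels whose
    distance to it falls below the fraction-quantile of all such distances,
    so the realized area fraction matches the target up to pixel
    quantization regardless of where the seed lands.
    """
    if fraction <= 0:
        return np.zeros_like(colony)
    if fraction >= 1:
        return colony.copy()
    ys, xs = np.nonzero(colony)
    i = rng.integers(len(ys))
    d2 = (ys - ys[i]) ** 2 + (xs - xs[i]) ** 2
    cutoff = np.quantile(d2, fraction)
    sub = np.zeros_like(colony)
    sub[ys[d2 <= cutoff], xs[d2 <= cutoff]] = True
    return sub


def _band_noise(shape: tuple[int, int], sigma_px: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited by a Gaussian blur."""
    n = rng.standard_normal(shape)
    if sigma_px > 0:
        n = ndimage.gaussian_filter(n, sigma_px)
        n /= max(n.std(), 1e-12)
    return n


def generate_field(
    params: ColonySimParams,
) -> tuple[ImageFrame, ImageFrame, LabelMask, CellPopulation]:
    """Generate one synthetic culture field.

    Returns the phase frame, the fluorescence frame, the ground-truth
    label mask and a matched point-cell population.  Deterministic in
    ``params.seed``: identical params give bit-identical arrays.

    The phase texture is the learnable signal: undifferentiated regions
    are rendered with fine granularity and high local contrast,
    differentiated regions with coarser, flatter texture, and colonies
    carry a bright halo ring at their rim as in phase-contrast optics.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.field_height_px, params.field_width_px
    px = params.pixel_size_um

    labels = np.zeros((h, w), dtype=np.uint8)
    colony_any = np.zeros((h, w), dtype=bool)

    r_lo, r_hi = (r / px for r in params.colony_radius_um)
    colonies: list[np.ndarray] = []
    for _ in range(params.n_colonies):
        radius = rng.uniform(r_lo, r_hi)
        # keep centers inside the frame with some margin; overlap allowed
        cx = rng.uniform(radius * 0.7, w - radius * 0.7)
        cy = rng.uniform(radius * 0.7, h - radius * 0.7)
        blob = _blob_mask((h, w), cx, cy, radius, rng)
        blob &= ~colony_any  # later colonies do not overwrite earlier ones
        if not blob.any():
            continue
        colonies.append(blob)
        colony_any |= blob

    diff_all = np.zeros((h, w), dtype=bool)
    for blob in colonies:
        sub = _diff_subregion(blob, params.differentiated_fraction, rng)
        diff_all |= sub
    labels[colony_any] = UNDIFF
    labels[diff_all] = DIFF

    # --- phase channel -----------------------------------------------------
    phase = np.full((h, w), 12000.0)
    # background: faint smooth mottle
    phase += 600.0 * _band_noise((h, w), 6.0, rng)
    # undifferentiated: fine granular, high-contrast texture
    fine = _band_noise((h, w), 1.0, rng)
    # differentiated: coarse, low-contrast texture, slightly brighter base
    coarse = _band_noise((h, w), 5.0, rng)
    undiff = labels == UNDIFF
    phase[undiff] += 3500.0 * fine[undiff] + 500.0
    phase[diff_all] += 1200.0 * coarse[diff_all] + 2500.0
    # rim halo: bright ring where colony meets background
    interior = ndimage.binary_erosion(colony_any, iterations=3)
    rim = colony_any & ~interior
    phase[rim] += 6000.0
    phase += params.texture_noise_sd * rng.standard_normal((h, w))
    np.clip(phase, 0, UINT16_MAX, out=phase)

    # --- fluorescence channel (rBC2LCN-FITC analog) ------------------------
    fluor = np.full((h, w), params.fluor_neg_level)
    fluor[undiff] = params.fluor_pos_level
    fluor += params.texture_noise_sd * rng.standard_normal((h, w))
    np.clip(fluor, 0, UINT16_MAX, out=fluor)

    # --- point cells: Poisson-sampled inside colony footprints -------------
    colony_area_mm2 = colony_any.sum() * (px / 1000.0) ** 2
    n_cells = int(rng.poisson(params.cell_density_per_mm2 * colony_area_mm2))
    ys, xs = np.nonzero(colony_any)
    xs_c: list[float] = []
    ys_c: list[float] = []
    if n_cells > 0 and len(ys) > 0:
        idx = rng.integers(len(ys), size=n_cells)
        # jitter inside the pixel so positions are continuous
        xs_c = (xs[idx] + rng.uniform(-0.5, 0.5, n_cells)) * px
        ys_c = (ys[idx] + rng.uniform(-0.5, 0.5, n_cells)) * px
    xs_c = np.asarray(xs_c, dtype=float)
    ys_c = np.asarray(ys_c, dtype=float)
    ix = np.clip(np.round(xs_c / px).astype(int), 0, w - 1)
    iy = np.clip(np.round(ys_c / px).astype(int), 0, h - 1)
    ctype = np.where(labels[iy, ix] == DIFF, "differentiated", "undifferentiated")

    pop = CellPopulation(
        x_um=xs_c,
        y_um=ys_c,
        diameter_um=np.full(len(xs_c), params.cell_diameter_um),
        type=ctype.astype(object) if len(xs_c) else np.array([], dtype=object),
        alive=np.ones(len(xs_c), dtype=bool),
    )
    return (
        ImageFrame(phase, "phase", px),
        ImageFrame(fluor, "fluorescence", px),
        LabelMask(labels, px),
        pop,
    )


# ---------------------------------------------------------------------------
# patch extraction


def _window_counts(indicator: np.ndarray, p: int) -> np.ndarray:
    """Count of True pixels in every p x p window (all anchors), via a
    2-D summed-area table."""
    ii = np.zeros((indicator.shape[0] + 1, indicator.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(indicator.astype(np.int64), axis=0), axis=1)
    return ii[p:, p:] - ii[:-p, p:] - ii[p:, :-p] + ii[:-p, :-p]


def extract_patches(
    frame: ImageFrame,
    mask: LabelMask,
    patch_px: int = 70,
    policy: str = "grid_nonoverlap",
    n_random: int = 200,
    purity_threshold: float = 0.8,
    seed: int = 0,
    background_as_undifferentiated: bool = False,
) -> PatchSet:
    """Cut a frame into labeled square patches.

    ``grid_nonoverlap`` tiles the frame with floor(W/p) x floor(H/p)
    disjoint crops anchored at the top-left; ``random`` samples
    ``n_random`` crops, stratified evenly between the two classes where
    both are available.  A patch's label is the majority class of its
    non-background mask pixels, and the patch is kept only if that class
    covers at least ``purity_threshold`` of all its pixels.
    """
    h, w = frame.shape
    if patch_px > h or patch_px > w:
        raise ValueError("patch larger than frame")
    if mask.labels.shape != frame.shape:
        raise ValueError("mask and frame shapes differ")

    lab = mask.labels
    if background_as_undifferentiated:
        lab = np.where(lab == BACKGROUND, UNDIFF, lab)

    n_undiff = _window_counts(lab == UNDIFF, patch_px)
    n_diff = _window_counts(lab == DIFF, patch_px)
    total = patch_px * patch_px
    majority_is_diff = n_diff > n_undiff
    majority_count = np.where(majority_is_diff, n_diff, n_undiff)
    valid = majority_count >= purity_threshold * total

    if policy == "grid_nonoverlap":
        rows = np.arange(0, h - patch_px + 1, patch_px)
        cols = np.arange(0, w - patch_px + 1, patch_px)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        anchors = np.stack([rr.ravel(), cc.ravel()], axis=1)
        keep = valid[anchors[:, 0], anchors[:, 1]]
        anchors = anchors[keep]
    elif policy == "random":
        rng = np.random.default_rng(seed)
        anchors_list = []
        for is_diff_cls, n_target in _split_counts(n_random):
            ok = valid & (majority_is_diff == is_diff_cls)
            ys, xs = np.nonzero(ok)
            if len(ys) == 0:
                continue
            pick = rng.integers(len(ys), size=n_target)
            anchors_list.append(np.stack([ys[pick], xs[pick]], axis=1))
        if not anchors_list:
            raise ValueError("no patch passes the purity filter")
        anchors = np.concatenate(anchors_list)
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if len(anchors) == 0:
        raise ValueError("no patch passes the purity filter")

    images = np.stack(
        [frame.pixels[r : r + patch_px, c : c + patch_px] for r, c in anchors]
    )
    patch_labels = np.where(
        majority_is_diff[anchors[:, 0], anchors[:, 1]], LABEL_DIFF, LABEL_UNDIFF
    )
    return PatchSet(images, patch_labels.astype(np.int64), np.asarray(anchors), patch_px)


def _split_counts(n: int) -> list[tuple[bool, int]]:
    half = n // 2
    return [(False, n - half), (True, half)]


# ---------------------------------------------------------------------------
# disk I/O (16-bit TIFF/PNG images, paletted PNG masks, CSV populations)


def write_image(path: str | Path, frame: ImageFrame) -> None:
    path = Path(path)
    data = np.clip(np.round(frame.pixels), 0, UINT16_MAX).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_image(path: str | Path, channel: str, pixel_size_um: float = 1.0) -> ImageFrame:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    return ImageFrame(np.asarray(data, dtype=np.float64), channel, pixel_size_um)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_mask(path: str | Path, pixel_size_um: float = 1.0) -> LabelMask:
    return LabelMask(np.asarray(iio.imread(Path(path)), dtype=np.uint8), pixel_size_um)


def write_population(path: str | Path, pop: CellPopulation) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_population(path: str | Path) -> CellPopulation:
    return CellPopulation.from_frame(pd.read_csv(path))
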