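"""Synthetic MRI and histology phantoms with known ground truth.

The generators emulate the statistical structure of an orthotopic mammary
tumor cross section carrying iron-laden macrophage deposits:

* MRI side: a ~1 cm tumor disc imaged at 0.1 mm in-plane resolution with a
  low-iron bulk (cancer cells and stroma) and rare compact high-iron deposits
  of a few pixels each, placed in a peripheral margin band.  The multi-echo
  signal follows S(TE) = S0 exp(-TE/T2*) with per-pixel T2* derived from the
  linear R2*-iron relation R2* = m C + b.

* Histology side: a full-resolution section (default 1 um/px) with iron+
  macrophage colonies (~14 cells each) in the same margin band, a diffuse
  background macrophage population, and per-cell M1-like (AIF1) / M2-like
  (CD206) polarization labels drawn at configurable frequencies.

Every generator is deterministic for a fixed configuration + seed, and the
ground truth (iron map, deposit pixel sets, cell tables) is returned
alongside the rendered data so each downstream stage can be validated
against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .exceptions import ConfigurationError
from .histo_spatial import BACKGROUND_CLASS, CELL_CLASS, IRON_CLASS, HistoRaster
from .relaxometry import MGESeries

__all__ = [
    "MRIPhantomConfig",
    "HistoPhantomConfig",
    "GroundTruth",
    "generate_mri_phantom",
    "generate_histo_phantom",
    "render_rgb",
]

DEFAULT_ECHO_TIMES = tuple(3.0 * n for n in range(1, 17))  # 3..48 ms


@dataclass(frozen=True)
class MRIPhantomConfig:
    """Parameters of the synthetic multi-gradient-echo tumor section.

    Defaults mimic the acquisition and tissue regime the pipeline targets:
    256x256 matrix at 0.1 mm pixels, 16 echoes 3 ms apart, a 5 mm-radius
    tumor disc with baseline iron 0.03 +/- 0.01 mg/g (well inside the low
    stratum), and 30 few-pixel deposits at 0.15-0.30 mg/g confined to a
    peripheral margin band.  Calibration constants (m=400 s^-1 per mg/g,
    b=20 s^-1) are stand-ins: the R2*-iron line is a measured input in real
    studies.
    """

    grid_rows: int = 256
    grid_cols: int = 256
    pixel_size: float = 0.1  # mm
    echo_times: tuple = DEFAULT_ECHO_TIMES  # ms
    tumor_radius: float = 50.0  # pixels
    baseline_iron_mean: float = 0.03  # mg/g
    baseline_iron_sd: float = 0.01  # mg/g
    n_deposits: int = 30
    deposit_area_mean: float = 4.0  # pixels
    deposit_iron_lo: float = 0.15  # mg/g
    deposit_iron_hi: float = 0.30  # mg/g
    margin_band: tuple = (0.55, 0.95)  # fractions of tumor_radius
    deposit_min_spacing: float = 4.0  # pixels, center-to-center
    calibration_slope: float = 400.0  # s^-1 per (mg/g)
    calibration_intercept: float = 20.0  # s^-1
    s0: float = 100.0  # signal units
    noise_sd: float = 0.01  # fraction of s0
    rician: bool = False
    seed: int = 0

    def validate(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size == 0:
            raise ConfigurationError("echo_times must not be empty")
        if te[0] <= 0 or np.any(np.diff(te) <= 0):
            raise ConfigurationError("echo_times must be positive, strictly increasing")
        if not (0 <= self.baseline_iron_mean < self.deposit_iron_lo
                <= self.deposit_iron_hi <= 0.3):
            raise ConfigurationError(
                "require 0 <= baseline_iron_mean < deposit_iron_lo "
                "<= deposit_iron_hi <= 0.3"
            )
        if self.n_deposits < 0:
            raise ConfigurationError("n_deposits must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.tumor_radius <= 0:
            raise ConfigurationError("tumor_radius must be positive")
        lo, hi = self.margin_band
        if not 0 <= lo < hi <= 1:
            raise ConfigurationError("margin_band fractions must satisfy 0<=lo<hi<=1")
        tumor_area = math.pi * self.tumor_radius**2
        if self.n_deposits * self.deposit_area_mean > 0.5 * tumor_area:
            raise ConfigurationError("requested deposit area exceeds tumor capacity")


@dataclass(frozen=True)
class HistoPhantomConfig:
    """Parameters of the synthetic stained section.

    The section is rendered as a class-label raster (background / macrophage
    / iron+ pixel) standing in for a Prussian-blue + nuclear-fast-red stain.
    Deposits are multicellular iron+ macrophage colonies (cell count per
    colony ~ Poisson(``cells_per_deposit_mean``), default 14) confined to a
    peripheral margin band of the tumor disc; background macrophages are
    spread over the whole disc and are iron+ with ``p_iron_background``
    (default 0.41%, the endogenous baseline).  Polarization flags: with
    probability ``p_double`` a macrophage is AIF1+CD206+; otherwise it is
    single-positive AIF1+ with relative weight ``p_m1`` vs CD206+ with
    ``p_m2`` (defaults 0.42/0.58, the control-cohort split).
    """

    section_rows: int = 4000
    section_cols: int = 4000
    microns_per_pixel: float = 1.0
    tumor_radius_um: Optional[float] = None  # default: 0.45 * min section extent
    n_deposits: int = 20
    cells_per_deposit_mean: float = 14.0
    n_background_macrophages: int = 5000
    p_m1: float = 0.42
    p_m2: float = 0.58
    p_double: float = 0.0
    p_iron_background: float = 0.0041
    deposit_margin_band: tuple = (0.60, 0.95)  # fractions of tumor radius
    deposit_min_spacing_um: float = 500.0
    colony_sigma_um: float = 15.0  # spread of cell centroids around colony center
    cell_radius_um: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_m1", "p_m2", "p_double", "p_iron_background"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.p_m1 + self.p_m2 <= 0:
            raise ConfigurationError("p_m1 + p_m2 must be positive")
        if self.cells_per_deposit_mean <= 0:
            raise ConfigurationError("cells_per_deposit_mean must be positive")
        if self.n_deposits < 0 or self.n_background_macrophages < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.microns_per_pixel <= 0:
            raise ConfigurationError("microns_per_pixel must be positive")
        lo, hi = self.deposit_margin_band
        if not 0 <= lo < hi <= 1:
            raise ConfigurationError("margin band fractions must satisfy 0<=lo<hi<=1")
        radius = self.resolved_tumor_radius_um()
        extent = min(self.section_rows, self.section_cols) * self.microns_per_pixel
        if radius * 2 > extent:
            raise ConfigurationError("tumor disc does not fit in the section")
        # disks of radius s/2 around pairwise-spaced centers are disjoint and
        # fit inside the annulus expanded by s/2: a cheap feasibility bound
        half = self.deposit_min_spacing_um / 2.0
        r_in = max(0.0, lo * radius - half)
        r_out = hi * radius + half
        capacity = math.pi * (r_out**2 - r_in**2)
        needed = self.n_deposits * math.pi * half**2
        if self.n_deposits and needed > capacity:
            raise ConfigurationError(
                "section too small for the requested number of spaced deposits"
            )

    def resolved_tumor_radius_um(self) -> float:
        if self.tumor_radius_um is not None:
            return self.tumor_radius_um
        return 0.45 * min(self.section_rows, self.section_cols) * self.microns_per_pixel


@dataclass
class GroundTruth:
    """Construction-time truth shared by both phantoms.

    ``deposit_table`` has one row per deposit (id, centroid, pixel/cell
    count, iron level); ``deposit_pixels`` lists every deposit pixel
    (MRI phantom only); ``cell_table`` lists every cell with marker flags
    (histology phantom only).  Deposit pixel sets are disjoint and lie
    inside ``tumor_mask``.
    """

    iron_map: Optional[np.ndarray] = None
    tumor_mask: Optional[np.ndarray] = None
    deposit_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    deposit_pixels: pd.DataFrame = field(default_factory=pd.DataFrame)
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    radius: float,
    band: tuple[float, float],
    min_spacing: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample n points uniformly over an annulus with min spacing."""
    lo, hi = band
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"could not place {n} deposits with spacing {min_spacing}"
            )
        attempts += 1
        r = radius * math.sqrt(rng.uniform(lo**2, hi**2))
        theta = rng.uniform(0, 2 * math.pi)
        y = center[0] + r * math.sin(theta)
        x = center[1] + r * math.cos(theta)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_spacing**2 for py, px in placed):
            placed.append((y, x))
    return np.array(placed).reshape(n, 2)


def _grow_blob(
    rng: np.random.Generator,
    start: tuple[int, int],
    target: int,
    allowed: np.ndarray,
    max_steps: int = 2000,
) -> list[tuple[int, int]]:
    """Grow a compact pixel blob by seeded random walk to a target count.

    Growth steps move from a random blob pixel to a random 4-neighbor and
    only enter ``allowed`` cells, which excludes pixels of (or adjacent to)
    previously grown deposits so distinct deposits never touch, even
    diagonally.
    """
    pixels = [start]
    members = {start}
    steps = 0
    while len(pixels) < target and steps < max_steps:
        steps += 1
        r, c = pixels[rng.integers(len(pixels))]
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        cand = (r + dr, c + dc)
        if cand in members:
            continue
        if 0 <= cand[0] < allowed.shape[0] and 0 <= cand[1] < allowed.shape[1]:
            if allowed[cand]:
                pixels.append(cand)
                members.add(cand)
    return pixels


def generate_mri_phantom(config: MRIPhantomConfig) -> tuple[MGESeries, GroundTruth]:
    """Simulate a multi-gradient-echo series of a tumor section.

    Returns the echo stack (with additive Gaussian magnitude noise, or
    Rician if ``config.rician``) together with the ground-truth iron map,
    tumor mask and deposit table.  Identical config + seed gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_rows, config.grid_cols
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)

    rr, cc = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(rr - center[0], cc - center[1])
    tumor_mask = dist <= config.tumor_radius

    iron = np.zeros((rows, cols))
    baseline = rng.normal(config.baseline_iron_mean, config.baseline_iron_sd,
                          size=(rows, cols))
    iron[tumor_mask] = np.clip(baseline[tumor_mask], 0.0, None)

    # deposits: spaced centers in the margin band, random-walk grown blobs
    centers = _place_centers(
        rng, config.n_deposits, center, config.tumor_radius,
        config.margin_band, config.deposit_min_spacing,
    )
    band_lo, band_hi = config.margin_band
    allowed = (
        tumor_mask
        & (dist >= band_lo * config.tumor_radius)
        & (dist <= band_hi * config.tumor_radius)
    )
    deposit_rows = []
    pixel_rows = []
    for dep_id in range(1, config.n_deposits + 1):
        cy, cx = centers[dep_id - 1]
        start = (int(round(cy)), int(round(cx)))
        if not allowed[start]:
            # nudge to the nearest allowed pixel in a small neighborhood
            found = None
            for radius_px in range(1, 4):
                for dy in range(-radius_px, radius_px + 1):
                    for dx in range(-radius_px, radius_px + 1):
                        cand = (start[0] + dy, start[1] + dx)
                        if (0 <= cand[0] < rows and 0 <= cand[1] < cols
                                and allowed[cand]):
                            found = cand
                            break
                    if found:
                        break
                if found:
                    break
            if found is None:
                raise ConfigurationError("deposit center blocked; spacing too tight")
            start = found
        target = max(1, int(rng.poisson(config.deposit_area_mean)))
        pixels = _grow_blob(rng, start, target, allowed)
        level = rng.uniform(config.deposit_iron_lo, config.deposit_iron_hi)
        prr = np.array([p[0] for p in pixels])
        pcc = np.array([p[1] for p in pixels])
        iron[prr, pcc] = level
        # block the blob and its 8-neighborhood from later growth
        for r, c in pixels:
            allowed[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = False
        deposit_rows.append(
            {
                "deposit_id": dep_id,
                "centroid_row": float(prr.mean()),
                "centroid_col": float(pcc.mean()),
                "n_pixels": len(pixels),
                "iron_mg_g": level,
            }
        )
        for r, c in pixels:
            pixel_rows.append(
                {"deposit_id": dep_id, "row": r, "col": c, "iron_mg_g": level}
            )

    # signal model: R2* = m C + b in s^-1, decay evaluated with TE in ms
    te = np.asarray(config.echo_times, dtype=float)
    r2star_s = config.calibration_slope * iron + config.calibration_intercept
    decay = np.exp(-te[:, None, None] * (r2star_s / 1000.0)[None])
    stack = np.where(tumor_mask[None], config.s0 * decay, 0.0)
    if config.noise_sd > 0:
        sigma = config.noise_sd * config.s0
        if config.rician:
            n1 = rng.normal(0.0, sigma, stack.shape)
            n2 = rng.normal(0.0, sigma, stack.shape)
            stack = np.hypot(stack + n1, n2)
        else:
            stack = np.abs(stack + rng.normal(0.0, sigma, stack.shape))

    series = MGESeries(stack=stack, echo_times=te, pixel_size=config.pixel_size)
    truth = GroundTruth(
        iron_map=iron,
        tumor_mask=tumor_mask,
        deposit_table=pd.DataFrame(
            deposit_rows,
            columns=["deposit_id", "centroid_row", "centroid_col",
                     "n_pixels", "iron_mg_g"],
        ),
        deposit_pixels=pd.DataFrame(
            pixel_rows, columns=["deposit_id", "row", "col", "iron_mg_g"]
        ),
    )
    return series, truth


def _sample_markers(rng: np.random.Generator, n: int, config: HistoPhantomConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample (aif1, cd206) flags for n macrophages."""
    double = rng.random(n) < config.p_double
    p1 = config.p_m1 / (config.p_m1 + config.p_m2)
    m1_single = rng.random(n) < p1
    aif1 = double | m1_single
    cd206 = double | ~m1_single
    return aif1, cd206


def generate_histo_phantom(
    config: HistoPhantomConfig,
) -> tuple[HistoRaster, GroundTruth]:
    """Simulate a stained tumor section with iron+ macrophage colonies.

    Returns a class-label raster plus ground truth: a cell table with
    positions in microns and CD68/F4-80/AIF1/CD206/iron flags, and a deposit
    table with true colony centers and cell counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mpp = config.microns_per_pixel
    rows, cols = config.section_rows, config.section_cols
    radius_um = config.resolved_tumor_radius_um()
    center_um = ((rows * mpp) / 2.0, (cols * mpp) / 2.0)  # (y, x)

    centers = _place_centers(
        rng, config.n_deposits, center_um, radius_um,
        config.deposit_margin_band, config.deposit_min_spacing_um,
    )

    cell_rows = []
    deposit_rows = []
    cell_id = 0
    for dep_id in range(1, config.n_deposits + 1):
        cy, cx = centers[dep_id - 1]
        n_cells = max(1, int(rng.poisson(config.cells_per_deposit_mean)))
        for _ in range(n_cells):
            cell_id += 1
            y = cy + rng.normal(0.0, config.colony_sigma_um)
            x = cx + rng.normal(0.0, config.colony_sigma_um)
            cell_rows.append({"cell_id": cell_id, "x_um": x, "y_um": y,
                              "iron": True, "deposit_id": dep_id})
        deposit_rows.append(
            {"deposit_id": dep_id, "centroid_row": cy / mpp,
             "centroid_col": cx / mpp, "n_cells": n_cells,
             "x_um": cx, "y_um": cy}
        )

    for _ in range(config.n_background_macrophages):
        cell_id += 1
        r = radius_um * math.sqrt(rng.uniform(0.0, 1.0))
        theta = rng.uniform(0, 2 * math.pi)
        cell_rows.append(
            {
                "cell_id": cell_id,
                "x_um": center_um[1] + r * math.cos(theta),
                "y_um": center_um[0] + r * math.sin(theta),
                "iron": bool(rng.random() < config.p_iron_background),
                "deposit_id": pd.NA,
            }
        )

    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "x_um", "y_um", "iron", "deposit_id"]
    )
    n = len(cells)
    aif1, cd206 = _sample_markers(rng, n, config)
    cells["cd68"] = True
    cells["f480"] = True
    cells["aif1"] = aif1
    cells["cd206"] = cd206
    cells = cells[["cell_id", "x_um", "y_um", "cd68", "f480",
                   "aif1", "cd206", "iron", "deposit_id"]]

    # render the label raster: macrophage disks, iron+ drawn on top
    raster = np.zeros((rows, cols), dtype=np.uint8)
    r_px = max(1.0, config.cell_radius_um / mpp)
    for iron_pass in (False, True):
        subset = cells[cells["iron"] == iron_pass]
        cls = IRON_CLASS if iron_pass else CELL_CLASS
        for _, cell in subset.iterrows():
            rr_d, cc_d = _draw_disk(
                (cell["y_um"] / mpp, cell["x_um"] / mpp), r_px, shape=(rows, cols)
            )
            raster[rr_d, cc_d] = cls

    dist = np.hypot(
        (np.arange(rows)[:, None] + 0.5) * mpp - center_um[0],
        (np.arange(cols)[None, :] + 0.5) * mpp - center_um[1],
    )
    truth = GroundTruth(
        tumor_mask=dist <= radius_um,
        deposit_table=pd.DataFrame(
            deposit_rows,
            columns=["deposit_id", "centroid_row", "centroid_col",
                     "n_cells", "x_um", "y_um"],
        ),
        cell_table=cells,
    )
    histo = HistoRaster(pixels=raster, microns_per_pixel=mpp, provenance="phantom")
    return histo, truth


# stain-like colors for the optional RGB rendering (Prussian blue reaction
# product and a nuclear-fast-red counterstain on a white slide background)
RGB_PALETTE = {
    BACKGROUND_CLASS: (255, 255, 255),
    CELL_CLASS: (205, 92, 92),
    IRON_CLASS: (45, 60, 160),
}


def render_rgb(label_raster: np.ndarray) -> np.ndarray:
    """Map a class-label raster to an RGB raster with stain-like colors."""
    out = np.zeros(label_raster.shape + (3,), dtype=np.uint8)
    for cls, color in RGB_PALETTE.items():
        out[label_raster == cls] = color
    return out
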