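"""Seeded synthetic adipose-histology generator with planted ground truth.

Generates RGB brightfield-like fields that carry the visual statistics the
detection pipeline assumes — bright adipocyte lumina bounded by dark
membranes on a bluish counterstain background, with reddish F4/80-positive
arcs ("crowns") around a controllable fraction of cells — together with a
full per-cell truth table (areas, planted stained fractions, CLS labels)
and label/membrane rasters.  Every field is a pure function of its
configuration, including the seed: identical config ⇒ bit-identical output.

Geometry is deliberately simple (non-overlapping circular lumina with
annular membranes, placed by seeded dart throwing): the downstream detector
only relies on connected bright lumina separated by dark membranes, not on
realistic tissue texture.

Color model
-----------
Each pixel has a target gray level ``g`` (lumen, membrane or background
mean) and a target red/blue ratio ``q`` (stain or counterstain).  Channels
are solved in float as ``B = g / (0.299 q + 0.701)``, ``R = q B``,
``G = B`` so that the ITU-R 601 gray equals ``g`` and ``R/B`` equals ``q``
exactly before quantization, then Gaussian noise is added and the result
rounded to 8 bit.  With the default ratios (counterstain 0.85, stain 1.20)
the blue channel stays ≥ 50 everywhere, so 8-bit rounding perturbs the
ratio by at most 1/50 = 0.02 and can never carry a pixel across the 1.05
stain boundary.

Stain geometry
--------------
A crowned cell receives an angular arc of stained pixels whose coverage of
the membrane annulus equals the planted fraction exactly to within one
pixel-arc (pixels are ranked by angle and exactly ``round(f * n)`` are
taken).  The stained band extends ``stain_band_inner`` pixels *into* the
lumen as well as across the membrane, so that any downstream morphological
ring of width ≤ ``stain_band_inner`` lies radially inside the stained band
and measures the planted angular fraction rather than half of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .segmentation import GRAY_WEIGHTS, ImageField

__all__ = [
    "GeneratorConfig",
    "TruthCell",
    "SyntheticTruth",
    "PackingError",
    "generate_field",
    "generate_cohort",
    "load_truth",
]

#: Manifest columns written by :func:`generate_cohort`.
MANIFEST_COLUMNS = [
    "animal_id",
    "group",
    "field_id",
    "image_path",
    "truth_path",
    "pixel_size_um",
]


class PackingError(RuntimeError):
    """Raised when the requested cell count cannot be placed."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic field.

    Attributes
    ----------
    field_shape:
        (height, width) in pixels.
    pixel_size:
        µm per pixel.
    n_cells_target:
        Number of adipocytes to place; placement failure raises
        :class:`PackingError` naming the achieved count.
    cell_radius_dist:
        (mean, sd, min) of lumen radii in µm; sampled from a normal
        truncated below at the minimum.
    membrane_width:
        Width in pixels of the dark membrane annulus around each lumen.
    lumen_intensity, membrane_intensity, background_intensity:
        (mean gray level, noise sd) pairs on the 8-bit scale.
    counterstain_rb_ratio, stain_rb_ratio:
        Red/blue ratio of unstained tissue (< 1.05) and of F4/80-positive
        pixels (> 1.05).
    cls_fraction:
        Fraction of cells that receive a crown, in [0, 1].
    stained_membrane_fraction_dist:
        (low, high) of the uniform distribution of planted stained-membrane
        fractions for crowned cells.
    background_stain_fraction_dist:
        Same for non-crowned cells (sporadic interstitial macrophages);
        default (0, 0) = no stain.
    stain_band_inner:
        How many pixels the stained band reaches into the lumen; keep at
        least as large as the detector ring width.
    allow_border_cells:
        When False (default), lumina are placed so the full stained annulus
        fits inside the field; when True, centers may sit near the edge and
        lumina are clipped (exercises border-exclusion logic).
    illumination_gradient:
        Relative left-to-right linear shading amplitude (0 = flat field).
    seed:
        Master seed of the field.
    """

    field_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    n_cells_target: int = 12
    cell_radius_dist: tuple[float, float, float] = (18.0, 4.0, 10.0)
    membrane_width: int = 4
    lumen_intensity: tuple[float, float] = (210.0, 2.0)
    membrane_intensity: tuple[float, float] = (60.0, 2.0)
    background_intensity: tuple[float, float] = (180.0, 2.0)
    counterstain_rb_ratio: float = 0.85
    stain_rb_ratio: float = 1.20
    cls_fraction: float = 0.3
    stained_membrane_fraction_dist: tuple[float, float] = (0.40, 0.90)
    background_stain_fraction_dist: tuple[float, float] = (0.0, 0.0)
    stain_band_inner: int = 4
    allow_border_cells: bool = False
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.counterstain_rb_ratio < self.stain_rb_ratio:
            raise ValueError(
                "counterstain_rb_ratio must be smaller than stain_rb_ratio"
            )
        if not 0 <= self.cls_fraction <= 1:
            raise ValueError("cls_fraction must lie in [0, 1]")
        for name in ("lumen_intensity", "membrane_intensity", "background_intensity"):
            mean, sd = getattr(self, name)
            if not (0 <= mean <= 255) or sd < 0:
                raise ValueError(f"{name} mean must be in [0, 255] and sd >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        lo, hi = self.stained_membrane_fraction_dist
        if not (0 <= lo <= hi <= 1):
            raise ValueError("stained_membrane_fraction_dist must be within [0, 1]")
        lo, hi = self.background_stain_fraction_dist
        if not (0 <= lo <= hi <= 1):
            raise ValueError("background_stain_fraction_dist must be within [0, 1]")


@dataclass
class TruthCell:
    """Planted ground truth for one generated adipocyte."""

    label: int
    true_area_um2: float
    planted_stained_fraction: float
    is_cls_true: bool
    touches_border: bool


@dataclass
class SyntheticTruth:
    """Planted truth for one field: cell table plus label/membrane rasters."""

    cells: list[TruthCell]
    label_raster: np.ndarray  # uint16, 0 = background, i = cell i's lumen
    membrane_raster: np.ndarray  # bool, membrane annuli

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])

    @property
    def n_cls_true(self) -> int:
        return sum(c.is_cls_true for c in self.cells)

    def pct_cls_true(self, include_border: bool = False) -> float:
        """Planted %CLS over non-border (or all) cells."""
        pool = [
            c for c in self.cells if include_border or not c.touches_border
        ]
        if not pool:
            raise ValueError("no eligible cells in truth")
        return 100.0 * sum(c.is_cls_true for c in pool) / len(pool)


def _solve_channels(gray: np.ndarray, ratio: np.ndarray) -> np.ndarray:
    """Invert the color model: gray level + R/B ratio -> float RGB."""
    wr, wg, wb = GRAY_WEIGHTS
    blue = gray / (wr * ratio + wg + wb)
    return np.stack([ratio * blue, blue, blue], axis=-1)


def _sample_radii(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    mean, sd, rmin = config.cell_radius_dist
    radii = np.empty(config.n_cells_target)
    for i in range(config.n_cells_target):
        for _ in range(1000):
            r = rng.normal(mean, sd)
            if r >= rmin:
                radii[i] = r
                break
        else:
            raise ValueError(
                "cell_radius_dist rejects everything: min radius too far "
                "above the mean"
            )
    return radii


def _place_centers(
    rng: np.random.Generator,
    radii_px: np.ndarray,
    config: GeneratorConfig,
    max_attempts_per_cell: int = 500,
) -> np.ndarray:
    """Dart-throwing placement of non-overlapping lumina.

    Centers keep a pairwise clearance of two membrane widths plus slack so
    that membranes and stained bands of neighboring cells never touch.
    """
    h, w = config.field_shape
    mw = config.membrane_width
    n_restarts = 30
    best_achieved = 0
    for _ in range(n_restarts):
        centers = np.empty((len(radii_px), 2))
        achieved = 0
        for i, r in enumerate(radii_px):
            margin = (
                0.0
                if config.allow_border_cells
                else r + mw + config.stain_band_inner + 1
            )
            if not config.allow_border_cells and (2 * margin >= h or 2 * margin >= w):
                raise PackingError(
                    f"placed 0 of {config.n_cells_target} cells: radius "
                    f"{r:.1f}px does not fit in a {h}x{w} field"
                )
            for _ in range(max_attempts_per_cell):
                c = np.array(
                    [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
                )
                dist = np.hypot(*(centers[:i] - c).T) if i else np.array([np.inf])
                clearance = radii_px[:i] + r + 2 * mw + 2 if i else np.array([0.0])
                if (dist >= clearance).all():
                    centers[i] = c
                    achieved = i + 1
                    break
            else:
                break
        if achieved == len(radii_px):
            return centers
        best_achieved = max(best_achieved, achieved)
    raise PackingError(
        f"placed only {best_achieved} of {config.n_cells_target} cells after "
        f"{n_restarts} restarts of {max_attempts_per_cell} attempts each; "
        "reduce n_cells_target or the cell radii"
    )


def generate_field(config: GeneratorConfig) -> tuple[ImageField, SyntheticTruth]:
    """Generate one synthetic field and its planted truth.

    Deterministic in ``config`` (including ``seed``).  Raises
    :class:`PackingError` when ``n_cells_target`` cannot be placed.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.field_shape
    radii_px = _sample_radii(rng, config) / config.pixel_size
    centers = _place_centers(rng, radii_px, config)

    rows, cols = np.mgrid[0:h, 0:w]
    gray = np.full((h, w), config.background_intensity[0])
    noise_sd = np.full((h, w), config.background_intensity[1])
    ratio = np.full((h, w), config.counterstain_rb_ratio)
    label_raster = np.zeros((h, w), dtype=np.uint16)
    membrane_raster = np.zeros((h, w), dtype=bool)

    # Crown assignment and planted fractions.
    crowned = rng.random(len(radii_px)) < config.cls_fraction
    lo_c, hi_c = config.stained_membrane_fraction_dist
    lo_b, hi_b = config.background_stain_fraction_dist
    target_fracs = np.where(
        crowned,
        rng.uniform(lo_c, hi_c, len(radii_px)),
        rng.uniform(lo_b, hi_b, len(radii_px)),
    )
    arc_starts = rng.uniform(0, 2 * np.pi, len(radii_px))

    cells: list[TruthCell] = []
    for i, (r, (cr, cc)) in enumerate(zip(radii_px, centers)):
        d = np.hypot(rows - cr, cols - cc)
        lumen = d <= r
        membrane = (d > r) & (d <= r + config.membrane_width)
        band = (d > r - config.stain_band_inner) & (d <= r + config.membrane_width)

        gray[lumen] = config.lumen_intensity[0]
        noise_sd[lumen] = config.lumen_intensity[1]
        gray[membrane] = config.membrane_intensity[0]
        noise_sd[membrane] = config.membrane_intensity[1]
        label_raster[lumen] = i + 1
        membrane_raster |= membrane

        # Plant the stained arc: exactly round(f * n) membrane pixels,
        # contiguous in angle from a random start, with the wider radial
        # band stained over the same angular window.
        theta = np.mod(np.arctan2(rows - cr, cols - cc) - arc_starts[i], 2 * np.pi)
        mem_angles = np.sort(theta[membrane])
        n_mem = len(mem_angles)
        k = int(round(target_fracs[i] * n_mem))
        if k > 0:
            if k >= n_mem:
                stained = band
            else:
                theta_cut = (mem_angles[k - 1] + mem_angles[k]) / 2
                stained = band & (theta <= theta_cut)
            ratio[stained] = config.stain_rb_ratio
        achieved = k / n_mem if n_mem else 0.0

        touches = bool(
            lumen[0, :].any()
            or lumen[-1, :].any()
            or lumen[:, 0].any()
            or lumen[:, -1].any()
        )
        cells.append(
            TruthCell(
                label=i + 1,
                true_area_um2=float(lumen.sum()) * config.pixel_size**2,
                planted_stained_fraction=achieved,
                is_cls_true=achieved > 0.30,
                touches_border=bool(touches),
            )
        )

    rgb = _solve_channels(gray, ratio)
    if config.illumination_gradient:
        shade = 1.0 + config.illumination_gradient * (
            cols / max(w - 1, 1) - 0.5
        )
        rgb = rgb * shade[..., None]
    rgb = rgb + rng.normal(0.0, 1.0, rgb.shape) * noise_sd[..., None]
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    image = ImageField(rgb=rgb, pixel_size=config.pixel_size)
    truth = SyntheticTruth(
        cells=cells, label_raster=label_raster, membrane_raster=membrane_raster
    )
    return image, truth


def _field_seed(master_seed: int, group_idx: int, animal_idx: int, field_idx: int) -> int:
    """Deterministic per-field seed from the cohort master seed.

    Uses numpy's SeedSequence keyed on (master, group, animal, field) and
    folds the state into a 31-bit integer.
    """
    ss = np.random.SeedSequence([master_seed, group_idx, animal_idx, field_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    group_configs: Mapping[str, GeneratorConfig],
    n_animals: int,
    fields_per_animal: int,
    out_dir: str | Path,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort on disk: images, truth files and a CSV manifest.

    For each group and each of ``n_animals`` animals, ``fields_per_animal``
    fields are generated with per-field seeds derived deterministically
    from ``master_seed`` (see :func:`_field_seed`).  Writes per field: the
    RGB image (TIFF), the truth cell table (JSON) and the 16-bit label map
    (TIFF); plus ``manifest.csv`` with one row per field.  Existing output
    paths are never overwritten silently.

    Returns the manifest as a DataFrame.
    """
    if fields_per_animal < 1:
        raise ValueError("fields_per_animal must be >= 1")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    out_dir = Path(out_dir).resolve()  # manifest paths are absolute
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for g_idx, (group, config) in enumerate(group_configs.items()):
        for a_idx in range(n_animals):
            animal_id = f"{group}_m{a_idx + 1}"
            for f_idx in range(fields_per_animal):
                field_id = f"f{f_idx + 1:02d}"
                seed = _field_seed(master_seed, g_idx, a_idx, f_idx)
                image, truth = generate_field(replace(config, seed=seed))
                stem = f"{animal_id}_{field_id}"
                image_path = out_dir / f"{stem}.tiff"
                truth_path = out_dir / f"{stem}_truth.json"
                label_path = out_dir / f"{stem}_labels.tiff"
                for p in (image_path, truth_path, label_path):
                    if p.exists():
                        raise FileExistsError(
                            f"refusing to overwrite existing output {p}"
                        )
                tifffile.imwrite(image_path, image.rgb, photometric="rgb")
                tifffile.imwrite(label_path, truth.label_raster)
                truth_path.write_text(
                    json.dumps(
                        {
                            "label_raster": label_path.name,
                            "pixel_size_um": config.pixel_size,
                            "cells": [asdict(c) for c in truth.cells],
                        },
                        indent=1,
                    )
                )
                records.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "field_id": field_id,
                        "image_path": str(image_path),
                        "truth_path": str(truth_path),
                        "pixel_size_um": config.pixel_size,
                    }
                )
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(f"refusing to overwrite existing output {manifest_path}")
    manifest.to_csv(manifest_path, index=False)
    return manifest


def load_truth(truth_path: str | Path) -> SyntheticTruth:
    """Load a truth file written by :func:`generate_cohort`."""
    truth_path = Path(truth_path)
    payload = json.loads(truth_path.read_text())
    label_raster = tifffile.imread(truth_path.parent / payload["label_raster"])
    cells = [TruthCell(**c) for c in payload["cells"]]
    return SyntheticTruth(
        cells=cells,
        label_raster=label_raster,
        membrane_raster=np.zeros_like(label_raster, dtype=bool),
    )
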