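"""End-to-end pipeline: configuration, manifest handling, orchestration.

A run is fully described by a :class:`PipelineConfig` (one YAML file that
round-trips losslessly).  ``run_pipeline`` reads a cohort manifest,
segments and CLS-scores every field, and writes per-field / per-animal /
per-group CSV tables, a JSON stats report, a resolved copy of the config
and a log file into the output directory.  Deterministic given config and
inputs; reruns produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import cls, morphometry, segmentation, synthetic
from .segmentation import ImageField

__all__ = [
    "SegmentationParams",
    "MorphometryParams",
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_manifest",
    "run_pipeline",
    "simulate_command",
]

logger = logging.getLogger("adipoquant")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and artifact-filter settings (see segmentation module)."""

    method: str | float = "otsu"  # "otsu" or a fixed grayscale level
    connectivity: int = 8
    min_area_um2: float = segmentation.DEFAULT_MIN_AREA_UM2
    max_area_um2: float = segmentation.DEFAULT_MAX_AREA_UM2
    exclude_border: bool = True
    fill_holes: bool = True


@dataclass(frozen=True)
class MorphometryParams:
    bin_width_um2: float = 500.0
    bin_max_um2: float = 16_000.0
    min_fields: int = 10
    strict_min_fields: bool = False

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, self.bin_max_um2 + self.bin_width_um2, self.bin_width_um2)


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cls: cls.ClsParams = field(default_factory=cls.ClsParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    manifest: str | None = None
    output_dir: str = "adipoquant_out"
    master_seed: int = 0
    pixel_size_um: float = 1.0  # fallback when the manifest lacks calibration
    n_animals: int = 3
    fields_per_animal: int = 10
    group_cls_fractions: dict = field(
        default_factory=lambda: {"control": 0.05, "obese": 0.40}
    )


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def norm(v):
        if isinstance(v, tuple):
            return [norm(x) for x in v]
        if isinstance(v, dict):
            return {k: norm(x) for k, x in v.items()}
        return v

    return {k: norm(v) for k, v in d.items()}


def _tupled(cls_type, data: dict):
    """Rebuild a dataclass, restoring list -> tuple for tuple-typed fields."""
    kwargs = {}
    for f in dataclasses.fields(cls_type):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls_type(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    payload = {
        "generator": _asdict(config.generator),
        "segmentation": _asdict(config.segmentation),
        "cls": _asdict(config.cls),
        "morphometry": _asdict(config.morphometry),
        "manifest": config.manifest,
        "output_dir": config.output_dir,
        "master_seed": config.master_seed,
        "pixel_size_um": config.pixel_size_um,
        "n_animals": config.n_animals,
        "fields_per_animal": config.fields_per_animal,
        "group_cls_fractions": dict(config.group_cls_fractions),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        generator=_tupled(synthetic.GeneratorConfig, payload.get("generator", {})),
        segmentation=_tupled(SegmentationParams, payload.get("segmentation", {})),
        cls=_tupled(cls.ClsParams, payload.get("cls", {})),
        morphometry=_tupled(MorphometryParams, payload.get("morphometry", {})),
        manifest=payload.get("manifest"),
        output_dir=payload.get("output_dir", "adipoquant_out"),
        master_seed=payload.get("master_seed", 0),
        pixel_size_um=payload.get("pixel_size_um", 1.0),
        n_animals=payload.get("n_animals", 3),
        fields_per_animal=payload.get("fields_per_animal", 10),
        group_cls_fractions=payload.get(
            "group_cls_fractions", {"control": 0.05, "obese": 0.40}
        ),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str, "field_id": str})
    required = {"animal_id", "group", "field_id", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"manifest {path} is missing required columns: {sorted(missing)}"
        )
    return df


def _load_field(row: pd.Series, default_pixel_size: float, base: Path) -> ImageField:
    img_path = Path(row["image_path"])
    if not img_path.is_absolute():
        img_path = base / img_path
    if not img_path.exists():
        raise FileNotFoundError(f"image not found: {img_path}")
    rgb = np.asarray(iio.imread(img_path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:  # drop alpha if present
        rgb = rgb[..., :3]
    pixel_size = float(row.get("pixel_size_um", default_pixel_size) or default_pixel_size)
    return ImageField(
        rgb=rgb,
        pixel_size=pixel_size,
        animal_id=str(row["animal_id"]),
        group=str(row["group"]),
        field_id=str(row["field_id"]),
    )


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def process_field(
    image: ImageField,
    seg_params: SegmentationParams,
    cls_params: cls.ClsParams,
    bin_edges: np.ndarray,
) -> tuple[morphometry.FieldSummary, pd.DataFrame]:
    """Segment + CLS-score one field; returns the summary and a cell table."""
    method = seg_params.method
    if not isinstance(method, str):
        method = float(method)
    seg = segmentation.segment_field(
        image,
        method=method,
        connectivity=seg_params.connectivity,
        min_area_um2=seg_params.min_area_um2,
        max_area_um2=seg_params.max_area_um2,
        exclude_border=seg_params.exclude_border,
        fill_holes=seg_params.fill_holes,
    )
    scores = cls.score_field(image.rgb, seg, cls_params)
    summary = morphometry.summarize_field(
        seg.cells,
        scores,
        animal_id=image.animal_id,
        group=image.group,
        field_id=image.field_id,
        bin_edges=bin_edges,
    )
    score_by_label = {s.label: s for s in scores}
    cell_rows = []
    for c in seg.cells:
        s = score_by_label[c.label]
        cell_rows.append(
            {
                "animal_id": image.animal_id,
                "group": image.group,
                "field_id": image.field_id,
                "label": c.label,
                "area_px": c.area_px,
                "area_um2": c.area_um2,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "touches_border": c.touches_border,
                "passed_filters": c.passed_filters,
                "ring_px": s.ring_px,
                "stained_ring_px": s.stained_ring_px,
                "stained_fraction": s.stained_fraction,
                "is_cls": s.is_cls,
            }
        )
    logger.info(
        "field %s/%s/%s: threshold=%.3f cells=%d passed=%d pct_cls=%.2f "
        "rb_threshold=%.3f fraction_threshold=%.3f ring_width=%d",
        image.group,
        image.animal_id,
        image.field_id,
        seg.threshold_used,
        len(seg.cells),
        summary.n_cells_passed,
        summary.pct_cls,
        cls_params.rb_ratio_threshold,
        cls_params.membrane_fraction_threshold,
        cls_params.ring_width,
    )
    return summary, pd.DataFrame(cell_rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole quantification over a cohort manifest.

    Writes into ``config.output_dir``: ``cells.csv`` (every segmented cell
    with morphometry and CLS score), ``per_field.csv``, ``per_animal.csv``,
    ``per_group.csv``, ``stats.json`` (ANOVA + Tukey on %CLS and mean area
    when the design allows), ``resolved_config.yaml`` and ``run.log``.
    """
    if config.manifest is None:
        raise ValueError("config.manifest is not set")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    try:
        manifest = read_manifest(config.manifest)
        base = Path(config.manifest).parent
        bin_edges = config.morphometry.bin_edges

        summaries: list[morphometry.FieldSummary] = []
        cell_tables: list[pd.DataFrame] = []
        for _, row in manifest.iterrows():
            image = _load_field(row, config.pixel_size_um, base)
            summary, cell_table = process_field(
                image, config.segmentation, config.cls, bin_edges
            )
            summaries.append(summary)
            cell_tables.append(cell_table)

        per_field = pd.DataFrame([s.to_row() for s in summaries])
        animal, group = morphometry.aggregate(
            per_field,
            min_fields=config.morphometry.min_fields,
            strict_min_fields=config.morphometry.strict_min_fields,
        )

        pd.concat(cell_tables, ignore_index=True).to_csv(
            out_dir / "cells.csv", index=False
        )
        per_field.to_csv(out_dir / "per_field.csv", index=False)
        animal.to_csv(out_dir / "per_animal.csv", index=False)
        group.to_csv(out_dir / "per_group.csv", index=False)

        stats_report: dict = {"n_fields": int(len(per_field))}
        by_group = {
            g: sub["pct_cls"].to_numpy() for g, sub in animal.groupby("group")
        }
        if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
            for metric in ("pct_cls", "mean_area_um2"):
                vals = {
                    g: sub[metric].to_numpy() for g, sub in animal.groupby("group")
                }
                res = morphometry.one_way_anova_tukey(vals)
                stats_report[metric] = {
                    "anova_f": res.f_statistic,
                    "anova_p": res.p_value,
                    "tukey_pairs": res.pairs.to_dict(orient="records"),
                }
        (out_dir / "stats.json").write_text(json.dumps(stats_report, indent=1))
        save_config(config, out_dir / "resolved_config.yaml")
        logger.info("run complete: %d fields, %d animals", len(per_field), len(animal))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


def simulate_command(config: PipelineConfig) -> pd.DataFrame:
    """Generate a synthetic cohort per the config; returns the manifest.

    Thin wrapper over :func:`adipoquant.synthetic.generate_cohort`: one
    generator config per group (differing in ``cls_fraction``), seeds
    derived from ``master_seed``.
    """
    group_configs = {
        g: dataclasses.replace(config.generator, cls_fraction=f)
        for g, f in config.group_cls_fractions.items()
    }
    return synthetic.generate_cohort(
        group_configs,
        n_animals=config.n_animals,
        fields_per_animal=config.fields_per_animal,
        out_dir=config.output_dir,
        master_seed=config.master_seed,
    )
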