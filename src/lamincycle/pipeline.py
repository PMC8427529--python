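"""Pipeline orchestration: configuration, logging, file I/O glue.

Wires the analysis stages together over a directory of per-cell TIFFs:
feature extraction -> serial gating -> colocalization + profiles ->
summaries, and separately CP trace fitting -> aggregation.  Every run
writes a manifest (config, seed, package versions) sufficient to
reproduce it; identical config + seed gives byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import skimage
import yaml

from . import __version__
from .colocalization import (
    cell_mask_from_channels,
    correlate_cell,
    records_to_frame,
    summaries_to_frame,
    summarize_by_phase,
)
from .cp_analysis import (
    aggregate_free_fraction,
    analyze_trace,
    fits_to_frame,
    read_traces_csv,
)
from .gating import GateConfig, gate_population, labels_to_frame
from .imaging_core import (
    CHANNELS,
    extract_features,
    features_to_frame,
    morphology_mask,
    read_cell_tiff,
)
from .profiles import (
    line_profile,
    periphery_interior_ratio,
    profiles_to_frame,
    ratios_to_frame,
)

log = logging.getLogger("lamincycle")

EXIT_OK = 0
EXIT_MISSING_INPUT = 2
EXIT_BAD_CONFIG = 3
EXIT_BAD_DATA = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    channel_map: tuple[str, ...] = CHANNELS
    gate: GateConfig = field(default_factory=GateConfig)
    coloc_mask_fraction: float = 0.1
    rim_width: int = 2
    cp_smooth_window_s: float = 0.1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        missing = {"laminA", "chromatin"} - set(self.channel_map)
        if missing:
            raise PipelineError(
                f"channel map must include {sorted(missing)}", EXIT_BAD_CONFIG
            )

    def to_yaml(self) -> str:
        data = asdict(self)
        data["channel_map"] = list(self.channel_map)
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise PipelineError("config file is not a mapping", EXIT_BAD_CONFIG)
        if "gate" in data and isinstance(data["gate"], dict):
            data["gate"] = GateConfig.from_dict(data["gate"])
        if "channel_map" in data:
            data["channel_map"] = tuple(data["channel_map"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineError(f"invalid config: {exc}", EXIT_BAD_CONFIG) from exc


def setup_logging(level: str, output_dir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if output_dir is not None:
        output_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(output_dir / "run.log", mode="w"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def write_manifest(config: PipelineConfig, out_dir: Path, extra: dict | None = None) -> None:
    manifest = {
        "lamincycle": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": yaml.safe_load(config.to_yaml()),
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_cells(config: PipelineConfig) -> list:
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise PipelineError(f"input directory not found: {input_dir}", EXIT_MISSING_INPUT)
    paths = sorted(input_dir.glob("*.tif")) + sorted(input_dir.glob("*.tiff"))
    if not paths:
        raise PipelineError(f"no TIFF images in {input_dir}", EXIT_MISSING_INPUT)
    cells = []
    for path in paths:
        try:
            cells.append(read_cell_tiff(path, config.channel_map))
        except Exception as exc:
            raise PipelineError(f"malformed TIFF {path.name}: {exc}", EXIT_BAD_DATA) from exc
    return cells


def run_imaging_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """features -> gating -> colocalization + profiles on an image directory.

    Returns the paths of the CSV artifacts written under ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = _load_cells(config)
    log.info("loaded %d cells from %s", len(cells), config.input_dir)

    features, masks_per_cell = [], []
    for image in cells:
        cell_mask = cell_mask_from_channels(
            image.channel("laminA"), image.channel("tubulin"),
            fraction=config.coloc_mask_fraction,
        )
        nucleus = morphology_mask(image.channel("chromatin"))
        masks = {"cell": cell_mask, "nucleus": nucleus}
        features.append(extract_features(image, masks))
        masks_per_cell.append(masks)

    labels = gate_population(features, config.gate)
    phase_of = {lab.cell_id: lab.label for lab in labels}

    records, ratios, sections = [], [], []
    for image, masks in zip(cells, masks_per_cell):
        phase = phase_of[image.cell_id]
        records.extend(correlate_cell(image, masks["cell"], phase=phase))
        if phase != "excluded":
            ratios.append(
                periphery_interior_ratio(
                    image.channel("laminA"), masks["nucleus"],
                    rim_width=config.rim_width,
                    cell_id=image.cell_id, phase=phase,
                )
            )
        sections.append(line_profile(image, cell_mask=masks["cell"]))

    summaries = summarize_by_phase([r for r in records if r.phase != "excluded"])

    artifacts = {
        "features": out / "features.csv",
        "labels": out / "labels.csv",
        "correlations": out / "correlations.csv",
        "correlation_summary": out / "correlation_summary.csv",
        "profiles": out / "profiles.csv",
        "ratios": out / "ratios.csv",
    }
    features_to_frame(features).to_csv(artifacts["features"], index=False)
    labels_to_frame(labels).to_csv(artifacts["labels"], index=False)
    records_to_frame(records).to_csv(artifacts["correlations"], index=False)
    summaries_to_frame(summaries).to_csv(artifacts["correlation_summary"], index=False)
    profiles_to_frame(sections).to_csv(artifacts["profiles"], index=False)
    ratios_to_frame(ratios).to_csv(artifacts["ratios"], index=False)
    write_manifest(config, out, {"n_cells": len(cells)})
    log.info("wrote %d artifacts to %s", len(artifacts), out)
    return artifacts


def run_cp_pipeline(config: PipelineConfig, traces_csv: str | Path) -> dict[str, Path]:
    """CP fitting pipeline: preprocess + fit every trace, aggregate per label."""
    traces_csv = Path(traces_csv)
    if not traces_csv.is_file():
        raise PipelineError(f"trace file not found: {traces_csv}", EXIT_MISSING_INPUT)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = read_traces_csv(traces_csv)
    log.info("fitting %d CP traces", len(traces))
    results = [analyze_trace(tr, config.cp_smooth_window_s) for tr in traces]

    rows = []
    for label in sorted({r.label for r in results}):
        group = [r for r in results if r.label == label]
        try:
            s = aggregate_free_fraction(group, label=label)
        except ValueError as exc:
            log.warning("label %r skipped: %s", label, exc)
            continue
        rows.append(
            {"label": label, "mean_free_fraction_percent": s.mean_percent,
             "std_free_fraction_percent": s.std_percent, "n_fits": s.n_fits}
        )
    artifacts = {"fits": out / "cp_fits.csv", "summary": out / "cp_summary.csv"}
    fits_to_frame(results).to_csv(artifacts["fits"], index=False)
    pd.DataFrame(
        rows, columns=["label", "mean_free_fraction_percent", "std_free_fraction_percent", "n_fits"]
    ).to_csv(artifacts["summary"], index=False)
    write_manifest(config, out, {"n_traces": len(traces)})
    return artifacts
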