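"""Serial gating tree for cell-cycle phase classification.

Reproduces an imaging-flow-cytometry gating strategy: single cells are
selected on brightfield area and aspect ratio, uncropped cells on
centroid-x, focused cells on gradient RMS, nuclear-intensity extremes are
discarded, and the mitotic population is split off by its low lamin A
max-pixel intensity over the peri-nuclear ring (dividing cells disperse
lamin A instead of concentrating it at the nuclear envelope).  Mitotic
cells are then sub-classified by nuclear morphology:

* prophase  — high nuclear aspect ratio, one nuclear spot
* metaphase — low nuclear aspect ratio, one nuclear spot
* anaphase  — low nuclear aspect ratio, two nuclear spots (flagged
  low-confidence: this phase is rare and sparsely sampled)

Telophase is drawn from the NON-mitotic population (daughter nuclei have
already re-formed a bright lamin rim): low nuclear aspect ratio with two
nuclear spots.  Everything else non-mitotic is interphase.

The original gates were drawn interactively on bivariate plots, so no
numeric thresholds exist to copy.  Data-driven defaults are used instead:
quantile anchors padded outward by an IQR-style fence, and a 1-D Otsu
split for the mitotic gate.  All thresholds are overridable through
:class:`GateConfig`; comparisons at an exact threshold pass (closed
bounds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging_core import CellFeatures

PHASES = ("interphase", "prophase", "metaphase", "anaphase", "telophase")

#: Minimum population for the data-driven (quantile / Otsu) gates.
MIN_POPULATION = 10


class PopulationTooSmallError(ValueError):
    """Population-level gates need at least MIN_POPULATION cells."""


@dataclass
class GateConfig:
    """Thresholds of the serial gate tree.

    Range fields left as ``None`` are resolved from the population:
    quantile anchors (``*_quantiles``) widened on both sides by
    ``fence_factor`` x IQR of the feature, so a clean unimodal population
    passes intact while debris, doublets and cropped cells far outside the
    bulk are cut.  The mitotic split defaults to a 1-D Otsu threshold on
    the lamin A max pixel over the peri-nuclear ring.
    """

    area_range: tuple[float, float] | None = None
    aspect_ratio_single_cell_min: float = 0.5
    centroid_x_range: tuple[float, float] | None = None
    gradient_rms_min: float = 0.01
    nuclear_intensity_range: tuple[float, float] | None = None
    mitotic_max_pixel_rule: dict = field(
        default_factory=lambda: {"method": "otsu", "value": None}
    )
    aspect_ratio_low_high_cut: float = 0.6
    spot_threshold_fraction: float = 0.6
    spot_min_area: int = 10
    area_quantiles: tuple[float, float] = (0.05, 0.95)
    centroid_x_quantiles: tuple[float, float] = (0.05, 0.95)
    nuclear_intensity_quantiles: tuple[float, float] = (0.02, 0.98)
    fence_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.aspect_ratio_low_high_cut < 1.0:
            raise ValueError("aspect_ratio_low_high_cut must lie in (0, 1)")
        for name in ("area_range", "centroid_x_range", "nuclear_intensity_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"{name} must be ordered")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GateConfig":
        known = {f for f in cls.__dataclass_fields__}
        clean = {}
        for key, value in data.items():
            if key not in known:
                raise ValueError(f"unknown gate-config key {key!r}")
            if key.endswith(("_range", "_quantiles")) and value is not None:
                value = tuple(value)
            clean[key] = value
        return cls(**clean)


@dataclass
class PhaseLabel:
    """Result of the serial gating for one cell."""

    cell_id: str
    label: str
    exclusion_reason: str | None = None
    gate_trace: list[tuple[str, bool]] = field(default_factory=list)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.label == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded labels need an exclusion_reason")
        if self.label != "excluded" and self.exclusion_reason:
            raise ValueError("only excluded labels carry an exclusion_reason")


def _otsu_split_exact(values: np.ndarray) -> float:
    """Otsu's two-class split computed exactly on the sample.

    Scans every gap of the sorted values for the split maximizing the
    between-class variance w1*w2*(m1-m2)^2 and thresholds at the midpoint
    of the optimal gap — avoiding both histogram-binning artifacts and
    thresholds that graze a cluster edge.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("cannot split a constant sample")
    csum = np.cumsum(v)
    k = np.arange(1, n)  # size of the lower class
    m1 = csum[:-1] / k
    m2 = (csum[-1] - csum[:-1]) / (n - k)
    between = k * (n - k) * (m1 - m2) ** 2
    best = int(between.argmax()) + 1
    return float((v[best - 1] + v[best]) / 2.0)


def _fenced_range(
    values: np.ndarray, quantiles: tuple[float, float], fence_factor: float
) -> tuple[float, float]:
    lo_q, hi_q = np.quantile(values, quantiles)
    iqr = float(np.quantile(values, 0.75) - np.quantile(values, 0.25))
    pad = fence_factor * iqr
    return float(lo_q - pad), float(hi_q + pad)


def resolve_config(features: Sequence[CellFeatures], config: GateConfig) -> GateConfig:
    """Fill data-driven thresholds from the full population.

    Computed once on the whole input so labels are invariant to input
    order.  Raises :class:`PopulationTooSmallError` below MIN_POPULATION
    cells when any data-driven rule is needed.
    """
    needs_population = (
        config.area_range is None
        or config.centroid_x_range is None
        or config.nuclear_intensity_range is None
        or config.mitotic_max_pixel_rule.get("value") is None
    )
    if needs_population and len(features) < MIN_POPULATION:
        raise PopulationTooSmallError(
            f"population-level gates need >= {MIN_POPULATION} cells, got {len(features)}"
        )
    resolved = GateConfig.from_dict(config.to_dict())
    areas = np.array([f.area for f in features], dtype=float)
    cx = np.array([f.centroid_x for f in features], dtype=float)
    hoechst = np.array([f.nuclear_total_chromatin for f in features], dtype=float)
    if resolved.area_range is None:
        resolved.area_range = _fenced_range(areas, resolved.area_quantiles, resolved.fence_factor)
    if resolved.centroid_x_range is None:
        resolved.centroid_x_range = _fenced_range(
            cx, resolved.centroid_x_quantiles, resolved.fence_factor
        )
    if resolved.nuclear_intensity_range is None:
        resolved.nuclear_intensity_range = _fenced_range(
            hoechst, resolved.nuclear_intensity_quantiles, resolved.fence_factor
        )
    rule = dict(resolved.mitotic_max_pixel_rule)
    if rule.get("value") is None:
        method = rule.get("method", "otsu")
        maxpix = np.array([f.max_pixel["perinuclear"] for f in features], dtype=float)
        if method == "otsu":
            rule["value"] = _otsu_split_exact(maxpix)
        elif method == "quantile":
            rule["value"] = float(np.quantile(maxpix, rule.get("quantile", 0.5)))
        else:
            raise ValueError(f"unknown mitotic split method {method!r}")
        resolved.mitotic_max_pixel_rule = rule
    return resolved


def _classify_one(f: CellFeatures, cfg: GateConfig) -> PhaseLabel:
    trace: list[tuple[str, bool]] = []

    def gate(name: str, passed: bool) -> bool:
        trace.append((name, bool(passed)))
        return bool(passed)

    lo, hi = cfg.area_range
    if not gate("single_cell", lo <= f.area <= hi and f.aspect_ratio >= cfg.aspect_ratio_single_cell_min):
        return PhaseLabel(f.cell_id, "excluded", "not_single_cell", trace)
    lo, hi = cfg.centroid_x_range
    if not gate("uncropped", lo <= f.centroid_x <= hi):
        return PhaseLabel(f.cell_id, "excluded", "cropped", trace)
    if not gate("focused", f.gradient_rms >= cfg.gradient_rms_min):
        return PhaseLabel(f.cell_id, "excluded", "out_of_focus", trace)
    lo, hi = cfg.nuclear_intensity_range
    if not gate("nuclear_intensity", lo <= f.nuclear_total_chromatin <= hi):
        return PhaseLabel(f.cell_id, "excluded", "nuclear_intensity_extreme", trace)

    split = cfg.mitotic_max_pixel_rule["value"]
    mitotic = gate("mitotic", f.max_pixel["perinuclear"] < split)
    low_ar = f.nuclear_aspect_ratio < cfg.aspect_ratio_low_high_cut
    spots = f.nuclear_spot_count

    if mitotic:
        if not low_ar and spots == 1:
            gate("prophase", True)
            return PhaseLabel(f.cell_id, "prophase", gate_trace=trace)
        if low_ar and spots == 1:
            gate("metaphase", True)
            return PhaseLabel(f.cell_id, "metaphase", gate_trace=trace)
        if low_ar and spots == 2:
            gate("anaphase", True)
            return PhaseLabel(f.cell_id, "anaphase", gate_trace=trace, low_confidence=True)
        gate("mitotic_subphase", False)
        return PhaseLabel(f.cell_id, "excluded", "ambiguous_morphology", trace)

    if gate("telophase", low_ar and spots == 2):
        return PhaseLabel(f.cell_id, "telophase", gate_trace=trace)
    return PhaseLabel(f.cell_id, "interphase", gate_trace=trace)


def gate_population(
    features: Sequence[CellFeatures], config: GateConfig | None = None
) -> list[PhaseLabel]:
    """Apply the serial gate tree to a cell population.

    Data-driven thresholds (quantile fences, Otsu mitotic split) are
    resolved on the full population first, then each cell is classified
    independently — so shuffling the input permutes but never changes
    the labels.
    """
    if len(features) == 0:
        raise ValueError("gate_population needs at least one cell")
    cfg = resolve_config(features, config or GateConfig())
    return [_classify_one(f, cfg) for f in features]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def labels_to_frame(labels: Iterable[PhaseLabel]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": lab.cell_id,
            "label": lab.label,
            "exclusion_reason": lab.exclusion_reason or "",
            "low_confidence": lab.low_confidence,
            "gate_trace": json.dumps(lab.gate_trace),
        }
        for lab in labels
    ]
    return pd.DataFrame(rows, columns=["cell_id", "label", "exclusion_reason", "low_confidence", "gate_trace"])


def write_labels_csv(labels: Iterable[PhaseLabel], path: str | Path) -> None:
    labels_to_frame(labels).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
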