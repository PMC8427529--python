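"""Synthetic ground-truth generator for cell images and CP traces.

No raw single-cell data accompany the study conditions this package
targets, so every pipeline stage is exercised on simulated data whose
ground truth is known by construction.

Image model: each cell is painted as piecewise-constant intensity
compartments on a 128x128 canvas (cytoplasm, nucleus, lamina rim,
spindle, chromosome plate/lobes ...), convolved with a Gaussian
point-spread blur, then degraded with additive Gaussian noise whose
standard deviation scales like sqrt(intensity) (a Poisson surrogate).
The per-phase presets encode the phenotypes the pipeline must detect:

* interphase — round nucleus, lamin A rim-enriched (rim/interior ratio
  ground truth > 1), nucleoplasmic pool, tubulin cytoplasmic.
* prophase  — round condensed nucleus, lamin A concentrated in the
  nucleoplasm but depleted at the nuclear margin (rim ratio < 1),
  tubulin forming asters.
* metaphase — chromosome plate (low aspect ratio), lamin A dispersed in
  the cytoplasm, depleted over/around the plate, mildly enriched along
  the spindle; tubulin in a bright bipolar spindle.
* anaphase  — two separating chromatid lobes, lamin A depleted around
  them with bright accumulations near the spindle poles (two spots).
* telophase — two daughter nuclei with re-assembled bright lamin rims
  (two spots, rim ratio > 1), tubulin back in the cytoplasm plus a
  midbody remnant.

Rim bands are painted with the same disk-erosion geometry the analysis
uses, so with blur and noise disabled the measured periphery/interior
ratio equals the preset ``rim_factor`` up to rasterization.

CP model: I(t) = a exp(-b t) + c t + d with a = 1 - f and d = f for a
true free fraction f, preceded by a short detector-baseline segment
before laser-on, plus additive Gaussian noise.  Named presets G1
(f = 0.85) and S (f = 0.75) define the two study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import morphology

from .cp_analysis import CPTrace
from .imaging_core import (
    CHANNELS,
    BinaryMask,
    MultiChannelCellImage,
    write_cell_tiff,
)

CANVAS = 128

PHASES = ("interphase", "prophase", "metaphase", "anaphase", "telophase")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasePreset:
    """Geometry and intensity levels (a.u.) for one cell-cycle phase."""

    phase: str
    cell_radius: float = 44.0
    nucleus_radii: tuple[float, float] = (20.0, 17.0)  # per lobe, px
    lobe_offset: float = 0.0  # lobe centers at +/- this distance (two-lobe phases)
    rim_width: int = 3  # painted lamina / margin band, px
    rim_factor: float = 1.0  # ground-truth periphery/interior lamin ratio
    lamin: Mapping[str, float] = field(default_factory=dict)
    chromatin: Mapping[str, float] = field(default_factory=dict)
    tubulin: Mapping[str, float] = field(default_factory=dict)
    brightfield: Mapping[str, float] = field(default_factory=dict)
    spindle_radii: tuple[float, float] | None = None
    aster_offset: float = 0.0
    aster_radius: float = 6.0
    cap_offset: float = 0.0
    cap_radius: float = 5.0
    midbody_radius: float = 0.0
    psf_sigma: float = 1.5
    noise_scale: float = 0.03
    position_jitter: float = 3.0
    size_jitter: float = 0.06  # relative radius jitter


_BF = {"background": 0.35, "cell": 0.65, "nucleus": 0.55}

PHASE_PRESETS: dict[str, PhasePreset] = {
    "interphase": PhasePreset(
        phase="interphase",
        nucleus_radii=(20.0, 17.0),
        rim_factor=3.0,
        lamin={"cytoplasm": 0.08, "interior": 0.30},
        chromatin={"cytoplasm": 0.03, "nucleus": 0.90},
        tubulin={"cytoplasm": 0.75, "nucleus": 0.05},
        brightfield=_BF,
    ),
    "prophase": PhasePreset(
        phase="prophase",
        nucleus_radii=(19.0, 16.0),
        rim_factor=0.7,
        lamin={"cytoplasm": 0.35, "interior": 0.45},
        chromatin={"cytoplasm": 0.03, "nucleus": 1.00},
        tubulin={"cytoplasm": 0.55, "nucleus": 0.08, "aster": 0.85},
        brightfield=_BF,
        aster_offset=27.0,
    ),
    "metaphase": PhasePreset(
        phase="metaphase",
        nucleus_radii=(22.0, 7.0),  # chromosome plate
        rim_factor=0.48,
        lamin={"cytoplasm": 0.42, "interior": 0.25, "spindle": 0.55},
        chromatin={"cytoplasm": 0.03, "nucleus": 1.00},
        tubulin={"cytoplasm": 0.25, "nucleus": 0.35, "spindle": 0.80, "halo": 0.35},
        brightfield=_BF,
        spindle_radii=(36.0, 9.0),
        rim_width=4,  # lamin exclusion margin around the condensed plate
    ),
    "anaphase": PhasePreset(
        phase="anaphase",
        nucleus_radii=(10.0, 8.0),
        lobe_offset=16.0,
        rim_factor=0.55,
        lamin={"cytoplasm": 0.35, "interior": 0.22, "cap": 0.80},
        chromatin={"cytoplasm": 0.03, "nucleus": 1.00},
        tubulin={"cytoplasm": 0.25, "nucleus": 0.35, "spindle": 0.75},
        brightfield=_BF,
        spindle_radii=(38.0, 8.0),
        cap_offset=36.0,
        cap_radius=5.0,
        rim_width=3,
    ),
    "telophase": PhasePreset(
        phase="telophase",
        nucleus_radii=(14.0, 14.0),
        lobe_offset=20.0,
        rim_factor=3.4,
        lamin={"cytoplasm": 0.12, "interior": 0.25},
        chromatin={"cytoplasm": 0.03, "nucleus": 0.90},
        tubulin={"cytoplasm": 0.60, "nucleus": 0.05, "midbody": 0.80},
        brightfield=_BF,
        midbody_radius=4.0,
    ),
}


@dataclass(frozen=True)
class CPSimConfig:
    """Forward-model parameters for simulated CP traces."""

    true_free_fraction: float
    bleach_rate: float = 0.3  # 1/s, bound-pool bleaching
    free_slope: float = -0.002  # a.u./s, slow bleaching of the free pool
    duration_s: float = 60.0
    sampling_rate_hz: float = 20.0
    pre_t0_baseline_s: float = 1.0
    baseline_level: float = 0.03
    noise_sigma: float = 0.02
    n_traces: int = 65

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_free_fraction <= 1.0:
            raise ValueError("true_free_fraction must lie in [0, 1]")
        if self.bleach_rate <= 0 or self.free_slope > 0:
            raise ValueError("need bleach_rate > 0 and free_slope <= 0")


#: Study conditions: free fractions used as simulation ground truth.
CP_PRESETS: dict[str, CPSimConfig] = {
    "G1": CPSimConfig(true_free_fraction=0.85),
    "S": CPSimConfig(true_free_fraction=0.75),
}


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.indices(shape, dtype=float)
    return rows, cols


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Boolean raster of a rotated ellipse (angle in radians, major axis first)."""
    rows, cols = _grid(shape)
    dr, dc = rows - center[0], cols - center[1]
    u = dc * np.cos(angle) + dr * np.sin(angle)
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    a, b = radii
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    return ellipse_mask(shape, center, (radius, radius))


def _rim_split(region: np.ndarray, rim_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a region into (rim band, interior) with disk erosion.

    Uses the same structuring element as the analysis-side erosion band,
    so painted rims align with measured ones exactly when blur is off.
    """
    interior = morphology.erosion(region, morphology.disk(rim_width))
    return region & ~interior, interior


# ---------------------------------------------------------------------------
# Cell rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderedCell:
    """A simulated cell image plus its ground truth."""

    image: MultiChannelCellImage
    masks: dict[str, BinaryMask]
    phase: str
    truth: dict[str, float]


def _nucleus_lobes(
    preset: PhasePreset,
    center: tuple[float, float],
    radii: tuple[float, float],
    lobe_offset: float,
    angle: float,
    shape: tuple[int, int],
) -> list[np.ndarray]:
    if lobe_offset <= 0:
        return [ellipse_mask(shape, center, radii, angle)]
    dr, dc = np.sin(angle) * lobe_offset, np.cos(angle) * lobe_offset
    return [
        ellipse_mask(shape, (center[0] - dr, center[1] - dc), radii, angle),
        ellipse_mask(shape, (center[0] + dr, center[1] + dc), radii, angle),
    ]


def render_cell(preset: PhasePreset, seed: int) -> RenderedCell:
    """Render one cell deterministically from (preset, seed).

    Geometry receives small random jitter (position, size, orientation);
    compartments are painted, blurred with the preset PSF and degraded
    with sqrt-scaled Gaussian noise.  Ground-truth masks (cell, nucleus,
    spindle where present) and the true phase ride along as sidecar
    metadata.
    """
    rng = np.random.default_rng(seed)
    shape = (CANVAS, CANVAS)
    jit = preset.position_jitter
    center = (CANVAS / 2 + rng.uniform(-jit, jit), CANVAS / 2 + rng.uniform(-jit, jit))
    size = 1.0 + rng.uniform(-preset.size_jitter, preset.size_jitter)
    angle = rng.uniform(0.0, np.pi)

    cell_radius = preset.cell_radius * size
    radii = (preset.nucleus_radii[0] * size, preset.nucleus_radii[1] * size)
    lobe_offset = preset.lobe_offset * size
    if cell_radius + max(jit, 0) + CANVAS / 2 >= CANVAS:
        raise ValueError("cell geometry exceeds canvas")

    cell = disk_mask(shape, center, cell_radius)
    lobes = _nucleus_lobes(preset, center, radii, lobe_offset, angle, shape)
    nucleus = np.logical_or.reduce(lobes)

    lam = np.zeros(shape)
    chrom = np.zeros(shape)
    tub = np.zeros(shape)
    bf = np.full(shape, preset.brightfield["background"])

    lam[cell] = preset.lamin["cytoplasm"]
    chrom[cell] = preset.chromatin["cytoplasm"]
    tub[cell] = preset.tubulin["cytoplasm"]
    bf[cell] = preset.brightfield["cell"]
    bf[nucleus] = preset.brightfield["nucleus"]

    spindle = None
    if preset.spindle_radii is not None:
        sr = (preset.spindle_radii[0] * size, preset.spindle_radii[1] * size)
        spindle = ellipse_mask(shape, center, sr, angle)
        tub[spindle] = preset.tubulin["spindle"]
        if "spindle" in preset.lamin:
            lam[spindle] = preset.lamin["spindle"]

    chrom[nucleus] = preset.chromatin["nucleus"]
    if "nucleus" in preset.tubulin:
        tub[nucleus] = preset.tubulin["nucleus"]

    # Lamin around/inside the nucleus: a rim band at rim_factor x interior
    # (bright lamina when > 1, exclusion margin when < 1).  For the mitotic
    # exclusion-margin phases the band extends rim_width outward as well.
    interior_level = preset.lamin["interior"]
    rim_level = preset.rim_factor * interior_level
    for lobe in lobes:
        if preset.rim_factor >= 1.0:
            band, interior = _rim_split(lobe, preset.rim_width)
            lam[interior] = interior_level
            lam[band] = rim_level
        else:
            halo = morphology.dilation(lobe, morphology.disk(preset.rim_width))
            band_in, interior = _rim_split(lobe, preset.rim_width)
            if "halo" in preset.tubulin:
                tub[halo & ~lobe] = preset.tubulin["halo"]
            lam[halo & ~lobe] = rim_level
            lam[band_in] = rim_level
            lam[interior] = interior_level

    if preset.aster_offset > 0:
        off = preset.aster_offset * size
        dr, dc = np.sin(angle) * off, np.cos(angle) * off
        for s in (-1, 1):
            aster = disk_mask(shape, (center[0] + s * dr, center[1] + s * dc), preset.aster_radius)
            tub[aster & cell] = preset.tubulin["aster"]

    if preset.cap_offset > 0:
        off = preset.cap_offset * size
        dr, dc = np.sin(angle) * off, np.cos(angle) * off
        for s in (-1, 1):
            cap = disk_mask(shape, (center[0] + s * dr, center[1] + s * dc), preset.cap_radius)
            lam[cap & cell] = preset.lamin["cap"]

    if preset.midbody_radius > 0:
        midbody = disk_mask(shape, center, preset.midbody_radius)
        tub[midbody] = preset.tubulin["midbody"]

    channels = {"brightfield": bf, "laminA": lam, "tubulin": tub, "chromatin": chrom}
    if preset.psf_sigma > 0:
        channels = {k: gaussian_filter(v, preset.psf_sigma) for k, v in channels.items()}
    if preset.noise_scale > 0:
        channels = {
            k: np.clip(v + rng.normal(0.0, preset.noise_scale * np.sqrt(v + 1e-3)), 0.0, None)
            for k, v in channels.items()
        }

    image = MultiChannelCellImage(
        cell_id=f"{preset.phase}_{seed:05d}", channels=channels, pixel_size=0.33
    )
    masks = {
        "cell": BinaryMask(cell, "truth:cell"),
        "nucleus": BinaryMask(nucleus, "truth:nucleus"),
    }
    if spindle is not None:
        masks["spindle"] = BinaryMask(spindle, "truth:spindle")
    truth = {
        "rim_factor": preset.rim_factor,
        "n_lobes": float(len(lobes)),
        "cell_radius": cell_radius,
    }
    return RenderedCell(image=image, masks=masks, phase=preset.phase, truth=truth)


def make_gallery(
    out_dir: str | Path, n_per_phase: int = 10, seed: int = 0,
    presets: Mapping[str, PhasePreset] | None = None,
) -> pd.DataFrame:
    """Render ``n_per_phase`` cells per phase to multi-page TIFFs + truth.csv.

    Each cell draws its own deterministic seed from (seed, phase, index),
    so different gallery seeds give different jitter under an identical
    truth-table schema.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    presets = presets or PHASE_PRESETS
    rows = []
    for pi, phase in enumerate(PHASES):
        preset = presets[phase]
        for i in range(n_per_phase):
            cell_seed = (seed * 100_003 + pi * 1_009 + i) % (2**31)
            cell = render_cell(preset, cell_seed)
            path = out_dir / f"{cell.image.cell_id}.tif"
            write_cell_tiff(cell.image, path, CHANNELS)
            rows.append(
                {
                    "cell_id": cell.image.cell_id,
                    "phase": phase,
                    "seed": cell_seed,
                    "rim_factor": cell.truth["rim_factor"],
                    "file": path.name,
                }
            )
    truth = pd.DataFrame(rows, columns=["cell_id", "phase", "seed", "rim_factor", "file"])
    truth.to_csv(out_dir / "truth.csv", index=False)
    return truth


# ---------------------------------------------------------------------------
# CP trace simulation
# ---------------------------------------------------------------------------


def simulate_cp_trace(config: CPSimConfig, seed: int, cell_id: str = "", label: str = "") -> CPTrace:
    """Forward-simulate one CP trace: baseline, laser-on jump, model decay.

    Post laser-on the noiseless signal is a exp(-b t) + c t + d with
    a = 1 - f and d = f (peak normalized to 1); additive Gaussian noise
    of the configured sigma is applied to the whole trace.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sampling_rate_hz
    n_pre = int(round(config.pre_t0_baseline_s / dt))
    n_post = int(round(config.duration_s / dt)) + 1
    t = np.arange(n_pre + n_post) * dt
    f = config.true_free_fraction
    a, d = 1.0 - f, f
    signal = np.full(t.size, config.baseline_level)
    t_rel = (np.arange(n_post)) * dt
    signal[n_pre:] = a * np.exp(-config.bleach_rate * t_rel) + config.free_slope * t_rel + d
    if config.noise_sigma > 0:
        signal = signal + rng.normal(0.0, config.noise_sigma, size=signal.shape)
    signal = np.clip(signal, 0.0, None)
    return CPTrace(time=t, intensity=signal, cell_id=cell_id or f"trace_{seed:05d}", label=label)


def simulate_cp_dataset(
    config: CPSimConfig, seed: int = 0, label: str = ""
) -> list[CPTrace]:
    """Simulate ``config.n_traces`` traces with per-trace seeds seed..seed+n-1."""
    return [
        simulate_cp_trace(config, seed + i, cell_id=f"{label or 'cp'}_{i:03d}", label=label)
        for i in range(config.n_traces)
    ]
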