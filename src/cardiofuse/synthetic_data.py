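"""Synthetic bilateral cell-trajectory cohorts with calibrated presets.

No tracking data were released for the cohorts this pipeline targets, so
the generator reproduces their statistical structure instead: two
bilateral populations of cardiomyocytes per embryo (placed in two medial
columns per side), moving as a biased random walk with

* a deterministic drift toward the midline (``medial_drift``, signed;
  positive = medial) plus an anterior-posterior drift,
* an embryo-level *coherent* stochastic component shared by every cell of
  the embryo at each timestep — the simplest mechanism that yields
  collective movement with negligible neighbor exchange,
* independent per-cell isotropic XY noise, and near-zero Z motion,
* a global imaging drift applied to every object (what drift correction
  must remove), and
* one reference-landmark track per embryo (the notochord tip) that shares
  the imaging drift and additionally retracts slowly posteriorly.

Two cohort presets are calibrated so that the per-cell mean
medial-lateral velocity matches the published cohort values: a wild-type
cohort of 8 embryos / 168 cells with cohort mean 0.19 μm/min, and a
*pdgfra* (ref) mutant cohort of 6 embryos / 137 cells — 2 "mild" embryos
with wild-type-like drift and 4 "severe" embryos sharing a single drift
value solved in closed form so the cell-weighted cohort mean equals
0.016 μm/min.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .track_io import TrackTable

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "EmbryoSpec",
    "CohortPreset",
    "WT_MEAN_VELOCITY_ML",
    "MUTANT_MEAN_VELOCITY_ML",
    "simulate_embryo",
    "simulate_cohort",
    "make_preset",
]

#: Published cohort-mean medial-lateral velocities (μm/min) the presets
#: are calibrated to reproduce.
WT_MEAN_VELOCITY_ML = 0.19
MUTANT_MEAN_VELOCITY_ML = 0.016


class ConfigurationError(ValueError):
    """Simulation parameters violate their invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the biased-random-walk embryo simulation.

    Attributes
    ----------
    cells_per_side
        Cells tracked per side: an exact count or an inclusive (lo, hi)
        range sampled per side.
    n_timepoints, dt
        31 frames at a 4-minute cadence by default (a 120-minute
        timelapse).
    medial_drift
        Expected per-cell medial velocity, μm/min; positive = toward the
        midline.
    ap_drift
        Anterior-posterior drift, μm/min (+ = anterior).
    coherent_fraction
        Share of the per-step XY noise *variance* drawn once per embryo
        per timestep and shared by all its cells; 1 = fully coherent
        movement, 0 = independent cells.
    noise_sigma
        Total per-step XY noise scale, μm per step per axis.
    z_noise_sigma
        Per-step Z noise, μm; small, as cells move negligibly in depth.
    initial_gap
        Distance between left and right population centroids at t0, μm.
    reference_retraction
        Posterior drift of the reference landmark, μm/min.
    imaging_drift
        (x, y) drift applied to ALL objects including the reference,
        μm/min; removed downstream by drift correction.
    midline_x
        Declared midline x-coordinate, μm.
    """

    n_embryos: int = 1
    cells_per_side: int | tuple[int, int] = (10, 12)
    n_timepoints: int = 31
    dt: float = 4.0
    medial_drift: float = WT_MEAN_VELOCITY_ML
    ap_drift: float = 0.05
    coherent_fraction: float = 0.5
    noise_sigma: float = 0.3
    z_noise_sigma: float = 0.05
    initial_gap: float = 100.0
    reference_retraction: float = 0.05
    imaging_drift: tuple[float, float] = (0.15, -0.1)
    midline_x: float = 0.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be at least 2")
        if self.noise_sigma < 0 or self.z_noise_sigma < 0:
            raise ConfigurationError("noise scales must be non-negative")
        if not 0.0 <= self.coherent_fraction <= 1.0:
            raise ConfigurationError("coherent_fraction must be in [0, 1]")
        return self

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["imaging_drift"] = list(self.imaging_drift)
        if isinstance(self.cells_per_side, tuple):
            d["cells_per_side"] = list(self.cells_per_side)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("imaging_drift"), list):
            d["imaging_drift"] = tuple(d["imaging_drift"])
        if isinstance(d.get("cells_per_side"), list):
            d["cells_per_side"] = tuple(d["cells_per_side"])
        return cls(**d).validate()


@dataclass
class EmbryoSpec:
    """Per-embryo override within a cohort preset."""

    embryo_id: str
    medial_drift: float
    n_left: int
    n_right: int
    phenotype: str = "wt"  # wt | mild | severe

    @property
    def n_cells(self) -> int:
        return self.n_left + self.n_right


@dataclass
class CohortPreset:
    """A calibrated cohort: per-embryo drifts and cell counts."""

    name: str
    group: str  # wt | mutant
    embryos: list[EmbryoSpec]
    target_mean_velocity_ml: float

    @property
    def total_cells(self) -> int:
        return sum(e.n_cells for e in self.embryos)

    def cell_weighted_mean_drift(self) -> float:
        return (
            sum(e.medial_drift * e.n_cells for e in self.embryos)
            / self.total_cells
        )


def _embryo_rng(seed: int, embryo_id: str) -> np.random.Generator:
    # stable per-embryo stream: (cohort seed, CRC32 of the embryo id)
    return np.random.default_rng([seed, zlib.crc32(str(embryo_id).encode())])


def _initial_positions(
    n: int, side_sign: int, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Two medial columns of cells per side, rows spaced along AP."""
    col_spacing, row_spacing = 8.0, 8.0
    cols = np.arange(n) % 2           # 0 = most medial column
    rows = np.arange(n) // 2
    centroid_x = cfg.midline_x - side_sign * cfg.initial_gap / 2
    x = centroid_x - side_sign * cols * col_spacing
    y = (rows - rows.mean()) * row_spacing
    jitter = rng.normal(0.0, 0.5, size=(n, 2))
    return np.column_stack([x, y]) + jitter


def simulate_embryo(
    config: SimulationConfig,
    embryo_id: str,
    group: str = "wt",
    n_left: int | None = None,
    n_right: int | None = None,
) -> TrackTable:
    """Simulate one embryo: bilateral cell tracks plus a reference track.

    Deterministic given ``(config.seed, embryo_id)``.  Left-side cells sit
    at x < midline and their medial direction is +x; right-side cells
    mirror them.  The reference landmark starts on the midline anterior to
    the cells, retracts posteriorly at ``reference_retraction`` and, like
    every cell, is translated by ``imaging_drift``.
    """
    config.validate()
    rng = _embryo_rng(config.seed, embryo_id)

    def draw_n() -> int:
        if isinstance(config.cells_per_side, (tuple, list)):
            lo, hi = config.cells_per_side
            return int(rng.integers(lo, hi + 1))
        return int(config.cells_per_side)

    n_left = draw_n() if n_left is None else n_left
    n_right = draw_n() if n_right is None else n_right
    T, dt = config.n_timepoints, config.dt
    sigma_shared = config.noise_sigma * np.sqrt(config.coherent_fraction)
    sigma_indiv = config.noise_sigma * np.sqrt(1.0 - config.coherent_fraction)
    imaging = np.asarray(config.imaging_drift, float) * dt

    # +1 medial direction sign for left (midline is at larger x), -1 for right
    side_sign = np.concatenate([np.ones(n_left), -np.ones(n_right)])
    sides = ["left"] * n_left + ["right"] * n_right
    n_cells = n_left + n_right

    pos0_left = _initial_positions(n_left, +1, config, rng)
    pos0_right = _initial_positions(n_right, -1, config, rng)
    pos = np.vstack([pos0_left, pos0_right])  # (n_cells, 2)
    z0 = rng.normal(0.0, 1.0, n_cells)

    shared = rng.normal(0.0, sigma_shared, size=(T - 1, 2))
    indiv = rng.normal(0.0, sigma_indiv, size=(T - 1, n_cells, 2))
    z_noise = rng.normal(0.0, config.z_noise_sigma, size=(T - 1, n_cells))

    drift = np.empty((n_cells, 2))
    drift[:, 0] = side_sign * config.medial_drift * dt
    drift[:, 1] = config.ap_drift * dt

    xyz = np.empty((T, n_cells, 3))
    xyz[0, :, :2] = pos
    xyz[0, :, 2] = z0
    for k in range(1, T):
        step = drift + shared[k - 1] + indiv[k - 1] + imaging
        xyz[k, :, :2] = xyz[k - 1, :, :2] + step
        xyz[k, :, 2] = xyz[k - 1, :, 2] + z_noise[k - 1]

    # reference landmark: on the midline, anterior to the cells
    ref = np.empty((T, 3))
    ref[0] = (config.midline_x, 120.0, 0.0)
    ref_step = np.array(
        [imaging[0], imaging[1] - config.reference_retraction * dt, 0.0]
    )
    for k in range(1, T):
        ref[k] = ref[k - 1] + ref_step

    t_index = np.arange(T)
    frames = []
    width = max(2, len(str(n_cells)))
    for i in range(n_cells):
        frames.append(
            pd.DataFrame(
                {
                    "embryo_id": embryo_id,
                    "group": group,
                    "track_id": f"{embryo_id}_c{i + 1:0{width}d}",
                    "cell_class": "cardiomyocyte",
                    "side": sides[i],
                    "t_index": t_index,
                    "t": t_index * dt,
                    "x": xyz[:, i, 0],
                    "y": xyz[:, i, 1],
                    "z": xyz[:, i, 2],
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "embryo_id": embryo_id,
                "group": group,
                "track_id": f"{embryo_id}_ref",
                "cell_class": "reference",
                "side": "none",
                "t_index": t_index,
                "t": t_index * dt,
                "x": ref[:, 0],
                "y": ref[:, 1],
                "z": ref[:, 2],
            }
        )
    )
    table = TrackTable(
        data=pd.concat(frames, ignore_index=True),
        midline_x=config.midline_x,
        dt=dt,
    )
    return table.validate()


# ---------------------------------------------------------------------
# calibrated cohort presets
# ---------------------------------------------------------------------

# Per-embryo drift offsets around the wild-type cohort mean; they sum to
# zero with equal per-embryo cell counts, so the cell-weighted cohort mean
# stays exactly on target while embryos spread realistically.
_WT_DRIFT_OFFSETS = (0.05, 0.03, 0.01, 0.02, -0.05, -0.03, -0.01, -0.02)
_WT_CELLS = (11, 10)      # per side; 21 cells per embryo, 8 embryos = 168
_MUT_MILD_CELLS = ((12, 11), (12, 11))            # 2 embryos, 23 cells each
_MUT_SEVERE_CELLS = ((12, 11), (12, 11), (12, 11), (11, 11))  # 23,23,23,22


def _severe_drift() -> float:
    """Closed-form calibration of the shared severe-embryo drift.

    With n_m mild cells at the wild-type drift v_wt and n_s severe cells
    at a common drift d, the cell-weighted cohort mean is
    (n_m v_wt + n_s d) / (n_m + n_s); solving for the published mutant
    mean v_mut gives d = ((n_m + n_s) v_mut - n_m v_wt) / n_s.
    """
    n_mild = sum(a + b for a, b in _MUT_MILD_CELLS)
    n_severe = sum(a + b for a, b in _MUT_SEVERE_CELLS)
    total = n_mild + n_severe
    return (total * MUTANT_MEAN_VELOCITY_ML - n_mild * WT_MEAN_VELOCITY_ML) / n_severe


def make_preset(name: str) -> tuple[SimulationConfig, CohortPreset]:
    """Return the calibrated (config, preset) pair for a named cohort.

    ``"wt"``: 8 embryos, 168 cells, all drifts positive, cell-weighted
    mean exactly 0.19 μm/min.  ``"ref_mutant"``: 6 embryos, 137 cells,
    2 mild embryos at the wild-type mean drift and 4 severe embryos at
    the closed-form drift making the cohort mean exactly 0.016 μm/min.
    """
    if name == "wt":
        embryos = [
            EmbryoSpec(
                embryo_id=f"wt_e{i + 1}",
                medial_drift=WT_MEAN_VELOCITY_ML + off,
                n_left=_WT_CELLS[0],
                n_right=_WT_CELLS[1],
                phenotype="wt",
            )
            for i, off in enumerate(_WT_DRIFT_OFFSETS)
        ]
        preset = CohortPreset(
            name="wt",
            group="wt",
            embryos=embryos,
            target_mean_velocity_ml=WT_MEAN_VELOCITY_ML,
        )
    elif name == "ref_mutant":
        d_severe = _severe_drift()
        embryos = [
            EmbryoSpec(
                embryo_id=f"ref_e{i + 1}",
                medial_drift=WT_MEAN_VELOCITY_ML,
                n_left=nl,
                n_right=nr,
                phenotype="mild",
            )
            for i, (nl, nr) in enumerate(_MUT_MILD_CELLS)
        ] + [
            EmbryoSpec(
                embryo_id=f"ref_e{i + 3}",
                medial_drift=d_severe,
                n_left=nl,
                n_right=nr,
                phenotype="severe",
            )
            for i, (nl, nr) in enumerate(_MUT_SEVERE_CELLS)
        ]
        preset = CohortPreset(
            name="ref_mutant",
            group="mutant",
            embryos=embryos,
            target_mean_velocity_ml=MUTANT_MEAN_VELOCITY_ML,
        )
    else:
        raise ValueError(f"unknown preset: {name!r} (expected 'wt' or 'ref_mutant')")
    config = SimulationConfig(n_embryos=len(preset.embryos)).validate()
    return config, preset


def simulate_cohort(
    preset: CohortPreset | str,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> TrackTable:
    """Simulate every embryo of a preset and concatenate the tracks.

    ``preset`` may be a name ("wt" / "ref_mutant") or a
    :class:`CohortPreset`.  ``seed`` overrides the config seed;
    reproducible given (preset, seed).
    """
    if isinstance(preset, str):
        default_config, preset = make_preset(preset)
        config = config or default_config
    elif config is None:
        config = SimulationConfig(n_embryos=len(preset.embryos))
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()

    pieces = []
    for spec in preset.embryos:
        cfg = replace(config, medial_drift=spec.medial_drift)
        tt = simulate_embryo(
            cfg,
            embryo_id=spec.embryo_id,
            group=preset.group,
            n_left=spec.n_left,
            n_right=spec.n_right,
        )
        pieces.append(tt.data)
    out = TrackTable(
        data=pd.concat(pieces, ignore_index=True),
        midline_x=config.midline_x,
        dt=config.dt,
    )
    return out.validate()
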