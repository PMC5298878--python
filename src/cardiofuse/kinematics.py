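"""Per-cell trajectory metrics: speed, efficiency, axis velocities, direction.

All metrics are computed on the XY plane only (cells move negligibly in
depth), from drift-corrected, side-aligned, complete tracks:

* ``path_length`` — polygonal length of the sampled trajectory ("distance").
* ``displacement`` — straight-line chord from first to last position.
* ``speed`` — path_length / duration (μm/min).
* ``efficiency`` — displacement / path_length, in [0, 1]; 1 for a
  perfectly straight path, 0 for a closed one.
* ``velocity_ml`` / ``velocity_ap`` — net medial (Δxm) and net AP (Δy)
  displacement over duration; positive medial velocity means net movement
  toward the midline.
* ``direction`` — angle of the net displacement vector (Δxm, |Δy|) from
  the medial axis, in degrees: 0° is purely medial, 90° purely AP,
  180° purely lateral.  Folding the AP component with an absolute value
  collapses anterior and posterior into one half-plane, so direction
  measures medial-vs-lateral bias irrespective of AP heading.

A naive reading of direction as a one-argument arctangent of
|Δy|/Δxm cannot distinguish medial from lateral movement when Δxm < 0;
the quadrant-aware two-argument form used here maps lateral movement to
the (90°, 180°] sector, which is what separates the mutant phenotype from
the wild type in the angular histogram.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .track_io import TrackTable

__all__ = ["compute_kinematics", "net_direction", "KINEMATIC_METRICS"]

logger = logging.getLogger(__name__)

#: Metric columns emitted by :func:`compute_kinematics`.
KINEMATIC_METRICS = [
    "duration",
    "path_length",
    "displacement",
    "speed",
    "efficiency",
    "velocity_ml",
    "velocity_ap",
    "direction",
]


def net_direction(dxm: float, dy: float) -> float:
    """Angle (degrees, [0, 180]) of a net displacement (Δxm, Δy).

    0° = purely medial, 90° = purely anterior-posterior, 180° = purely
    lateral.  Uses the quadrant-aware two-argument arctangent of
    (|Δy|, Δxm).

    Raises
    ------
    ValueError
        For the zero vector, whose direction is undefined.
    """
    if dxm == 0 and dy == 0:
        raise ValueError("direction undefined for zero displacement")
    return float(np.degrees(np.arctan2(abs(dy), dxm)))


def compute_kinematics(tracks: TrackTable) -> pd.DataFrame:
    """Compute one row of track-level metrics per cardiomyocyte.

    Requires an aligned table (``xm`` present) of complete tracks.  Net
    quantities use the first and last timepoint of each track; no
    smoothing or windowing is applied.  Stationary tracks (zero path
    length) get speed 0 and missing efficiency/direction rather than
    zeros, to avoid biasing cohort means; their count is logged.

    Returns
    -------
    DataFrame with columns ``embryo_id, group, track_id, side, ap_band``
    (if present) plus :data:`KINEMATIC_METRICS`.
    """
    if not tracks.aligned:
        raise ValueError("compute_kinematics requires an aligned table")
    rows = []
    n_stationary = 0
    has_band = "ap_band" in tracks.data.columns
    for (emb, tid), sub in tracks.cells.groupby(["embryo_id", "track_id"], sort=False):
        sub = sub.sort_values("t_index")
        t = sub["t"].to_numpy(float)
        duration = t[-1] - t[0]
        if duration <= 0:
            raise ValueError(
                f"track ({emb!r}, {tid!r}) has non-positive duration"
            )
        xy = sub[["xm", "y"]].to_numpy(float)
        steps = np.diff(xy, axis=0)
        path_length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        dxm, dy = xy[-1] - xy[0]
        displacement = float(np.hypot(dxm, dy))
        if path_length > 0:
            efficiency = displacement / path_length
        else:
            efficiency = np.nan
            n_stationary += 1
        direction = (
            net_direction(dxm, dy) if displacement > 0 else np.nan
        )
        row = {
            "embryo_id": emb,
            "group": sub["group"].iloc[0],
            "track_id": tid,
            "side": sub["side"].iloc[0],
            "duration": duration,
            "path_length": path_length,
            "displacement": displacement,
            "speed": path_length / duration,
            "efficiency": efficiency,
            "velocity_ml": dxm / duration,
            "velocity_ap": dy / duration,
            "direction": direction,
        }
        if has_band:
            row["ap_band"] = sub["ap_band"].iloc[0]
        rows.append(row)
    if n_stationary:
        logger.info(
            "%d stationary track(s): efficiency/direction reported as missing",
            n_stationary,
        )
    return pd.DataFrame(rows)
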