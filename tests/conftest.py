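import numpy as np
import pandas as pd
import pytest

from cardiofuse import SimulationConfig, TrackTable
from cardiofuse.track_io import TRACK_COLUMNS


def build_table(tracks, dt=4.0, midline_x=0.0, embryo_id="e1", group="wt",
                add_reference=True, ref_path=None, n_timepoints=None):
    """Build a TrackTable from {track_id: (side, [(x, y), ...])} literals.

    A stationary reference at the midline is added unless ``ref_path``
    (list of (x, y)) is given or ``add_reference`` is False.
    """
    rows = []
    t_max = 0
    for tid, (side, path) in tracks.items():
        t_max = max(t_max, len(path) - 1)
        for k, (x, y) in enumerate(path):
            rows.append(
                dict(embryo_id=embryo_id, group=group, track_id=tid,
                     cell_class="cardiomyocyte", side=side, t_index=k,
                     t=k * dt, x=x, y=y, z=0.0)
            )
    if n_timepoints is not None:
        t_max = max(t_max, n_timepoints - 1)
    if add_reference:
        path = ref_path if ref_path is not None else [(midline_x, 100.0)] * (t_max + 1)
        for k, (x, y) in enumerate(path):
            rows.append(
                dict(embryo_id=embryo_id, group=group, track_id=f"{embryo_id}_ref",
                     cell_class="reference", side="none", t_index=k,
                     t=k * dt, x=x, y=y, z=0.0)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return TrackTable(data=df, midline_x=midline_x, dt=dt)


@pytest.fixture
def noiseless_config():
    """All stochastic terms and nuisance drifts off: pure medial drift."""
    return SimulationConfig(
        cells_per_side=5,
        n_timepoints=31,
        medial_drift=0.5,
        ap_drift=0.0,
        coherent_fraction=0.0,
        noise_sigma=0.0,
        z_noise_sigma=0.0,
        reference_retraction=0.0,
        imaging_drift=(0.0, 0.0),
        seed=7,
    )


@pytest.fixture
def straight_table():
    """One left cell stepping +1 μm medially per 4-min frame, 29 frames."""
    path = [(-50.0 + k, 0.0) for k in range(29)]
    return build_table({"c1": ("left", path)})


def run_pipeline(tt):
    """drift_correct -> align_sides -> compute_kinematics."""
    from cardiofuse import align_sides, compute_kinematics, drift_correct

    return compute_kinematics(align_sides(drift_correct(tt)))
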