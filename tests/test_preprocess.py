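import numpy as np
import pandas as pd
import pytest

import cardiofuse as cf

from conftest import build_table, run_pipeline


def test_stationary_reference_leaves_positions_unchanged():
    tt = build_table({"c1": ("left", [(-50.0 + k, float(k)) for k in range(5)])})
    out = cf.drift_correct(tt)
    cells = tt.cells.reset_index(drop=True)
    pd.testing.assert_frame_equal(out.data[["x", "y", "z"]], cells[["x", "y", "z"]])
    assert out.drift_corrected
    assert (out.data["cell_class"] == "cardiomyocyte").all()  # reference dropped


def test_reference_motion_sign_is_subtracted():
    # cell stationary, reference moves (0, -1) per step -> cell moves (0, +1)
    n = 6
    tt = build_table(
        {"c1": ("left", [(-50.0, 0.0)] * n)},
        ref_path=[(0.0, 100.0 - k) for k in range(n)],
    )
    out = cf.drift_correct(tt)
    assert np.allclose(np.diff(out.data["y"]), 1.0)
    assert np.allclose(np.diff(out.data["x"]), 0.0)


def test_cumulative_displacement_subtraction():
    # reference path (k*D, 0); cell path (k*D + k, 0) -> corrected net = k steps of 1
    n, D = 8, 3.0
    tt = build_table(
        {"c1": ("left", [(k * D + k, 0.0) for k in range(n)])},
        ref_path=[(k * D, 100.0) for k in range(n)],
    )
    out = cf.drift_correct(tt)
    x = out.data["x"].to_numpy()
    assert x[-1] - x[0] == pytest.approx(n - 1)
    assert np.allclose(np.diff(x), 1.0)


def test_missing_or_incomplete_reference_raises():
    tt = build_table({"c1": ("left", [(-50.0, 0.0)] * 4)}, add_reference=False)
    with pytest.raises(cf.CorrectionError, match="no reference"):
        with pytest.warns(UserWarning):
            cf.drift_correct(tt.validate())
    tt2 = build_table(
        {"c1": ("left", [(-50.0, 0.0)] * 4)},
        ref_path=[(0.0, 100.0)] * 3,  # one timepoint short
    )
    with pytest.raises(cf.CorrectionError, match="incomplete"):
        cf.drift_correct(tt2)


def test_drift_correct_idempotent_with_stationary_reference():
    tt = build_table({"c1": ("left", [(-50.0 + k, 2.0 * k) for k in range(5)])},
                     ref_path=[(0.0 + 0.5 * k, 100.0) for k in range(5)])
    once = cf.drift_correct(tt)
    # re-insert a stationary reference and correct again
    ref = tt.data[tt.data["cell_class"] == "reference"].copy()
    ref[["x", "y", "z"]] = [0.0, 100.0, 0.0]
    again = cf.TrackTable(
        data=pd.concat([once.data, ref], ignore_index=True),
        midline_x=tt.midline_x, dt=tt.dt,
    )
    twice = cf.drift_correct(again)
    pd.testing.assert_frame_equal(
        twice.data.reset_index(drop=True), once.data.reset_index(drop=True)
    )


@pytest.mark.parametrize(
    "side, x0, dx, expected_dxm",
    [
        ("left", -50.0, +2.0, +2.0),   # left moving +x = medial
        ("right", +50.0, +2.0, -2.0),  # right moving +x = lateral
    ],
)
def test_align_sides_medial_sign(side, x0, dx, expected_dxm):
    tt = build_table({"c1": (side, [(x0, 0.0), (x0 + dx, 0.0)])})
    out = cf.align_sides(cf.drift_correct(tt))
    xm = out.data["xm"].to_numpy()
    assert xm[1] - xm[0] == pytest.approx(expected_dxm)
    assert out.aligned


def test_align_requires_flags_and_labels():
    tt = build_table({"c1": ("left", [(-50.0, 0.0)] * 3)})
    with pytest.raises(ValueError, match="drift-corrected"):
        cf.align_sides(tt)
    corrected = cf.drift_correct(tt)
    corrected.midline_x = None
    with pytest.raises(ValueError, match="midline_x"):
        cf.align_sides(corrected)


def test_mirror_invariance_of_xm_and_kinematics():
    rng = np.random.default_rng(11)
    paths = {}
    for i in range(4):
        steps = rng.normal(0.3, 0.8, size=(9, 2))
        pts = np.cumsum(np.vstack([[(-40.0, 5.0 * i)], steps]), axis=0)
        paths[f"c{i}"] = ("left", [tuple(p) for p in pts])
    tt = build_table(paths)
    kin = run_pipeline(tt)

    # reflect about the midline (x -> -x) and swap side labels
    mirrored = tt.copy()
    mirrored.data["x"] = 2 * tt.midline_x - mirrored.data["x"]
    is_cell = mirrored.data["cell_class"] == "cardiomyocyte"
    mirrored.data.loc[is_cell, "side"] = "right"
    kin_m = run_pipeline(mirrored)

    for col in ["speed", "efficiency", "velocity_ml", "velocity_ap", "direction"]:
        np.testing.assert_allclose(kin[col], kin_m[col], rtol=0, atol=1e-12)


def test_shared_displacement_field_exactly_cancelled(noiseless_config):
    from dataclasses import replace

    base = replace(noiseless_config, medial_drift=0.0)
    drifting = replace(base, imaging_drift=(1.0, -0.7))
    a = cf.align_sides(cf.drift_correct(cf.simulate_embryo(base, "e1")))
    b = cf.align_sides(cf.drift_correct(cf.simulate_embryo(drifting, "e1")))
    np.testing.assert_allclose(
        a.data[["x", "y"]].to_numpy(), b.data[["x", "y"]].to_numpy(), atol=1e-9
    )
    # and with zero drift the corrected cells are stationary
    assert np.allclose(b.data.groupby("track_id")["x"].std(ddof=0), 0.0, atol=1e-9)


@pytest.mark.parametrize(
    "n, expected_bands",
    [
        (9, {"top": 3, "middle": 3, "bottom": 3}),
        (2, {"top": 1, "bottom": 1}),
        (4, {"top": 2, "middle": 1, "bottom": 1}),
    ],
)
def test_ap_band_tertiles(n, expected_bands):
    paths = {
        f"c{i}": ("left", [(-40.0, 10.0 * i), (-39.0, 10.0 * i)]) for i in range(n)
    }
    tt = build_table(paths)
    out = cf.split_ap_bands(cf.align_sides(cf.drift_correct(tt)))
    first = out.data[out.data["t_index"] == 0]
    counts = first["ap_band"].value_counts().to_dict()
    assert counts == expected_bands
    # most anterior (largest y) cell is 'top'
    top_ids = set(first.loc[first["ap_band"] == "top", "track_id"])
    assert f"c{n - 1}" in top_ids


def test_ap_band_tie_break_is_deterministic():
    paths = {f"c{i}": ("left", [(-40.0, 5.0), (-39.0, 5.0)]) for i in range(3)}
    tt = build_table(paths)
    out = cf.split_ap_bands(cf.align_sides(cf.drift_correct(tt)))
    first = out.data[out.data["t_index"] == 0].set_index("track_id")
    # identical y: bands assigned in track_id order
    assert first.loc["c0", "ap_band"] == "top"
    assert first.loc["c1", "ap_band"] == "middle"
    assert first.loc["c2", "ap_band"] == "bottom"
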