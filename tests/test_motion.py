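"""Motion observables: superposition, distance series, swing-twist
decomposition and crystal-form proximity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pdiflex.geomsim import ConformerTrajectory
from pdiflex.motion import (crystal_form_proximity, domain_midpoint_distance,
                            interface_mobility_summary, kabsch, kabsch_rmsd,
                            pair_distance, tilt_twist)
from pdiflex.synth import Hinge, Translate, Twist, apply_known_motion


def test_kabsch_identity():
    p = np.random.default_rng(0).normal(size=(10, 3))
    r, t, rmsd = kabsch(p, p)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(r, np.eye(3), atol=1e-10)


def test_kabsch_recovers_applied_rotation():
    rng = np.random.default_rng(1)
    p = rng.normal(size=(25, 3))
    rot = Rotation.from_euler("zyx", [33, -71, 12], degrees=True)
    q = rot.apply(p) + np.array([1.0, -2.0, 3.0])
    r, t, rmsd = kabsch(p, q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(r, rot.as_matrix(), atol=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0)


def test_kabsch_rejects_degenerate_input():
    with pytest.raises(ValueError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch(line, line)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_kabsch_rmsd_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(8, 3))
    b = rng.normal(size=(8, 3))
    _, _, r_ab = kabsch_rmsd(a, b)
    _, _, r_ba = kabsch_rmsd(b, a)
    assert r_ab == pytest.approx(r_ba, abs=1e-9)


def _traj(structure, frames):
    return ConformerTrajectory(structure, None,
                               {k: c for k, c in enumerate(frames)})


def test_pair_distance_same_site_is_zero(dumbbell):
    traj = _traj(dumbbell, [dumbbell.coords])
    site = ("A", 1, "CA")
    ds = pair_distance(traj, site, site)
    assert ds.values[0] == 0.0


def test_pair_distance_missing_atom_names_site(dumbbell):
    traj = _traj(dumbbell, [dumbbell.coords])
    with pytest.raises(KeyError, match="site_2"):
        pair_distance(traj, ("A", 1, "CA"), ("A", 999, "CA"))


def test_pair_distance_tracks_constructed_translation(dumbbell,
                                                      dumbbell_annotation):
    coords = dumbbell.coords
    labels = np.array(dumbbell.domain_labels)
    is_ca = np.array([a.name == "CA" for a in dumbbell.atoms])
    axis = (coords[(labels == "D2") & is_ca].mean(0)
            - coords[(labels == "D1") & is_ca].mean(0))
    axis /= np.linalg.norm(axis)
    frames = []
    for k in range(4):
        moved = apply_known_motion(dumbbell, Translate(k * 2.0 * axis), "D2")
        frames.append(moved.coords)
    traj = _traj(dumbbell, frames)
    ds = domain_midpoint_distance(traj, "D1", "D2", dumbbell_annotation)
    increments = np.diff([ds.values[k] for k in range(4)])
    np.testing.assert_allclose(increments, 2.0, atol=1e-9)


def test_single_residue_domains_reduce_to_pair_distance(dumbbell):
    from pdiflex.structure import DomainAnnotation

    ann = DomainAnnotation([("p", [(1, 1)]), ("q", [(44, 44)])], "mature", 0)
    traj = _traj(dumbbell, [dumbbell.coords])
    mid = domain_midpoint_distance(traj, "p", "q", ann)
    direct = pair_distance(traj, ("A", 1, "CA"), ("A", 44, "CA"))
    assert mid.values[0] == pytest.approx(direct.values[0], abs=1e-12)


def test_tilt_twist_zero_at_reference(dumbbell, dumbbell_annotation):
    traj = _traj(dumbbell, [dumbbell.coords])
    s = tilt_twist(traj, ("D1", "D2"), dumbbell_annotation)
    assert s.tilt[0] == pytest.approx(0.0, abs=1e-6)
    assert s.twist[0] == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("angle", [8.0, 20.0, 45.0])
def test_twist_recovered_within_half_degree(dumbbell, dumbbell_annotation, angle):
    moved = apply_known_motion(dumbbell, Twist(angle), "D2")
    traj = _traj(dumbbell, [dumbbell.coords, moved.coords])
    s = tilt_twist(traj, ("D1", "D2"), dumbbell_annotation)
    assert s.twist[1] == pytest.approx(angle, abs=0.5)
    assert s.tilt[1] == pytest.approx(0.0, abs=0.5)


@pytest.mark.parametrize("angle", [5.0, 15.0, 30.0])
def test_tilt_recovered_within_half_degree(dumbbell, dumbbell_annotation, angle):
    coords = dumbbell.coords
    labels = np.array(dumbbell.domain_labels)
    c1 = coords[labels == "D1"].mean(0)
    c2 = coords[labels == "D2"].mean(0)
    axis = np.cross(c2 - c1, [0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    moved = apply_known_motion(dumbbell, Hinge(angle, axis=axis, pivot=c2), "D2")
    traj = _traj(dumbbell, [coords, moved.coords])
    s = tilt_twist(traj, ("D1", "D2"), dumbbell_annotation)
    assert s.tilt[1] == pytest.approx(angle, abs=0.5)
    assert s.twist[1] == pytest.approx(0.0, abs=0.5)


def test_observables_invariant_under_global_transform(dumbbell,
                                                      dumbbell_annotation):
    rot = Rotation.from_euler("xyz", [17, 123, -44], degrees=True)
    shift = np.array([10.0, -20.0, 5.0])
    moved = apply_known_motion(dumbbell, Twist(12.0), "D2")
    frames = [dumbbell.coords, moved.coords]
    frames_t = [rot.apply(f) + shift for f in frames]
    t1, t2 = _traj(dumbbell, frames), _traj(dumbbell, frames_t)
    d1 = pair_distance(t1, ("A", 1, "CA"), ("A", 44, "CA"))
    d2 = pair_distance(t2, ("A", 1, "CA"), ("A", 44, "CA"))
    assert d1.values == pytest.approx(d2.values, abs=1e-9)
    s1 = tilt_twist(t1, ("D1", "D2"), dumbbell_annotation)
    s2 = tilt_twist(t2, ("D1", "D2"), dumbbell_annotation)
    assert s1.tilt[1] == pytest.approx(s2.tilt[1], abs=1e-6)
    assert s1.twist[1] == pytest.approx(s2.twist[1], abs=1e-6)


def test_interface_mobility_summary_orders_by_injected_range(dumbbell,
                                                             dumbbell_annotation):
    frames_small = [dumbbell.coords,
                    apply_known_motion(dumbbell, Twist(5.0), "D2").coords]
    frames_large = [dumbbell.coords,
                    apply_known_motion(dumbbell, Twist(40.0), "D2").coords]
    s_small = tilt_twist(_traj(dumbbell, frames_small), ("D1", "D2"),
                         dumbbell_annotation)
    s_large = tilt_twist(_traj(dumbbell, frames_large), ("D1", "D2"),
                         dumbbell_annotation)
    report = interface_mobility_summary({("small", "i"): [s_small],
                                         ("large", "i"): [s_large]})
    assert [r["interface"] for r in report] == [("small", "i"), ("large", "i")]
    assert report[1]["twist_range"] == pytest.approx(40.0, abs=0.5)


def test_single_conformer_ranges_are_zero(dumbbell, dumbbell_annotation):
    s = tilt_twist(_traj(dumbbell, [dumbbell.coords]), ("D1", "D2"),
                   dumbbell_annotation)
    report = interface_mobility_summary({("D1", "D2"): [s]})
    assert report[0]["combined_range"] == 0.0


def test_interface_mobility_summary_rejects_empty():
    with pytest.raises(ValueError):
        interface_mobility_summary({})


def test_crystal_form_proximity_zero_on_trajectory_member(dumbbell,
                                                          dumbbell_annotation):
    moved = apply_known_motion(dumbbell, Twist(25.0), "D2")
    traj = _traj(dumbbell, [dumbbell.coords, moved.coords])
    series = tilt_twist(traj, ("D1", "D2"), dumbbell_annotation)
    gap = crystal_form_proximity(series, moved, traj, ("D1", "D2"),
                                 dumbbell_annotation)
    assert gap == pytest.approx(0.0, abs=0.2)
    gap_ref = crystal_form_proximity(series, dumbbell, traj, ("D1", "D2"),
                                     dumbbell_annotation)
    assert gap_ref == pytest.approx(0.0, abs=1e-6)
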