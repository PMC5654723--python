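"""Geometric simulation: ghost templates, relaxation and trajectories."""

import numpy as np
import pytest

from pdiflex.geomsim import (DEFAULT_CLASH_TOL, DEFAULT_TOL, build_ghosts, relax,
                             run_trajectory)
from pdiflex.motion import kabsch
from pdiflex.pebble import RigidClusterDecomposition, pebble_game


def test_ghost_units_cover_all_atoms_and_connect(dumbbell_ghosts, dumbbell):
    covered = set()
    for unit in dumbbell_ghosts.units:
        covered.update(int(a) for a in unit.atoms)
    assert covered == set(range(len(dumbbell.atoms)))
    assert dumbbell_ghosts.unit_adjacency_connected()


def test_ghosts_reject_incomplete_decomposition(dumbbell, dumbbell_network):
    bad = RigidClusterDecomposition({}, {}, 0)
    with pytest.raises(ValueError):
        build_ghosts(dumbbell, bad, dumbbell_network)


def test_fully_rigid_toy_is_single_unit(dumbbell, dumbbell_network):
    n = len(dumbbell.atoms)
    dec = RigidClusterDecomposition({i: 0 for i in range(n)},
                                    {0: set(range(n))}, 0)
    ghosts = build_ghosts(dumbbell, dec, dumbbell_network)
    sizes = sorted((len(u.atoms) for u in ghosts.units), reverse=True)
    assert sizes[0] == n  # the rigid cluster is one unit (plus no flexible ones)
    assert len(ghosts.units) == 1


def test_relax_is_fixed_point_on_satisfied_coords(dumbbell, dumbbell_ghosts):
    res0 = relax(dumbbell.coords, dumbbell_ghosts)
    assert res0.converged
    res = relax(res0.coords, dumbbell_ghosts)
    assert res.converged
    assert res.n_iter == 0
    np.testing.assert_allclose(res.coords, res0.coords, atol=1e-12)


def test_relax_restores_stretched_bond(dumbbell, dumbbell_ghosts, dumbbell_network):
    coords = dumbbell.coords
    res0 = relax(coords, dumbbell_ghosts)
    coords = res0.coords.copy()
    # stretch one terminal bond by 0.5 A
    e = next(e for e in dumbbell_network.edges
             if e.kind == "covalent" and e.i == 0)
    direction = coords[e.i] - coords[e.j]
    direction /= np.linalg.norm(direction)
    coords[e.i] += 0.5 * direction
    res = relax(coords, dumbbell_ghosts)
    assert res.converged
    d = np.linalg.norm(res.coords[e.i] - res.coords[e.j])
    assert abs(d - e.rest_length) < DEFAULT_TOL


def test_zero_step_size_gives_degenerate_trajectory(dumbbell, dumbbell_ghosts,
                                                    dumbbell_modes):
    _, ms = dumbbell_modes
    traj = run_trajectory(dumbbell, ms.mode(7), "+", ghosts=dumbbell_ghosts,
                          max_conformers=5, step_size=0.0)
    assert traj.degenerate
    for k in range(6):
        np.testing.assert_array_equal(traj.conformers[k], dumbbell.coords)


def test_zero_mode_vector_rejected(dumbbell, dumbbell_ghosts):
    n_ca = len(dumbbell.ca_indices())
    with pytest.raises(ValueError, match="zero mode"):
        run_trajectory(dumbbell, np.zeros(3 * n_ca), "+", ghosts=dumbbell_ghosts)


def test_conformer_zero_is_input_and_indices_contiguous(dumbbell_closing_run,
                                                        dumbbell):
    for traj in dumbbell_closing_run.values():
        np.testing.assert_array_equal(traj.conformers[0], dumbbell.coords)
        idx = traj.indices()
        assert idx == list(range(min(idx), max(idx) + 1))


def test_covalent_geometry_conserved_along_trajectory(dumbbell_closing_run,
                                                      dumbbell_network):
    cov = [(e.i, e.j, e.rest_length) for e in dumbbell_network.edges
           if e.kind == "covalent"]
    ii = np.array([c[0] for c in cov])
    jj = np.array([c[1] for c in cov])
    rest = np.array([c[2] for c in cov])
    for traj in dumbbell_closing_run.values():
        for coords in traj.conformers.values():
            d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
            assert np.abs(d - rest).max() < DEFAULT_TOL + 0.01


def test_rigid_cluster_shape_conserved(dumbbell_closing_run,
                                       dumbbell_decomposition, dumbbell):
    ref = dumbbell.coords
    for cid, members in dumbbell_decomposition.clusters.items():
        if len(members) < 4:
            continue
        idx = np.array(sorted(members))
        for traj in dumbbell_closing_run.values():
            for coords in traj.conformers.values():
                _, _, rmsd = kabsch(ref[idx], coords[idx])
                assert rmsd < DEFAULT_TOL


def test_steric_soundness_of_recorded_conformers(dumbbell_closing_run,
                                                 dumbbell_ghosts):
    from scipy.spatial import cKDTree

    radii = dumbbell_ghosts.radii
    excluded = dumbbell_ghosts.same_unit_pairs
    for traj in dumbbell_closing_run.values():
        for coords in traj.conformers.values():
            tree = cKDTree(coords)
            for i, j in tree.query_pairs(2 * radii.max() * 0.85):
                if (min(i, j), max(i, j)) in excluded:
                    continue
                limit = 0.85 * (radii[i] + radii[j])
                d = np.linalg.norm(coords[i] - coords[j])
                assert d >= limit - DEFAULT_CLASH_TOL - 1e-9


def test_closing_direction_jams_sterically(dumbbell_closing_run, dumbbell,
                                           dumbbell_annotation):
    """The hinge-closing run must end in steric contact between domains."""
    from pdiflex.motion import domain_midpoint_distance

    halts = {}
    for direction, traj in dumbbell_closing_run.items():
        ds = domain_midpoint_distance(traj, "D1", "D2", dumbbell_annotation)
        closing = ds.min() < ds.values[0] - 1.0
        halt = traj.halt_reason_pos if direction == "+" else traj.halt_reason_neg
        halts[closing] = halt
    assert halts[True] == "jammed-steric"


def test_coarse_ca_pipeline_with_domain_ghosts(dumbbell, dumbbell_spec,
                                               dumbbell_annotation):
    """A C-alpha-only trace with domain-rigid units supports the same
    trajectory machinery (the coarse mode used for large structures)."""
    import warnings

    from pdiflex.enm import build_enm, compute_modes
    from pdiflex.geomsim import build_ghosts_from_domains
    from pdiflex.motion import domain_midpoint_distance
    from pdiflex.network import build_network
    from pdiflex.structure import ca_subset

    coarse = ca_subset(dumbbell)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(coarse)
    assert {e.kind for e in net.edges} == {"covalent"}  # pseudo-bonded trace
    ghosts = build_ghosts_from_domains(coarse, dumbbell_annotation, net,
                                       bead_radius=2.2)
    assert ghosts.unit_adjacency_connected()
    ms = compute_modes(build_enm(coarse, 10.0), 1)
    traj = run_trajectory(coarse, ms.mode(7), "-", ghosts=ghosts,
                          max_conformers=60, mode_index=7)
    ds = domain_midpoint_distance(traj, "D1", "D2", dumbbell_annotation)
    assert abs(ds.max() - ds.min()) > 1.0  # the hinge actually moves


def test_trajectory_determinism(dumbbell, dumbbell_ghosts, dumbbell_modes):
    _, ms = dumbbell_modes
    a = run_trajectory(dumbbell, ms.mode(7), "+", ghosts=dumbbell_ghosts,
                       max_conformers=10)
    b = run_trajectory(dumbbell, ms.mode(7), "+", ghosts=dumbbell_ghosts,
                       max_conformers=10)
    assert a.conformers.keys() == b.conformers.keys()
    for k in a.conformers:
        np.testing.assert_array_equal(a.conformers[k], b.conformers[k])
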