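"""Geometric simulation of flexible motion along elastic-network modes.

The structure is decomposed into rigid "ghost" template units (rigid
clusters plus small overlapping bond-local units for flexible regions).
Each step biases the C-alpha positions along a low-frequency mode, drags
all atoms with their residues, and then iteratively re-fits the ghost
templates and resolves steric overlaps until local geometry is restored.
A trajectory halts when the conformer budget is exhausted or when template
fitting and steric exclusion can no longer be reconciled (jamming) -- for a
closing motion this is the steric contact between approaching domains.

The method is purely geometric: it maps the scope of motion, not its
energetics or timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .network import ConstraintNetwork, build_network
from .pebble import RigidClusterDecomposition, pebble_game
from .structure import Structure

__all__ = [
    "GhostUnit",
    "GhostTemplateSet",
    "ConformerTrajectory",
    "RelaxResult",
    "build_ghosts",
    "relax",
    "run_trajectory",
    "combine_directions",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
_DEFAULT_RADIUS = 1.70

DEFAULT_STEP_SIZE = 0.05     # A, max single-Ca displacement per step
DEFAULT_CLASH_SCALE = 0.85   # fraction of vdW-radius sum
DEFAULT_TOL = 0.125          # A, max atom-to-template mismatch at convergence
DEFAULT_CLASH_TOL = 0.05     # A, residual overlap tolerated at convergence
CLASH_MARGIN = 0.05          # A, extra separation applied when resolving a clash
DEFAULT_MAX_ITER = 200
MIN_RIGID_UNIT = 3           # clusters smaller than this are treated as flexible
STALL_WINDOW = 20            # steps in the moving window of realised progress
STALL_MEAN = 0.2             # mean realised fraction below which motion is jammed


@dataclass
class GhostUnit:
    atoms: np.ndarray        # atom indices, ascending
    template: np.ndarray     # (m, 3) local coordinates, centroid at origin


@dataclass
class GhostTemplateSet:
    units: list[GhostUnit]
    n_atoms: int
    radii: np.ndarray
    units_of_atom: list[list[int]] = field(default_factory=list)
    same_unit_pairs: set[tuple[int, int]] = field(default_factory=set)
    bond_index: np.ndarray | None = None    # (m, 2) covalent pairs
    bond_rest: np.ndarray | None = None     # (m,) rest lengths, A

    def unit_adjacency_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.units)))
        owner: dict[int, list[int]] = {}
        for ui, u in enumerate(self.units):
            for a in u.atoms:
                owner.setdefault(int(a), []).append(ui)
        for ulist in owner.values():
            for a, b in zip(ulist, ulist[1:]):
                g.add_edge(a, b)
        return nx.is_connected(g) if len(self.units) else False


@dataclass
class RelaxResult:
    coords: np.ndarray
    converged: bool
    n_iter: int
    jam_reason: str | None = None     # jammed-steric | jammed-no-convergence
    max_mismatch: float = 0.0
    max_overlap: float = 0.0


@dataclass
class ConformerTrajectory:
    structure: Structure
    mode_index: int | None
    conformers: dict[int, np.ndarray]
    halt_reason_pos: str | None = None   # completed | jammed-steric | jammed-no-convergence
    halt_reason_neg: str | None = None
    step_parameters: dict = field(default_factory=dict)
    degenerate: bool = False

    def indices(self) -> list[int]:
        return sorted(self.conformers)


def build_ghosts(structure: Structure, decomposition: RigidClusterDecomposition,
                 network: ConstraintNetwork | None = None,
                 min_rigid_size: int = MIN_RIGID_UNIT) -> GhostTemplateSet:
    """Construct rigid template units covering every atom.

    Rigid clusters of >= ``min_rigid_size`` atoms become single units.
    Every atom that is not strictly interior to such a cluster also gets a
    bond-local unit (itself plus its covalent neighbours, at most 5 atoms),
    so consecutive units overlap on the atoms of the shared bond and the
    unit-adjacency graph is connected for a connected molecule.
    """
    n = len(structure.atoms)
    if n == 0:
        raise ValueError("empty structure")
    if not decomposition.cluster_of or len(decomposition.cluster_of) != n:
        raise ValueError("decomposition does not cover all atoms")
    if network is None:
        network = build_network(structure)
    coords = structure.coords
    adj = network.covalent_adjacency()

    units: list[np.ndarray] = []
    big_cluster_of = {}
    for cid, members in sorted(decomposition.clusters.items()):
        if len(members) >= min_rigid_size:
            arr = np.array(sorted(members), dtype=int)
            units.append(arr)
            for a in members:
                big_cluster_of[a] = cid

    for a in range(n):
        neigh = sorted(adj[a])
        interior = (a in big_cluster_of
                    and all(b in big_cluster_of and big_cluster_of[b] == big_cluster_of[a]
                            for b in neigh))
        if interior:
            continue
        local = [a] + neigh[:4]
        units.append(np.array(sorted(set(local)), dtype=int))

    ghost_units = [GhostUnit(u, coords[u] - coords[u].mean(axis=0)) for u in units]
    radii = np.array([VDW_RADII.get(at.element, _DEFAULT_RADIUS) for at in structure.atoms])
    units_of_atom: list[list[int]] = [[] for _ in range(n)]
    same_unit: set[tuple[int, int]] = set()
    for ui, u in enumerate(ghost_units):
        for a in u.atoms:
            units_of_atom[int(a)].append(ui)
        for x in range(len(u.atoms)):
            for y in range(x + 1, len(u.atoms)):
                i, j = int(u.atoms[x]), int(u.atoms[y])
                same_unit.add((min(i, j), max(i, j)))
    uncovered = [a for a in range(n) if not units_of_atom[a]]
    if uncovered:
        raise AssertionError(f"internal consistency: atoms {uncovered[:5]} not covered by any unit")
    # pairs within 4 covalent bonds (1-2 to 1-5) are governed by covalent
    # geometry and torsions, not steric exclusion; leave them to the
    # templates, as nonbonded lists conventionally do
    for a in range(n):
        frontier = {a}
        seen = {a}
        for _ in range(4):
            frontier = {b for x in frontier for b in adj[x]} - seen
            seen |= frontier
        for b in seen:
            if b > a:
                same_unit.add((a, b))
    cov = [(e.i, e.j, e.rest_length) for e in network.edges if e.kind == "covalent"]
    bond_index = np.array([(i, j) for i, j, _ in cov], dtype=int) if cov else None
    bond_rest = np.array([r for _, _, r in cov]) if cov else None
    return GhostTemplateSet(ghost_units, n, radii, units_of_atom, same_unit,
                            bond_index, bond_rest)


def build_ghosts_from_domains(structure: Structure, annotation,
                              network: ConstraintNetwork | None = None,
                              bead_radius: float | None = None,
                              structure_convention: str = "mature") -> GhostTemplateSet:
    """Domain-rigid ghost units for coarse (e.g. C-alpha-only) runs.

    Each annotated domain becomes one rigid unit; linker atoms keep
    bond-local units.  ``bead_radius`` overrides the element van der Waals
    radii, which underestimate residue-level packing when one bead stands
    for a whole residue.
    """
    from .structure import assign_domains

    labelled = assign_domains(structure, annotation, structure_convention)
    cluster_of: dict[int, int] = {}
    clusters: dict[int, set[int]] = {}
    name_to_id = {name: k for k, name in enumerate(annotation.domain_names())}
    next_id = len(name_to_id)
    for i, lab in enumerate(labelled.domain_labels):
        if lab in name_to_id:
            cid = name_to_id[lab]
        else:
            cid = next_id
            next_id += 1
        cluster_of[i] = cid
        clusters.setdefault(cid, set()).add(i)
    dec = RigidClusterDecomposition(cluster_of, clusters, 0)
    if network is None:
        network = build_network(structure)
    ghosts = build_ghosts(structure, dec, network)
    if bead_radius is not None:
        ghosts.radii = np.full(ghosts.n_atoms, float(bead_radius))
    return ghosts


def _fit_targets(coords: np.ndarray, ghosts: GhostTemplateSet):
    """Least-squares fit of every unit; returns per-atom template targets.

    Units of equal size are fitted with one batched SVD.
    """
    n = ghosts.n_atoms
    acc = np.zeros((n, 3))
    cnt = np.zeros(n)
    worst = 0.0
    by_size: dict[int, list[int]] = {}
    for ui, unit in enumerate(ghosts.units):
        by_size.setdefault(len(unit.atoms), []).append(ui)
    for m, unit_ids in by_size.items():
        idx = np.stack([ghosts.units[ui].atoms for ui in unit_ids])      # (k, m)
        templates = np.stack([ghosts.units[ui].template for ui in unit_ids])
        cur = coords[idx]                                                # (k, m, 3)
        centroids = cur.mean(axis=1, keepdims=True)
        cur0 = cur - centroids
        h = np.einsum("kmi,kmj->kij", templates, cur0)                   # (k, 3, 3)
        u, _, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("kij,klj->kil", vt.transpose(0, 2, 1), u))
        corr = np.repeat(np.eye(3)[None], len(unit_ids), axis=0)
        corr[:, 2, 2] = np.where(det < 0, -1.0, 1.0)
        rot = np.einsum("kij,kjl,kml->kim", vt.transpose(0, 2, 1), corr, u)
        fitted = np.einsum("kmj,kij->kmi", templates, rot) + centroids
        worst = max(worst, float(np.linalg.norm(fitted - cur, axis=2).max()))
        np.add.at(acc, idx.ravel(), fitted.reshape(-1, 3))
        np.add.at(cnt, idx.ravel(), 1.0)
    return acc / cnt[:, None], worst


def _clash_pushes(coords: np.ndarray, ghosts: GhostTemplateSet, clash_scale: float):
    """Displacements resolving steric overlaps; returns (push, max_overlap)."""
    n = ghosts.n_atoms
    push = np.zeros((n, 3))
    max_overlap = 0.0
    rmax = 2.0 * ghosts.radii.max() * clash_scale
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(rmax):
        key = (min(i, j), max(i, j))
        if key in ghosts.same_unit_pairs:
            continue
        limit = clash_scale * (ghosts.radii[i] + ghosts.radii[j])
        d = coords[j] - coords[i]
        dist = float(np.linalg.norm(d))
        if dist >= limit or dist == 0.0:
            continue
        overlap = limit - dist
        max_overlap = max(max_overlap, overlap)
        # separate slightly past the limit so the template pull-back of the
        # next iteration does not immediately re-enter contact
        step = 0.5 * (overlap + CLASH_MARGIN) * d / dist
        push[i] -= step
        push[j] += step
    return push, max_overlap


def relax(coords: np.ndarray, ghosts: GhostTemplateSet,
          clash_scale: float = DEFAULT_CLASH_SCALE, tol: float = DEFAULT_TOL,
          max_iter: int = DEFAULT_MAX_ITER) -> RelaxResult:
    """Restore local geometry: alternate template fitting and clash removal.

    Converged when the worst atom-to-template mismatch is below ``tol`` and
    no non-bonded pair is closer than ``clash_scale`` times the sum of the
    van der Waals radii.  Hitting ``max_iter`` signals jamming; the reason
    is steric when overlaps dominate the residual, non-convergence
    otherwise.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    coords = np.array(coords, dtype=float)

    def residuals(c):
        targets, mismatch = _fit_targets(c, ghosts)
        push, overlap = _clash_pushes(c, ghosts, clash_scale)
        if ghosts.bond_index is not None:
            d = np.linalg.norm(c[ghosts.bond_index[:, 0]] - c[ghosts.bond_index[:, 1]],
                               axis=1)
            mismatch = max(mismatch, float(np.abs(d - ghosts.bond_rest).max()))
        return targets, push, mismatch, overlap

    mismatch = overlap = np.inf
    for it in range(max_iter):
        targets, push, mismatch, overlap = residuals(coords)
        if mismatch < tol and overlap <= DEFAULT_CLASH_TOL:
            return RelaxResult(coords, True, it, None, mismatch, overlap)
        coords = targets + push
    _, _, mismatch, overlap = residuals(coords)
    if mismatch < tol and overlap <= DEFAULT_CLASH_TOL:
        return RelaxResult(coords, True, max_iter, None, mismatch, overlap)
    reason = "jammed-steric" if overlap > DEFAULT_CLASH_TOL else "jammed-no-convergence"
    return RelaxResult(coords, False, max_iter, reason, mismatch, overlap)


def _expand_mode(structure: Structure, mode3: np.ndarray, ca_indices: np.ndarray):
    """Per-atom displacement: every atom follows its residue's C-alpha."""
    n = len(structure.atoms)
    ca_of_res = {structure.atoms[int(i)].residue_key(): k
                 for k, i in enumerate(ca_indices)}
    full = np.zeros((n, 3))
    for i, a in enumerate(structure.atoms):
        key = a.residue_key()
        if key in ca_of_res:
            full[i] = mode3[ca_of_res[key]]
        else:
            # residue without a C-alpha (e.g. retained ligand): nearest node
            pos = a.position
            dists = [np.linalg.norm(pos - structure.atoms[int(j)].position)
                     for j in ca_indices]
            full[i] = mode3[int(np.argmin(dists))]
    return full


def run_trajectory(structure: Structure, mode: np.ndarray, direction: str,
                   ghosts: GhostTemplateSet | None = None,
                   decomposition: RigidClusterDecomposition | None = None,
                   network: ConstraintNetwork | None = None,
                   max_conformers: int = 500, step_size: float = DEFAULT_STEP_SIZE,
                   record_every: int = 1, clash_scale: float = DEFAULT_CLASH_SCALE,
                   tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                   reproject: bool = True, mode_index: int | None = None) -> ConformerTrajectory:
    """Step the structure along +/- one mode, one direction.

    ``mode`` is a 3M vector over the M C-alpha nodes.  Each step displaces
    the C-alpha targets by at most ``step_size`` (the largest single
    C-alpha move), drags all atoms with their residues and relaxes.  One
    conformer is recorded every ``record_every`` accepted steps, at
    contiguous indices 0, +/-1, +/-2, ...; the run halts at
    ``max_conformers`` recorded conformers or on jamming.  With
    ``reproject`` the bias direction is re-orthogonalised against the
    current rigid-body motions after every accepted step so that large
    excursions stay meaningful; ``reproject=False`` freezes the eigenvector.
    """
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    sign = 1 if direction == "+" else -1
    mode = np.asarray(mode, float).ravel()
    ca = structure.ca_indices()
    if mode.shape[0] != 3 * len(ca):
        raise ValueError(f"mode length {mode.shape[0]} != 3 x {len(ca)} C-alpha nodes")
    if np.linalg.norm(mode) == 0:
        raise ValueError("zero mode vector")
    if step_size < 0:
        raise ValueError("step_size must be non-negative")

    params = dict(direction=direction, max_conformers=max_conformers, step_size=step_size,
                  record_every=record_every, clash_scale=clash_scale, tol=tol,
                  max_iter=max_iter, reproject=reproject)
    coords0 = structure.coords
    traj = ConformerTrajectory(structure, mode_index, {0: coords0.copy()},
                               step_parameters=params)

    if step_size < 1e-10:
        for k in range(1, max_conformers + 1):
            traj.conformers[sign * k] = coords0.copy()
        traj.degenerate = True
        _set_halt(traj, sign, "completed")
        return traj

    if ghosts is None:
        if network is None:
            network = build_network(structure)
        if decomposition is None:
            decomposition = pebble_game(network)
        ghosts = build_ghosts(structure, decomposition, network)

    mode3 = mode.reshape(-1, 3).copy()
    mode3 /= np.linalg.norm(mode3, axis=1).max()

    from collections import deque

    coords = coords0.copy()
    halt = "completed"
    recorded = 0
    accepted = 0
    window: deque[float] = deque(maxlen=STALL_WINDOW)
    while recorded < max_conformers:
        bias_ca = sign * step_size * mode3
        bias = _expand_mode(structure, bias_ca, ca)
        result = relax(coords + bias, ghosts, clash_scale, tol, max_iter)
        if not result.converged:
            halt = result.jam_reason
            break
        # realised fraction of the intended step; blocked motion relaxes
        # back onto valid geometry, so vanishing mean progress is a jam
        achieved = result.coords[ca] - coords[ca]
        window.append(float(np.sum(achieved * bias_ca) / np.sum(bias_ca * bias_ca)))
        if len(window) == STALL_WINDOW and float(np.mean(window)) < STALL_MEAN:
            halt = _diagnose_jam(coords, bias, bias_ca, ca, ghosts, tol, max_iter)
            break
        coords = result.coords
        accepted += 1
        if accepted % record_every == 0:
            recorded += 1
            traj.conformers[sign * recorded] = coords.copy()
        if reproject:
            mode3 = _reproject(mode3, coords[ca])
            if mode3 is None:
                halt = "completed"
                break
    _set_halt(traj, sign, halt)
    return traj


def _diagnose_jam(coords, bias, bias_ca, ca, ghosts, tol, max_iter) -> str:
    """Steric jam if the step would succeed with clash resolution disabled."""
    free = relax(coords + bias, ghosts, clash_scale=0.0, tol=tol, max_iter=max_iter)
    if not free.converged:
        return "jammed-no-convergence"
    achieved = free.coords[ca] - coords[ca]
    progress = float(np.sum(achieved * bias_ca) / np.sum(bias_ca * bias_ca))
    return "jammed-steric" if progress >= 2 * STALL_MEAN else "jammed-no-convergence"


def _reproject(mode3: np.ndarray, ca_coords: np.ndarray):
    from .enm import rigid_body_basis

    flat = mode3.ravel().copy()
    basis = rigid_body_basis(ca_coords)
    flat -= basis @ (basis.T @ flat)
    m = flat.reshape(-1, 3)
    peak = np.linalg.norm(m, axis=1).max()
    if peak < 1e-9:
        return None
    return m / peak


def _set_halt(traj: ConformerTrajectory, sign: int, reason: str):
    if sign > 0:
        traj.halt_reason_pos = reason
    else:
        traj.halt_reason_neg = reason


def combine_directions(pos: ConformerTrajectory, neg: ConformerTrajectory) -> ConformerTrajectory:
    """Merge a '+' and a '-' run on the same structure into one trajectory."""
    if pos.structure is not neg.structure and len(pos.structure.atoms) != len(neg.structure.atoms):
        raise ValueError("trajectories come from different structures")
    conformers = dict(neg.conformers)
    conformers.update(pos.conformers)
    return ConformerTrajectory(pos.structure, pos.mode_index, conformers,
                               pos.halt_reason_pos, neg.halt_reason_neg,
                               {"pos": pos.step_parameters, "neg": neg.step_parameters},
                               pos.degenerate or neg.degenerate)
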