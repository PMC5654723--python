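"""Observables over conformer trajectories.

Pairwise site distances, domain-midpoint distances, least-squares
superposition (Kabsch), and the swing-twist decomposition of inter-domain
rotations into a hinge-bending "tilt" and an axial "twist" angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import DomainAnnotation, Structure, domain_atom_indices

__all__ = [
    "DistanceSeries",
    "InterfaceAngleSeries",
    "kabsch",
    "kabsch_rmsd",
    "pair_distance",
    "domain_midpoint_distance",
    "tilt_twist",
    "interface_mobility_summary",
    "crystal_form_proximity",
]


@dataclass
class DistanceSeries:
    label: str
    values: dict[int, float]

    def min(self) -> float:
        return min(self.values.values())

    def max(self) -> float:
        return max(self.values.values())

    def as_arrays(self):
        idx = sorted(self.values)
        return np.array(idx), np.array([self.values[i] for i in idx])


@dataclass
class InterfaceAngleSeries:
    interface: tuple[str, str]
    tilt: dict[int, float] = field(default_factory=dict)      # degrees, [0, 180]
    twist: dict[int, float] = field(default_factory=dict)     # degrees, (-180, 180]
    reference: object = 0

    def tilt_range(self) -> float:
        vals = list(self.tilt.values())
        return max(vals) - min(vals) if vals else 0.0

    def twist_range(self) -> float:
        vals = list(self.twist.values())
        return max(vals) - min(vals) if vals else 0.0

    def combined_range(self) -> float:
        return self.tilt_range() + self.twist_range()


# ---------------------------------------------------------------------------
# Superposition

def kabsch(p: np.ndarray, q: np.ndarray):
    """Optimal proper rotation R and translation t mapping p onto q.

    Returns ``(R, t, rmsd)`` with ``q ~ p @ R.T + t`` in the least-squares
    sense; det(R) = +1 always.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if len(p) < 3:
        raise ValueError("need >= 3 paired points for superposition")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    s = np.linalg.svd(p0, compute_uv=False)
    if s[1] <= 1e-10 * max(1.0, s[0]):
        raise ValueError("degenerate geometry: points are collinear")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = qc - r @ pc
    diff = (p @ r.T + t) - q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return r, t, rmsd


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                pairing: np.ndarray | None = None):
    """Superpose two point sets (optionally re-paired) -> (R, t, rmsd)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if pairing is not None:
        pairing = np.asarray(pairing)
        a = a[pairing[:, 0]]
        b = b[pairing[:, 1]]
    return kabsch(a, b)


# ---------------------------------------------------------------------------
# Distance series

def pair_distance(trajectory, site_1, site_2) -> DistanceSeries:
    """Per-conformer distance between two named atoms.

    Sites are ``(chain, residue_number, atom_name)`` tuples.
    """
    s = trajectory.structure
    try:
        i = s.atom_index(*site_1)
    except KeyError as exc:
        raise KeyError(f"site_1 {site_1}: {exc}") from exc
    try:
        j = s.atom_index(*site_2)
    except KeyError as exc:
        raise KeyError(f"site_2 {site_2}: {exc}") from exc
    values = {idx: float(np.linalg.norm(c[i] - c[j]))
              for idx, c in trajectory.conformers.items()}
    label = f"{site_1[0]}:{site_1[1]}:{site_1[2]}-{site_2[0]}:{site_2[1]}:{site_2[2]}"
    return DistanceSeries(label, values)


def domain_midpoint_distance(trajectory, domain_1: str, domain_2: str,
                             annotation: DomainAnnotation,
                             structure_convention: str = "mature") -> DistanceSeries:
    """Distance between unweighted C-alpha centroids of two domains."""
    from .structure import assign_domains

    s = assign_domains(trajectory.structure, annotation, structure_convention)
    idx1 = domain_atom_indices(s, domain_1, "CA")
    idx2 = domain_atom_indices(s, domain_2, "CA")
    if len(idx1) == 0:
        raise ValueError(f"domain {domain_1!r} has no C-alpha atoms")
    if len(idx2) == 0:
        raise ValueError(f"domain {domain_2!r} has no C-alpha atoms")
    values = {}
    for idx, c in trajectory.conformers.items():
        values[idx] = float(np.linalg.norm(c[idx1].mean(axis=0) - c[idx2].mean(axis=0)))
    return DistanceSeries(f"mid:{domain_1}-{domain_2}", values)


# ---------------------------------------------------------------------------
# Tilt / twist

def _swing_twist_angles(rot: Rotation, axis: np.ndarray):
    """Decompose a rotation into swing (tilt) and twist about ``axis``.

    twist is the signed rotation component about the axis in (-180, 180];
    tilt is the remaining swing angle in [0, 180].
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z, w = rot.as_quat()
    v = np.array([x, y, z])
    proj = np.dot(v, axis) * axis
    q_twist = np.array([proj[0], proj[1], proj[2], w])
    n = np.linalg.norm(q_twist)
    if n < 1e-12:
        # 180 degree swing exactly perpendicular to the axis
        return 180.0, 0.0
    q_twist /= n
    twist_rot = Rotation.from_quat(q_twist)
    swing_rot = rot * twist_rot.inv()
    tilt = float(np.degrees(swing_rot.magnitude()))
    twist = float(np.degrees(2.0 * np.arctan2(np.dot(v, axis), w)))
    if twist <= -180.0:
        twist += 360.0
    elif twist > 180.0:
        twist -= 360.0
    return tilt, twist


def tilt_twist(trajectory, interface: tuple[str, str], annotation: DomainAnnotation,
               reference=0, structure_convention: str = "mature") -> InterfaceAngleSeries:
    """Per-conformer tilt/twist of ``interface[1]`` relative to ``interface[0]``.

    Each conformer is first superposed onto the reference on the first
    domain's C-alpha atoms; the residual rotation carrying the reference's
    second domain onto the conformer's is then decomposed by swing-twist
    about the reference inter-centroid axis.  Both angles are zero at the
    reference by construction.

    ``reference`` is a conformer index or an external :class:`Structure`
    (restricted to residues present in both).
    """
    from .structure import assign_domains

    dom1, dom2 = interface
    s = assign_domains(trajectory.structure, annotation, structure_convention)
    idx1 = domain_atom_indices(s, dom1, "CA")
    idx2 = domain_atom_indices(s, dom2, "CA")
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError(f"interface {interface}: need >= 3 C-alpha per domain")

    if isinstance(reference, Structure):
        ref1, ref2 = _matched_reference_coords(s, reference, annotation,
                                               dom1, dom2, structure_convention)
        ref_label = reference.source_id or "external"
        # restrict trajectory indices to the matched residues
        idx1, idx2 = ref1[0], ref2[0]
        ref1, ref2 = ref1[1], ref2[1]
    else:
        ref_coords = trajectory.conformers[reference]
        ref1, ref2 = ref_coords[idx1], ref_coords[idx2]
        ref_label = reference

    axis = ref2.mean(axis=0) - ref1.mean(axis=0)
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("coincident domain centroids in the reference")

    series = InterfaceAngleSeries(interface, reference=ref_label)
    for idx, c in sorted(trajectory.conformers.items()):
        # frame of the first domain
        r1, t1, _ = kabsch(c[idx1], ref1)
        c_al = c @ r1.T + t1
        r2, _, _ = kabsch(ref2, c_al[idx2])
        tilt, twist = _swing_twist_angles(Rotation.from_matrix(r2), axis)
        series.tilt[idx] = tilt
        series.twist[idx] = twist
    return series


def _matched_reference_coords(s, target: Structure, annotation, dom1, dom2,
                              structure_convention):
    """C-alpha coordinates of the two domains on residues present in both."""
    from .structure import assign_domains

    t = assign_domains(target, annotation, structure_convention)
    out = []
    for dom in (dom1, dom2):
        si = domain_atom_indices(s, dom, "CA")
        ti = domain_atom_indices(t, dom, "CA")
        s_res = {(s.atoms[i].chain, s.atoms[i].residue_number): i for i in si}
        t_res = {(t.atoms[i].chain, t.atoms[i].residue_number): i for i in ti}
        shared = sorted(set(s_res) & set(t_res))
        if len(shared) < 3:
            raise ValueError(f"domain {dom}: fewer than 3 shared residues with target")
        s_idx = np.array([s_res[k] for k in shared])
        t_coords = np.array([t.atoms[t_res[k]].position for k in shared])
        out.append((s_idx, t_coords))
    return out[0], out[1]


def interface_mobility_summary(series_by_interface: dict[tuple[str, str],
                                                         list[InterfaceAngleSeries]]):
    """Pooled tilt/twist ranges per interface, ordered by combined range.

    Input maps each interface to the angle series collected over the modes
    analysed (typically 7-11).  Returns a list of dicts sorted ascending by
    combined (tilt + twist) angular range, so a stiff interface comes first.
    """
    if not series_by_interface:
        raise ValueError("no interface series supplied")
    report = []
    for interface, series_list in series_by_interface.items():
        if not series_list:
            raise ValueError(f"interface {interface}: empty series list")
        tilts = [v for s in series_list for v in s.tilt.values()]
        twists = [v for s in series_list for v in s.twist.values()]
        tilt_range = max(tilts) - min(tilts)
        twist_range = max(twists) - min(twists)
        report.append({
            "interface": interface,
            "tilt_range": tilt_range,
            "twist_range": twist_range,
            "combined_range": tilt_range + twist_range,
        })
    report.sort(key=lambda r: r["combined_range"])
    return report


def crystal_form_proximity(series: InterfaceAngleSeries, target: Structure,
                           trajectory, interface, annotation: DomainAnnotation,
                           structure_convention: str = "mature") -> float:
    """Smallest (tilt, twist) Euclidean gap from any conformer to a target.

    The target structure's angles are computed against the same reference
    as ``series`` (the trajectory's reference conformer), then the minimum
    over conformers of sqrt(dtilt^2 + dtwist^2) is returned, in degrees.
    """
    ref = series.reference if not isinstance(series.reference, str) else 0
    target_series = tilt_twist(_SingleConformer(trajectory, target), interface,
                               annotation, reference=ref,
                               structure_convention=structure_convention)
    t_tilt = next(iter(target_series.tilt.values()))
    t_twist = next(iter(target_series.twist.values()))
    best = np.inf
    for idx in series.tilt:
        gap = np.hypot(series.tilt[idx] - t_tilt, series.twist[idx] - t_twist)
        best = min(best, float(gap))
    return best


class _SingleConformer:
    """Trajectory view carrying the reference conformer plus a target frame.

    Index 0 keeps the original reference so angle decomposition uses the
    same axis; index 1 is the external structure mapped onto the
    trajectory's atom ordering by (chain, residue, atom name).
    """

    def __init__(self, trajectory, target: Structure):
        s = trajectory.structure
        lookup = {}
        for a in target.atoms:
            lookup[(a.chain, a.residue_number, a.name)] = a.position
        coords = trajectory.conformers[0].copy()
        matched = np.zeros(len(s.atoms), dtype=bool)
        for i, a in enumerate(s.atoms):
            key = (a.chain, a.residue_number, a.name)
            if key in lookup:
                coords[i] = lookup[key]
                matched[i] = True
        if matched.sum() < 3:
            raise ValueError("target structure shares fewer than 3 atoms with trajectory")
        self.structure = s
        self.conformers = {0: trajectory.conformers[0], 1: coords}
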