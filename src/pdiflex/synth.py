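"""Download-free synthetic multi-domain test structures.

Poly-alanine chains are built residue by residue from ideal internal
coordinates (NeRF construction).  Domains are alpha-helical segments --
dense in backbone hydrogen bonds, hence rigid under the default constraint
network -- joined by short extended linkers with no hydrogen bonds, hence
flexible.  The ``dumbbell`` geometry gives two domains with a single hinge;
``horseshoe`` gives four domains curled into a C with two marked
active-site residues on the outer domains, emulating the a-b-b'-a'
architecture of protein disulfide isomerase at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import AtomRecord, DomainAnnotation, Structure

__all__ = ["SyntheticSpec", "make_structure", "default_annotation",
           "apply_known_motion", "Hinge", "Twist", "Translate", "GenerationError"]

# ideal backbone internal coordinates (A, degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
B_C_O, B_CA_CB = 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O, A_C_CA_CB = 120.8, 110.1
IMPROPER_N_C_CA_CB = -122.6
OMEGA = 180.0

HELIX = (-57.0, -47.0)
EXTENDED = (-120.0, 130.0)
# two-residue turn that folds a helix back onto itself into an antiparallel
# hairpin (centroid separation ~8 A), giving compact two-helix domains
TURN = [(160.0, -40.0), (-40.0, 80.0)]

# linker torsion schedules, frozen after inspecting the resulting shapes:
# all beta-region (no intra-linker hydrogen bonds, so the linkers stay
# flexible) but varied so the chain kinks between domains instead of
# running straight on.
DUMBBELL_LINKER = [(-80.0, 120.0), (-130.0, 140.0), (-70.0, 150.0), (-110.0, 125.0)]
HORSESHOE_LINKER = [(-148.0, 111.0), (-60.0, 108.0), (-74.0, 132.0), (-77.0, 134.0)]

MIN_NONBONDED = 1.6  # A, self-avoidance floor


class GenerationError(ValueError):
    """The requested spec produced a sterically impossible structure."""


@dataclass
class SyntheticSpec:
    n_domains: int = 2
    residues_per_domain: int = 20
    linker_length: int = 4
    geometry: str = "dumbbell"
    seed: int = 0
    jitter: float = 0.03           # A, seeded coordinate noise to break symmetry
    with_cb: bool = True
    plant_active_sites: bool = False   # rename residues to CGHC on outer domains

    def __post_init__(self):
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.geometry not in ("dumbbell", "horseshoe"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _place(a, b, c, bond, angle, torsion):
    """NeRF placement of atom d bonded to c, given chain a-b-c."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(torsion),
                   bond * np.sin(angle) * np.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _torsion_schedule(spec: SyntheticSpec):
    """Per-residue (phi, psi); linker torsions come from the frozen tables."""
    table = DUMBBELL_LINKER if spec.geometry == "dumbbell" else HORSESHOE_LINKER
    schedule: list[tuple[float, float]] = []
    regions: list[tuple[str, int, int]] = []   # (label, first_res, last_res) 1-based
    res = 0
    for d in range(spec.n_domains):
        start = res + 1
        rpd = spec.residues_per_domain
        if rpd >= 8:
            # helix-turn-helix bundle: compact, internally well-constrained
            h1 = (rpd - 2 + 1) // 2
            domain_torsions = [HELIX] * h1 + TURN + [HELIX] * (rpd - 2 - h1)
        else:
            domain_torsions = [HELIX] * rpd
        schedule.extend(domain_torsions)
        res += rpd
        regions.append((f"D{d + 1}", start, res))
        if d < spec.n_domains - 1:
            lstart = res + 1
            for k in range(spec.linker_length):
                schedule.append(table[k % len(table)])
                res += 1
            regions.append((f"L{d + 1}", lstart, res))
    return schedule, regions


def make_structure(spec: SyntheticSpec) -> Structure:
    """Build the synthetic structure; deterministic for fixed spec + seed."""
    schedule, regions = _torsion_schedule(spec)
    n_res = len(schedule)
    rng = np.random.default_rng(spec.seed)

    # backbone trace via NeRF
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([B_N_CA, 0.0, 0.0])]
    c0 = _place(np.array([0.0, 1.0, 0.0]), n_pos[0], ca_pos[0], B_CA_C, A_N_CA_C, 45.0)
    c_pos = [c0]
    for i in range(1, n_res):
        phi_prev, psi_prev = schedule[i - 1]
        n = _place(n_pos[-1], ca_pos[-1], c_pos[-1], B_C_N, A_CA_C_N, psi_prev)
        ca = _place(ca_pos[-1], c_pos[-1], n, B_N_CA, A_C_N_CA, OMEGA)
        phi, _ = schedule[i]
        c = _place(c_pos[-1], n, ca, B_CA_C, A_N_CA_C, phi)
        n_pos.append(n)
        ca_pos.append(ca)
        c_pos.append(c)

    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n_res):
        resnum = i + 1
        entries = [("N", "N", n_pos[i]), ("CA", "C", ca_pos[i]), ("C", "C", c_pos[i])]
        if i + 1 < n_res:
            o = _place(n_pos[i + 1], ca_pos[i], c_pos[i], B_C_O, A_CA_C_O, 180.0)
        else:
            o = _place(n_pos[i], ca_pos[i], c_pos[i], B_C_O, A_CA_C_O, schedule[i][1] + 180.0)
        entries.append(("O", "O", o))
        if spec.with_cb:
            cb = _place(n_pos[i], c_pos[i], ca_pos[i], B_CA_CB, A_C_CA_CB,
                        IMPROPER_N_C_CA_CB)
            entries.append(("CB", "C", cb))
        for name, element, pos in entries:
            serial += 1
            jittered = pos + rng.normal(0.0, spec.jitter, 3)
            atoms.append(AtomRecord(serial, name, element, "A", resnum, "", "ALA",
                                    jittered))

    structure = Structure(atoms, ["A"],
                          source_id=f"synthetic-{spec.geometry}-{spec.seed}")
    if spec.plant_active_sites:
        structure = _plant_cghc(structure, spec, regions)
    _check_self_avoidance(structure)
    ann = default_annotation(spec)
    structure.domain_labels = [ann.label_of(a.residue_number) for a in structure.atoms]
    return structure


def _plant_cghc(structure: Structure, spec: SyntheticSpec, regions):
    """Rename four residues near the tip of each outer domain to CGHC."""
    domains = [r for r in regions if r[0].startswith("D")]
    first, last = domains[0], domains[-1]
    # outer tips: near the free end of the first and last domains
    sites = [first[1] + 1, last[2] - 4]
    rename = {}
    for start in sites:
        for offset, name in enumerate(("CYS", "GLY", "HIS", "CYS")):
            rename[start + offset] = name
    atoms = []
    for a in structure.atoms:
        name = rename.get(a.residue_number, a.residue_name)
        if name == "GLY" and a.name == "CB":
            continue  # glycine has no side chain
        atoms.append(replace(a, residue_name=name))
    atoms = [replace(a, serial=k + 1) for k, a in enumerate(atoms)]
    return Structure(atoms, list(structure.chains), list(structure.missing_ranges),
                     structure.source_id)


def _check_self_avoidance(structure: Structure):
    from scipy.spatial import cKDTree

    coords = structure.coords
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(MIN_NONBONDED):
        ri = structure.atoms[i].residue_number
        rj = structure.atoms[j].residue_number
        if abs(ri - rj) > 1:
            raise GenerationError(
                f"steric overlap between residues {ri} and {rj} "
                f"({np.linalg.norm(coords[i] - coords[j]):.2f} A)")


def default_annotation(spec: SyntheticSpec) -> DomainAnnotation:
    """Domain table matching the generator's layout (mature numbering)."""
    _, regions = _torsion_schedule(spec)
    domains = [(label, [(start, end)]) for label, start, end in regions
               if label.startswith("D")]
    return DomainAnnotation(domains, "mature", 0)


# ---------------------------------------------------------------------------
# Known rigid motions (oracle factory for the motion analytics)

@dataclass
class Hinge:
    angle: float                       # degrees
    axis: np.ndarray | None = None     # default: normal of the bend plane
    pivot: np.ndarray | None = None    # default: adjacent linker centroid


@dataclass
class Twist:
    angle: float                       # degrees, about the inter-centroid axis


@dataclass
class Translate:
    vector: np.ndarray = field(default_factory=lambda: np.zeros(3))


def apply_known_motion(structure: Structure, motion, moving_domain: str) -> Structure:
    """Rigidly transform one domain; linker atoms are interpolated.

    The structure must carry domain labels (``make_structure`` attaches
    them; otherwise call ``assign_domains`` first).  Linker residues
    adjacent to the moving domain get a fraction of the transform that
    ramps from 0 at the fixed side to 1 at the moving side.
    """
    if structure.domain_labels is None:
        raise ValueError("structure has no domain labels")
    labels = structure.domain_labels
    if moving_domain not in labels:
        raise ValueError(f"unknown domain {moving_domain!r}")
    coords = structure.coords
    moving = np.array([lab == moving_domain for lab in labels])
    fixed = np.array([lab not in (moving_domain, "unassigned") for lab in labels])

    # centroids over C-alpha atoms, matching the observables in the motion
    # analytics (all-atom centroids tilt the axis by a fraction of a degree)
    is_ca = np.array([a.name == "CA" for a in structure.atoms])
    mov_sel = moving & is_ca if (moving & is_ca).any() else moving
    fix_sel = fixed & is_ca if (fixed & is_ca).any() else fixed
    mov_centroid = coords[mov_sel].mean(axis=0)
    fixed_centroid = coords[fix_sel].mean(axis=0) if fix_sel.any() else coords.mean(axis=0)

    weights = _linker_weights(structure, moving_domain)

    if isinstance(motion, Translate):
        delta = np.asarray(motion.vector, float)
        new = coords + np.outer(np.where(moving, 1.0, weights), delta)
        return structure.with_coords(new)

    if isinstance(motion, Twist):
        axis = mov_centroid - fixed_centroid
        axis /= np.linalg.norm(axis)
        pivot = mov_centroid
        angle = motion.angle
    elif isinstance(motion, Hinge):
        pivot = motion.pivot
        if pivot is None:
            pivot = _adjacent_linker_centroid(structure, moving_domain, coords)
        axis = motion.axis
        if axis is None:
            v1 = mov_centroid - pivot
            v2 = fixed_centroid - pivot
            axis = np.cross(v1, v2)
            if np.linalg.norm(axis) < 1e-9:
                axis = np.array([0.0, 0.0, 1.0])
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        angle = motion.angle
    else:
        raise TypeError(f"unknown motion {motion!r}")

    if angle == 0.0:
        return structure.with_coords(coords)
    new = coords.copy()
    frac = np.where(moving, 1.0, weights)
    for f in np.unique(frac[frac > 0]):
        rot = Rotation.from_rotvec(np.deg2rad(angle * f) * axis)
        sel = frac == f
        new[sel] = rot.apply(coords[sel] - pivot) + pivot
    return structure.with_coords(new)


def _linker_weights(structure: Structure, moving_domain: str) -> np.ndarray:
    """Per-atom interpolation weight for unassigned (linker) residues."""
    labels = structure.domain_labels
    residues = structure.residues()
    res_label = {}
    for ch, num, ic, _ in residues:
        for a, lab in zip(structure.atoms, labels):
            if a.chain == ch and a.residue_number == num and a.insertion_code == ic:
                res_label[(ch, num, ic)] = lab
                break
    keys = [(ch, num, ic) for ch, num, ic, _ in residues]
    weights_by_res = {k: 0.0 for k in keys}
    runs = _unassigned_runs(keys, res_label)
    for run in runs:
        before = keys.index(run[0]) - 1
        after = keys.index(run[-1]) + 1
        before_lab = res_label[keys[before]] if before >= 0 else None
        after_lab = res_label[keys[after]] if after < len(keys) else None
        if after_lab == moving_domain and before_lab != moving_domain:
            for p, k in enumerate(run, start=1):
                weights_by_res[k] = p / (len(run) + 1)
        elif before_lab == moving_domain and after_lab != moving_domain:
            for p, k in enumerate(run, start=1):
                weights_by_res[k] = 1.0 - p / (len(run) + 1)
    return np.array([weights_by_res[a.residue_key()] for a in structure.atoms])


def _unassigned_runs(keys, res_label):
    runs, current = [], []
    for k in keys:
        if res_label[k] == "unassigned":
            current.append(k)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def _adjacent_linker_centroid(structure: Structure, moving_domain: str, coords):
    labels = structure.domain_labels
    dom_res = [a.residue_number for a, lab in zip(structure.atoms, labels)
               if lab == moving_domain]
    lo, hi = min(dom_res), max(dom_res)
    adjacent = [i for i, (a, lab) in enumerate(zip(structure.atoms, labels))
                if lab == "unassigned" and (abs(a.residue_number - lo) <= 6
                                            or abs(a.residue_number - hi) <= 6)]
    if adjacent:
        return coords[adjacent].mean(axis=0)
    return coords.mean(axis=0)
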