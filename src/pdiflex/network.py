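"""Typed distance-constraint network over atoms.

Edges carry a bar multiplicity in the body-bar convention: every atom is a
6-degree-of-freedom body, a rotatable single bond contributes 5 bars, a bond
with locked torsion (peptide, carbonyl double bond, disulfide) 6 bars, a
hydrogen bond 5 bars and a hydrophobic tether 2 bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["ConstraintEdge", "ConstraintNetwork", "build_network"]

BARS_SINGLE = 5
BARS_LOCKED = 6
BARS_HBOND = 5
BARS_TETHER = 2

# Intra-residue heavy-atom bonds: (atom1, atom2, bars).  The carbonyl C=O is
# torsion-locked; everything else here is a rotatable single bond.
_BACKBONE = [("N", "CA", BARS_SINGLE), ("CA", "C", BARS_SINGLE), ("C", "O", BARS_LOCKED),
             ("C", "OXT", BARS_SINGLE)]
RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, int]]] = {
    "GLY": list(_BACKBONE),
    "ALA": _BACKBONE + [("CA", "CB", BARS_SINGLE)],
    "CYS": _BACKBONE + [("CA", "CB", BARS_SINGLE), ("CB", "SG", BARS_SINGLE)],
    "SER": _BACKBONE + [("CA", "CB", BARS_SINGLE), ("CB", "OG", BARS_SINGLE)],
    "HIS": _BACKBONE + [("CA", "CB", BARS_SINGLE), ("CB", "CG", BARS_SINGLE),
                        ("CG", "ND1", BARS_LOCKED), ("CG", "CD2", BARS_LOCKED),
                        ("ND1", "CE1", BARS_LOCKED), ("CD2", "NE2", BARS_LOCKED),
                        ("CE1", "NE2", BARS_LOCKED)],
}

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP", "CYS", "GLY"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

PEPTIDE_BOND_MAX = 2.0      # A, C(i)-N(i+1) sanity cutoff
DISULFIDE_MAX = 2.5         # A, SG-SG
CA_PSEUDO_BOND_MAX = 4.5    # A, coarse Ca-trace chaining
_COVALENT_FALLBACK = 1.9    # A, generic heavy-heavy bond guess
_COVALENT_FALLBACK_S = 2.2  # A, when sulfur involved


@dataclass(frozen=True)
class ConstraintEdge:
    i: int
    j: int
    kind: str            # covalent | hydrogen-bond | hydrophobic-tether
    bars: int
    rest_length: float


@dataclass
class ConstraintNetwork:
    n_atoms: int
    edges: list[ConstraintEdge] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e.i == e.j:
                raise ValueError(f"self-edge on atom {e.i}")
            key = (min(e.i, e.j), max(e.i, e.j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def edges_of_kind(self, kind: str) -> list[ConstraintEdge]:
        return [e for e in self.edges if e.kind == kind]

    def covalent_adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for e in self.edges:
            if e.kind == "covalent":
                adj[e.i].add(e.j)
                adj[e.j].add(e.i)
        return adj


def build_network(structure: Structure, hbond_distance_max: float = 3.5,
                  hbond_angle_min: float = 90.0, hydrophobic_cutoff: float = 3.9,
                  max_tethers_per_atom: int = 3) -> ConstraintNetwork:
    """Build the covalent / hydrogen-bond / hydrophobic-tether network.

    Covalent edges come from residue topology templates plus inter-residue
    peptide bonds and disulfides; hydrogen bonds from heavy-atom
    donor-acceptor geometry (distance <= ``hbond_distance_max``, angle at the
    donor >= ``hbond_angle_min``); tethers between apolar side-chain C/S
    atoms within ``hydrophobic_cutoff`` (at most ``max_tethers_per_atom``
    per atom, nearest first).  Covalent edges never span a recorded chain
    break, and edge kinds are resolved with priority
    covalent > hydrogen bond > tether.
    """
    atoms = structure.atoms
    if len(atoms) < 2:
        raise ValueError("need at least 2 atoms to build a constraint network")
    coords = structure.coords
    missing = set()
    for chain, start, end in structure.missing_ranges:
        for r in range(start, end + 1):
            missing.add((chain, r))

    # group atoms by residue, in file order
    res_order: list[tuple] = []
    res_atoms: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(atoms):
        key = a.residue_key()
        if key not in res_atoms:
            res_atoms[key] = {}
            res_order.append(key)
        res_atoms[key].setdefault(a.name, i)

    pairs: dict[tuple[int, int], tuple[str, int]] = {}

    def add(i, j, kind, bars):
        if i == j:
            return
        key = (min(i, j), max(i, j))
        rank = {"covalent": 2, "hydrogen-bond": 1, "hydrophobic-tether": 0}
        if key in pairs and rank[pairs[key][0]] >= rank[kind]:
            return
        pairs[key] = (kind, bars)

    # --- intra-residue covalent bonds from templates
    warned: set[str] = set()
    for key in res_order:
        names = res_atoms[key]
        resname = atoms[next(iter(names.values()))].residue_name
        template = RESIDUE_TEMPLATES.get(resname)
        if template is None:
            if resname not in warned and len(names) > 1:
                warnings.warn(f"no topology template for residue {resname}; "
                              "using distance-based bonding", stacklevel=2)
                warned.add(resname)
            idx = list(names.values())
            for ii in idx:
                for jj in idx:
                    if ii < jj:
                        cut = (_COVALENT_FALLBACK_S
                               if "S" in (atoms[ii].element, atoms[jj].element)
                               else _COVALENT_FALLBACK)
                        if np.linalg.norm(coords[ii] - coords[jj]) <= cut:
                            add(ii, jj, "covalent", BARS_SINGLE)
        else:
            for n1, n2, bars in template:
                if n1 in names and n2 in names:
                    add(names[n1], names[n2], "covalent", bars)

    # --- peptide bonds between consecutive residues (torsion-locked),
    #     with a Ca-Ca pseudo-bond fallback for coarse traces
    for k1, k2 in zip(res_order, res_order[1:]):
        (c1, r1, _), (c2, r2, _) = k1, k2
        if c1 != c2 or r2 != r1 + 1 or (c1, r1) in missing or (c2, r2) in missing:
            continue  # numbering gap or recorded missing region: chain break
        n1, n2 = res_atoms[k1], res_atoms[k2]
        if "C" in n1 and "N" in n2:
            if np.linalg.norm(coords[n1["C"]] - coords[n2["N"]]) <= PEPTIDE_BOND_MAX:
                add(n1["C"], n2["N"], "covalent", BARS_LOCKED)
        elif "CA" in n1 and "CA" in n2 and len(n1) == 1 and len(n2) == 1:
            # coarse Ca-only trace: chain successive Ca beads
            if np.linalg.norm(coords[n1["CA"]] - coords[n2["CA"]]) <= CA_PSEUDO_BOND_MAX:
                add(n1["CA"], n2["CA"], "covalent", BARS_SINGLE)

    # --- disulfides
    sg = [i for i, a in enumerate(atoms) if a.name == "SG"]
    for ii in range(len(sg)):
        for jj in range(ii + 1, len(sg)):
            if np.linalg.norm(coords[sg[ii]] - coords[sg[jj]]) <= DISULFIDE_MAX:
                add(sg[ii], sg[jj], "covalent", BARS_LOCKED)

    cov_adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for (i, j), (kind, _) in pairs.items():
        if kind == "covalent":
            cov_adj[i].add(j)
            cov_adj[j].add(i)

    def bonded_within(i, j, max_bonds):
        """Covalent graph distance between i and j is <= max_bonds."""
        frontier = {i}
        seen = {i}
        for _ in range(max_bonds):
            frontier = {b for a in frontier for b in cov_adj[a]} - seen
            if j in frontier:
                return True
            seen |= frontier
        return False

    def bonded_within_two(i, j):
        return bonded_within(i, j, 2)

    # --- hydrogen bonds: heavy-atom donor-acceptor geometry
    donors = [i for i, a in enumerate(atoms) if a.element == "N"
              or (a.element == "O" and a.name in ("OG", "OH", "OG1"))]
    acceptors = [i for i, a in enumerate(atoms) if a.element == "O"]
    if donors and acceptors:
        tree = cKDTree(coords[acceptors])
        for d_idx in donors:
            for hit in tree.query_ball_point(coords[d_idx], hbond_distance_max):
                a_idx = acceptors[hit]
                # donors separated from the acceptor by 3 covalent bonds or
                # fewer (e.g. backbone N(i)-O(i)) are local geometry, not
                # hydrogen bonds
                if a_idx == d_idx or bonded_within(d_idx, a_idx, 3):
                    continue
                if _donor_angle_ok(coords, cov_adj, d_idx, a_idx, hbond_angle_min):
                    add(d_idx, a_idx, "hydrogen-bond", BARS_HBOND)

    # --- hydrophobic tethers
    apolar = [i for i, a in enumerate(atoms)
              if a.residue_name in APOLAR_RESIDUES and a.element in ("C", "S")
              and a.name not in _BACKBONE_NAMES]
    if apolar:
        tree = cKDTree(coords[apolar])
        cand: dict[int, list[tuple[float, int]]] = {i: [] for i in apolar}
        for pi, pj in tree.query_pairs(hydrophobic_cutoff):
            i, j = apolar[pi], apolar[pj]
            if bonded_within_two(i, j) or atoms[i].residue_key() == atoms[j].residue_key():
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            cand[i].append((d, j))
            cand[j].append((d, i))
        count = {i: 0 for i in apolar}
        flat = sorted((d, min(i, j), max(i, j)) for i, lst in cand.items() for d, j in lst if i < j)
        for d, i, j in flat:
            if count[i] < max_tethers_per_atom and count[j] < max_tethers_per_atom:
                add(i, j, "hydrophobic-tether", BARS_TETHER)
                count[i] += 1
                count[j] += 1

    edges = [ConstraintEdge(i, j, kind, bars, float(np.linalg.norm(coords[i] - coords[j])))
             for (i, j), (kind, bars) in sorted(pairs.items())]
    return ConstraintNetwork(len(atoms), edges)


def _donor_angle_ok(coords, cov_adj, donor, acceptor, angle_min):
    """Angle antecedent-donor-acceptor >= angle_min for some antecedent."""
    antecedents = cov_adj.get(donor, ())
    if not antecedents:
        return True  # no geometry available: accept on distance alone
    v_da = coords[acceptor] - coords[donor]
    n_da = np.linalg.norm(v_da)
    for ant in antecedents:
        v_ant = coords[ant] - coords[donor]
        denom = np.linalg.norm(v_ant) * n_da
        if denom == 0:
            continue
        cosang = np.dot(v_ant, v_da) / denom
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= angle_min:
            return True
    return False
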