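"""All-atom structure container, PDB reading/writing and domain annotation.

Coordinates are in Angstrom throughout.  Residue numbering is taken verbatim
from the source file (1-based in standard PDB files); the mature vs
translation-product numbering conventions used in the PDI literature are
handled by a single integer offset on :class:`DomainAnnotation`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "DomainAnnotation",
    "ActiveSitePair",
    "PDBParseError",
    "EmptyStructureError",
    "StructuralMismatchError",
    "ActiveSiteError",
    "parse_pdb",
    "parse_pdb_text",
    "write_structure",
    "write_ensemble",
    "locate_active_sites",
    "assign_domains",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Malformed coordinate record; message names the offending line."""


class EmptyStructureError(ValueError):
    """No ATOM records found in the input."""


class StructuralMismatchError(ValueError):
    """Conformers in an ensemble disagree in atom count or ordering."""


class ActiveSiteError(ValueError):
    """Structure does not contain the expected pair of CGHC motifs."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False

    def residue_key(self):
        return (self.chain, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered collection of atoms with chain-break bookkeeping."""

    atoms: list[AtomRecord]
    chains: list[str]
    missing_ranges: list[tuple[str, int, int]] = field(default_factory=list)
    source_id: str = ""
    domain_labels: list[str] | None = None

    def __len__(self):
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a fresh copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructuralMismatchError(
                f"coordinate array shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        new_atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(new_atoms, list(self.chains), list(self.missing_ranges),
                         self.source_id, list(self.domain_labels) if self.domain_labels else None)

    def atom_index(self, chain: str, residue_number: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.residue_number == residue_number and a.name == atom_name:
                return i
        raise KeyError(f"atom {atom_name} of {chain}:{residue_number} not found")

    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=int)

    def residues(self):
        """Ordered unique residues as (chain, resnum, icode, resname)."""
        seen, out = set(), []
        for a in self.atoms:
            key = a.residue_key()
            if key not in seen:
                seen.add(key)
                out.append((a.chain, a.residue_number, a.insertion_code, a.residue_name))
        return out

    def chain_sequence(self, chain: str):
        """List of (residue_number, one_letter) for one chain, file order."""
        out = []
        for ch, num, _ic, name in self.residues():
            if ch == chain:
                out.append((num, THREE_TO_ONE.get(name, "X")))
        return out


@dataclass
class DomainAnnotation:
    """Named residue ranges (e.g. the PDI regions a, b, b', x, a', c).

    ``numbering_convention`` is ``"mature"`` or ``"translation-product"``;
    translation-product numbers = mature numbers + ``offset`` (default +17,
    the signal-peptide length of human PDI).
    """

    domains: list[tuple[str, list[tuple[int, int]]]]
    numbering_convention: str = "mature"
    offset: int = 17

    def __post_init__(self):
        if self.numbering_convention not in ("mature", "translation-product"):
            raise ValueError(f"unknown numbering convention {self.numbering_convention!r}")
        spans = []
        for name, ranges in self.domains:
            for start, end in ranges:
                if end < start:
                    raise ValueError(f"domain {name}: inverted range {start}-{end}")
                spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping domain ranges: {n1} {s1}-{e1} and {n2} {s2}-{e2}")

    def to_convention(self, convention: str) -> "DomainAnnotation":
        if convention == self.numbering_convention:
            return self
        shift = self.offset if convention == "translation-product" else -self.offset
        shifted = [(name, [(s + shift, e + shift) for s, e in ranges])
                   for name, ranges in self.domains]
        return DomainAnnotation(shifted, convention, self.offset)

    def label_of(self, residue_number: int) -> str:
        for name, ranges in self.domains:
            for start, end in ranges:
                if start <= residue_number <= end:
                    return name
        return "unassigned"

    def domain_names(self):
        return [name for name, _ in self.domains]


@dataclass
class ActiveSitePair:
    """The exposed (N-terminal) active-site cysteines of the two CGHC motifs."""

    site_a: tuple[str, int]
    site_a_prime: tuple[str, int]


# ---------------------------------------------------------------------------
# PDB parsing

_REMARK465_RE = re.compile(r"^REMARK 465\s+[A-Z]{2,3}\s+(\w)\s+(-?\d+)\s*$")


def parse_pdb(path, altloc_policy: str = "highest-occupancy", model_policy="first",
              keep_hetatm: bool = False, source_id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    altloc_policy : ``"highest-occupancy"`` (ties broken by altloc letter) or
        ``"first"`` (first record encountered wins).
    model_policy : ``"first"`` or an integer model number to select from a
        multi-model file.
    keep_hetatm : retain non-water HETATM records (e.g. bound ligands) as
        steric-only bodies.  Waters are always dropped.
    """
    with open(path) as fh:
        text = fh.read()
    sid = source_id if source_id is not None else str(path)
    return parse_pdb_text(text, altloc_policy, model_policy, keep_hetatm, sid)


def parse_pdb_text(text: str, altloc_policy: str = "highest-occupancy", model_policy="first",
                   keep_hetatm: bool = False, source_id: str = "") -> Structure:
    if altloc_policy not in ("highest-occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    want_model = None if model_policy == "first" else int(model_policy)
    current_model = None
    model_done = False
    atoms: list[AtomRecord] = []
    remark_missing: list[tuple[str, int]] = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            current_model = int(line[10:14]) if line[10:14].strip() else (current_model or 0) + 1
            if want_model is None and atoms:
                model_done = True
        elif rec == "ENDMDL":
            if atoms and (want_model is None or current_model == want_model):
                model_done = True
        elif line.startswith("REMARK 465"):
            m = _REMARK465_RE.match(line.rstrip())
            if m:
                remark_missing.append((m.group(1), int(m.group(2))))
        elif rec in ("ATOM  ", "HETATM"):
            if model_done:
                continue
            if want_model is not None and current_model is not None and current_model != want_model:
                continue
            is_het = rec == "HETATM"
            resname = line[17:20].strip()
            if is_het and (resname in _WATER_NAMES or not keep_hetatm):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16].strip()
                chain = line[21].strip() or " "
                resnum = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed coordinate record at line {lineno}: {line!r}") from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _element_from_name(name)
            pos = np.array([x, y, z], dtype=float)
            if not np.all(np.isfinite(pos)):
                raise PDBParseError(f"non-finite coordinates at line {lineno}")
            atoms.append(AtomRecord(serial, name, element, chain, resnum, icode,
                                    resname, pos, occ, bfac, is_het))
            atoms[-1]._altloc = altloc  # transient, resolved below

    if not atoms:
        raise EmptyStructureError("no ATOM records found")

    atoms = _resolve_altlocs(atoms, altloc_policy)
    chains = []
    for a in atoms:
        if a.chain not in chains:
            chains.append(a.chain)
    missing = _missing_ranges(atoms, remark_missing)
    return Structure(atoms, chains, missing, source_id)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _resolve_altlocs(atoms, policy):
    groups: dict[tuple, list[AtomRecord]] = {}
    order = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.insertion_code, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            chosen = group[0]
        elif policy == "first":
            chosen = group[0]
        else:  # highest occupancy, ties by altloc letter
            chosen = sorted(group, key=lambda a: (-a.occupancy, getattr(a, "_altloc", "")))[0]
        if hasattr(chosen, "_altloc"):
            del chosen._altloc
        out.append(chosen)
    return out


def _missing_ranges(atoms, remark_missing):
    """Chain breaks from REMARK 465 when present, else from numbering gaps."""
    observed: dict[str, list[int]] = {}
    for a in atoms:
        if not a.is_hetatm:
            observed.setdefault(a.chain, [])
            if not observed[a.chain] or observed[a.chain][-1] != a.residue_number:
                observed[a.chain].append(a.residue_number)
    ranges: list[tuple[str, int, int]] = []
    if remark_missing:
        by_chain: dict[str, list[int]] = {}
        for chain, num in remark_missing:
            by_chain.setdefault(chain, []).append(num)
        for chain, nums in by_chain.items():
            span = observed.get(chain)
            for start, end in _runs(sorted(set(nums))):
                if span and span[0] < start and end < span[-1]:
                    ranges.append((chain, start, end))
    else:
        for chain, nums in observed.items():
            for prev, nxt in zip(nums, nums[1:]):
                if nxt > prev + 1:
                    ranges.append((chain, prev + 1, nxt - 1))
    return ranges


def _runs(sorted_nums):
    if not sorted_nums:
        return
    start = prev = sorted_nums[0]
    for n in sorted_nums[1:]:
        if n == prev + 1:
            prev = n
        else:
            yield (start, prev)
            start = prev = n
    yield (start, prev)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_line(a: AtomRecord, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    rec = "HETATM" if a.is_hetatm else "ATOM  "
    return (f"{rec}{serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} {a.chain:1s}"
            f"{a.residue_number:>4d}{a.insertion_code:1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}")


def write_structure(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        _write_model_atoms(fh, structure)
        fh.write("END\n")


def _write_model_atoms(fh, structure: Structure):
    prev_chain = None
    serial = 0
    for a in structure.atoms:
        if prev_chain is not None and a.chain != prev_chain:
            fh.write("TER\n")
        serial += 1
        fh.write(_format_atom_line(a, serial) + "\n")
        prev_chain = a.chain
    fh.write("TER\n")


def write_ensemble(trajectory, path) -> None:
    """Write a conformer trajectory as a multi-model PDB.

    Model 1 is the most negative conformer index, ascending through the
    input structure (index 0) to the most positive.
    """
    indices = sorted(trajectory.conformers)
    if not indices:
        raise StructuralMismatchError("empty trajectory: nothing to write")
    template = trajectory.structure
    n = len(template.atoms)
    for idx in indices:
        if trajectory.conformers[idx].shape != (n, 3):
            raise StructuralMismatchError(
                f"conformer {idx} has shape {trajectory.conformers[idx].shape}, expected ({n}, 3)")
    with open(path, "w") as fh:
        for model_num, idx in enumerate(indices, start=1):
            fh.write(f"MODEL     {model_num:>4d}\n")
            _write_model_atoms(fh, template.with_coords(trajectory.conformers[idx]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Active sites and domains

def locate_active_sites(structure: Structure) -> ActiveSitePair:
    """Find the exposed active-site cysteines of a PDI-like structure.

    Scans each chain for Cys-Gly-His-Cys tetrapeptides on consecutively
    numbered residues and returns the N-terminal cysteine of the first and
    last motifs in chain order.  Works for any residue numbering.
    """
    motifs: list[tuple[str, int]] = []
    for chain in structure.chains:
        seq = structure.chain_sequence(chain)
        for i in range(len(seq) - 3):
            nums = [seq[i + k][0] for k in range(4)]
            letters = "".join(seq[i + k][1] for k in range(4))
            if letters == "CGHC" and nums == list(range(nums[0], nums[0] + 4)):
                motifs.append((chain, nums[0]))
    if len(motifs) < 2:
        raise ActiveSiteError(
            f"expected at least two CGHC motifs, found {len(motifs)}: {motifs}")
    return ActiveSitePair(motifs[0], motifs[-1])


def assign_domains(structure: Structure, table: DomainAnnotation,
                   structure_convention: str = "mature") -> Structure:
    """Label every atom with a domain name (or ``"unassigned"``).

    The table's numbering convention is converted to the structure's via the
    annotation offset before ranges are applied.
    """
    table = table.to_convention(structure_convention)
    labels = [table.label_of(a.residue_number) for a in structure.atoms]
    out = Structure(structure.atoms, list(structure.chains), list(structure.missing_ranges),
                    structure.source_id, labels)
    return out


def ca_subset(structure: Structure) -> Structure:
    """C-alpha-only view of a structure (coarse-grained simulations)."""
    atoms = [a for a in structure.atoms if a.name == "CA"]
    labels = None
    if structure.domain_labels is not None:
        labels = [lab for a, lab in zip(structure.atoms, structure.domain_labels)
                  if a.name == "CA"]
    if not atoms:
        raise EmptyStructureError("structure has no C-alpha atoms")
    return Structure(atoms, list(structure.chains), list(structure.missing_ranges),
                     structure.source_id, labels)


def domain_atom_indices(structure: Structure, domain: str, atom_name: str | None = "CA") -> np.ndarray:
    """Indices of atoms labelled with ``domain`` (optionally one atom name)."""
    if structure.domain_labels is None:
        raise ValueError("structure has no domain labels; call assign_domains first")
    idx = [i for i, (a, lab) in enumerate(zip(structure.atoms, structure.domain_labels))
           if lab == domain and (atom_name is None or a.name == atom_name)]
    return np.array(idx, dtype=int)
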