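"""Atomic-structure I/O for receptor–peptide complexes.

Reads PDB and mmCIF files (through gemmi), assigns chain roles
(receptor / peptide / other), and canonicalizes noncanonical peptide
residues so that downstream atom typing can treat them as their parent
canonical residue.  Only the first model of multi-model files is kept,
altlocs are resolved to the highest-occupancy conformer, waters and
hydrogens are discarded.  Coordinates are never remodeled.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_RESIDUES = frozenset(THREE_TO_ONE)
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureError(ValueError):
    """Raised for unreadable, empty, or internally inconsistent structures."""


class ConfigurationError(ValueError):
    """Raised when a configuration references entities absent from the data."""


@dataclass
class AtomRecord:
    """One heavy atom: name, element, Cartesian coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    name3: str
    atoms: List[AtomRecord] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def res_id(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in file order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.coord for a in self.atoms])

    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")


@dataclass
class ComplexStructure:
    """A parsed complex: ordered chains of residues plus chain roles."""

    complex_id: str
    chains: Dict[str, List[ResidueRecord]]
    roles: Dict[str, str] = field(default_factory=dict)

    def residues(self, chain_id: str) -> List[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ConfigurationError(
                f"{self.complex_id}: chain {chain_id!r} not present "
                f"(available: {sorted(self.chains)})"
            ) from None

    @property
    def receptor_chain(self) -> str:
        for cid, role in self.roles.items():
            if role == "receptor":
                return cid
        raise ConfigurationError(f"{self.complex_id}: no receptor chain assigned")

    @property
    def peptide_chains(self) -> List[str]:
        return [cid for cid, role in self.roles.items() if role == "peptide"]

    def receptor_residues(self) -> List[ResidueRecord]:
        return self.chains[self.receptor_chain]

    def peptide_residues(self) -> List[ResidueRecord]:
        out: List[ResidueRecord] = []
        for cid in self.peptide_chains:
            out.extend(self.chains[cid])
        return out

    def all_residues(self) -> List[ResidueRecord]:
        out: List[ResidueRecord] = []
        for residues in self.chains.values():
            out.extend(residues)
        return out

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.all_residues())

    def copy(self) -> "ComplexStructure":
        return copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Return a rigidly moved copy (x -> R x + t applied to every atom)."""
        new = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in new.all_residues():
            for a in res.atoms:
                a.coord = R @ a.coord + t
        return new


@dataclass
class NoncanonicalEntry:
    """How one noncanonical residue maps onto a canonical parent."""

    parent: str
    atom_renames: Dict[str, str] = field(default_factory=dict)
    delete_atoms: List[str] = field(default_factory=list)
    delete_links: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parent not in CANONICAL_RESIDUES:
            raise ConfigurationError(
                f"noncanonical parent {self.parent!r} is not one of the 20 canonical residues"
            )


@dataclass
class NoncanonicalMap:
    """name3 -> parent mapping plus residues (caps) to delete outright."""

    entries: Dict[str, NoncanonicalEntry] = field(default_factory=dict)
    delete_residues: List[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: Mapping) -> "NoncanonicalMap":
        entries = {
            name: NoncanonicalEntry(
                parent=spec["parent"],
                atom_renames=dict(spec.get("atom_renames", {})),
                delete_atoms=list(spec.get("delete_atoms", [])),
                delete_links=list(spec.get("delete_links", [])),
            )
            for name, spec in data.get("entries", {}).items()
        }
        return cls(entries=entries, delete_residues=list(data.get("delete_residues", [])))


def _sort_chain(residues: List[ResidueRecord]) -> List[ResidueRecord]:
    return sorted(residues, key=lambda r: (r.seq_number, r.insertion_code))


def _resolve_altlocs(res: gemmi.Residue) -> List[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: Dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the retained atoms
    kept = set()
    out = []
    for atom in res:
        if best.get(atom.name) is atom and atom.name not in kept:
            kept.add(atom.name)
            out.append(atom)
    return out


_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
            "auto": gemmi.CoorFormat.Detect}


def read_structure(path, format: str = "auto", complex_id: Optional[str] = None) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    First model only; altlocs resolved to the highest-occupancy conformer;
    waters and hydrogens excluded; hetero residues retained and flagged.
    auth_ numbering is used for mmCIF (matches PDB-format convention).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ConfigurationError(f"unknown structure format {format!r}")
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    if len(st) > 1:
        logger.info("%s: %d models; keeping the first only", path.name, len(st))
    model = st[0]

    chains: Dict[str, List[ResidueRecord]] = {}
    n_polymer = 0
    for chain in model:
        residues: List[ResidueRecord] = []
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            atoms = []
            is_het = res.het_flag == "H"
            for atom in _resolve_altlocs(res):
                if atom.element.is_hydrogen:
                    continue
                atoms.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=(atom.altloc if atom.altloc != "\0" else ""),
                    is_hetero=is_het,
                ))
            if not atoms:
                continue
            rec = ResidueRecord(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                name3=res.name,
                atoms=atoms,
                is_polymer=not is_het,
            )
            if rec.is_polymer:
                n_polymer += 1
            residues.append(rec)
        if residues:
            chains[chain.name] = _sort_chain(residues)

    if n_polymer == 0:
        raise StructureError(f"{path}: no polymer residues (empty structure)")
    return ComplexStructure(complex_id=complex_id or path.stem, chains=chains)


def assign_roles(cs: ComplexStructure, receptor_chain: str,
                 peptide_chains: Iterable[str]) -> ComplexStructure:
    """Mark one chain as receptor and the given chains as peptide; rest are other."""
    peptide_chains = list(peptide_chains)
    for cid in [receptor_chain, *peptide_chains]:
        if cid not in cs.chains:
            raise ConfigurationError(
                f"{cs.complex_id}: chain {cid!r} named in config is absent "
                f"(available: {sorted(cs.chains)})"
            )
    if receptor_chain in peptide_chains:
        raise ConfigurationError(
            f"{cs.complex_id}: chain {receptor_chain!r} cannot be receptor and peptide")
    if not peptide_chains:
        raise ConfigurationError(f"{cs.complex_id}: at least one peptide chain required")
    new = cs.copy()
    new.roles = {}
    for cid in new.chains:
        if cid == receptor_chain:
            new.roles[cid] = "receptor"
        elif cid in peptide_chains:
            new.roles[cid] = "peptide"
        else:
            new.roles[cid] = "other"
    return new


def canonicalize_noncanonical(cs: ComplexStructure, ncmap: NoncanonicalMap,
                              strict: bool = True) -> ComplexStructure:
    """Rename mapped noncanonical peptide residues to their canonical parent.

    Atom coordinates are untouched (typing/bond bookkeeping only, no
    remodeling).  Listed capping residues and atoms (e.g. an N-terminal
    acetyl) are deleted; deleted covalent links are recorded on the log.
    """
    new = cs.copy()
    chains = new.peptide_chains or list(new.chains)
    for cid in chains:
        kept: List[ResidueRecord] = []
        for res in new.chains[cid]:
            if res.name3 in ncmap.delete_residues:
                logger.info("%s: deleting capping residue %s %s%d",
                            new.complex_id, res.name3, cid, res.seq_number)
                continue
            if res.name3 not in CANONICAL_RESIDUES:
                entry = ncmap.entries.get(res.name3)
                if entry is None:
                    if strict:
                        raise StructureError(
                            f"{new.complex_id}: unmapped noncanonical residue "
                            f"{res.name3} at {cid}{res.seq_number}{res.insertion_code}")
                    logger.warning("%s: leaving unmapped noncanonical %s at %s%d",
                                   new.complex_id, res.name3, cid, res.seq_number)
                else:
                    for link in entry.delete_links:
                        logger.info("%s: omitting covalent link %s for %s %s%d",
                                    new.complex_id, link, res.name3, cid, res.seq_number)
                    res.atoms = [a for a in res.atoms if a.name not in entry.delete_atoms]
                    for a in res.atoms:
                        a.name = entry.atom_renames.get(a.name, a.name)
                    res.name3 = entry.parent
                    res.is_polymer = True
            kept.append(res)
        new.chains[cid] = kept
    return new


def extract_sequence(cs: ComplexStructure, chain_id: str,
                     from_res: Optional[int] = None,
                     to_res: Optional[int] = None) -> str:
    """One-letter sequence of a residue range (inclusive seq numbers).

    Unmapped noncanonical residues render as 'X'.
    """
    residues = cs.residues(chain_id)
    if from_res is None:
        from_res = residues[0].seq_number
    if to_res is None:
        to_res = residues[-1].seq_number
    lo = min(r.seq_number for r in residues)
    hi = max(r.seq_number for r in residues)
    if from_res < lo or to_res > hi or from_res > to_res:
        raise StructureError(
            f"{cs.complex_id}: range {from_res}-{to_res} outside chain "
            f"{chain_id} ({lo}-{hi})")
    return "".join(r.one_letter() for r in residues
                   if from_res <= r.seq_number <= to_res)


def write_structure(cs: ComplexStructure, path, format: str = "pdb") -> None:
    """Write the complex as a fixed-column PDB file.

    Chain ids and numbering are preserved so the file round-trips through
    :func:`read_structure` (coordinates to PDB precision, 1e-3 Å).
    """
    if format != "pdb":
        raise ConfigurationError(f"unsupported output format {format!r}")
    n_atoms = cs.atom_count()
    if n_atoms == 0:
        raise StructureError(f"{cs.complex_id}: refusing to write empty structure")
    if n_atoms > 99999:
        raise StructureError(
            f"{cs.complex_id}: {n_atoms} atoms exceed the PDB fixed-width limit (99999)")

    st = gemmi.Structure()
    st.name = cs.complex_id
    model = gemmi.Model("1")
    for cid, residues in cs.chains.items():
        chain = gemmi.Chain(cid)
        for res in _sort_chain(residues):
            g = gemmi.Residue()
            g.name = res.name3
            g.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            g.het_flag = "A" if res.is_polymer else "H"
            for a in res.atoms:
                if not np.all(np.isfinite(a.coord)):
                    raise StructureError(f"{cs.complex_id}: non-finite coordinate on {a.name}")
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                ga.b_iso = 0.0
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
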