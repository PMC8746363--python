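"""Atom-type parameter table and residue typing.

The table ships as two plain-text files under ``gpcrpocket/data``:
``atom_types.tsv`` (Lennard-Jones and Lazaridis–Karplus parameters plus
hydrogen-bond donor/acceptor flags per type) and ``residue_atoms.tsv``
(atom-name -> type, united-atom partial charge and donor base atoms per
canonical residue).  Unknown atoms are skipped with a warning in lenient
mode and raise in strict mode.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .structure_io import ResidueRecord

logger = logging.getLogger(__name__)


class TypingError(ValueError):
    """Raised in strict mode when an atom cannot be typed."""


@dataclass(frozen=True)
class AtomTypeParams:
    type_name: str
    lj_radius: float
    lj_welldepth: float
    lk_dgfree: float
    lk_lambda: float
    lk_volume: float
    is_donor: bool
    is_acceptor: bool

    def __post_init__(self) -> None:
        if self.lj_radius <= 0 or self.lk_lambda <= 0 or self.lj_welldepth < 0:
            raise ValueError(f"invalid parameters for atom type {self.type_name}")


@dataclass(frozen=True)
class AtomEntry:
    params: AtomTypeParams
    charge: float
    bases: Tuple[str, ...]


@dataclass
class TypedAtom:
    name: str
    coord: np.ndarray
    params: AtomTypeParams
    charge: float
    bases: Tuple[str, ...]


@dataclass
class TypedResidue:
    name3: str
    res_id: Tuple[str, int, str]
    atoms: List[TypedAtom]
    by_name: Dict[str, TypedAtom] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_name = {a.name: a for a in self.atoms}


def _read_tsv(name: str) -> List[Dict[str, str]]:
    text = resources.files("gpcrpocket.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


class ParameterTable:
    """Lookup from (residue name, atom name) to typed parameters."""

    def __init__(self, atom_types: Dict[str, AtomTypeParams],
                 residue_atoms: Dict[Tuple[str, str], AtomEntry]):
        self.atom_types = atom_types
        self.residue_atoms = residue_atoms

    @classmethod
    def from_rows(cls, type_rows, residue_rows) -> "ParameterTable":
        types = {}
        for row in type_rows:
            types[row["type"]] = AtomTypeParams(
                type_name=row["type"],
                lj_radius=float(row["lj_radius"]),
                lj_welldepth=float(row["lj_welldepth"]),
                lk_dgfree=float(row["lk_dgfree"]),
                lk_lambda=float(row["lk_lambda"]),
                lk_volume=float(row["lk_volume"]),
                is_donor=row["donor"] == "1",
                is_acceptor=row["acceptor"] == "1",
            )
        entries = {}
        for row in residue_rows:
            bases = tuple(b for b in row["bases"].split(",") if b and b != "-")
            entries[(row["res"], row["atom"])] = AtomEntry(
                params=types[row["type"]],
                charge=float(row["charge"]),
                bases=bases,
            )
        return cls(types, entries)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "ParameterTable":
        return cls.from_rows(_read_tsv("atom_types.tsv"), _read_tsv("residue_atoms.tsv"))

    def lookup(self, res_name: str, atom_name: str) -> Optional[AtomEntry]:
        entry = self.residue_atoms.get((res_name, atom_name))
        if entry is None:
            entry = self.residue_atoms.get(("*", atom_name))
        return entry

    def type_residue(self, res: ResidueRecord, strict: bool = False) -> TypedResidue:
        atoms: List[TypedAtom] = []
        for a in res.atoms:
            if a.element in ("H", "D"):
                continue
            entry = self.lookup(res.name3, a.name)
            if entry is None:
                msg = (f"untypeable atom {a.name} in {res.name3} "
                       f"{res.chain_id}{res.seq_number}{res.insertion_code}")
                if strict:
                    raise TypingError(msg)
                logger.warning("%s; skipped", msg)
                continue
            atoms.append(TypedAtom(name=a.name, coord=a.coord, params=entry.params,
                                   charge=entry.charge, bases=entry.bases))
        return TypedResidue(name3=res.name3, res_id=res.res_id, atoms=atoms)
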