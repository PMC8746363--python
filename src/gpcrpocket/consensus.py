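"""Interface contacts, per-complex ΔΔG tables, cross-complex consensus,
and the ECL1 motif scan.

The consensus pocket is the set of Ballesteros–Weinstein positions whose
average per-residue ΔΔG across contacting complexes is below a threshold
(default −1) and which contact the peptide in at least ``min_count`` of
the analyzed complexes (default 7 of 9).  The ECL1 scan looks for the
five-residue [Y/H]xWxF pattern centered on W23.50 and its relaxed xWxF
form.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energy import ScoreConfig, per_residue_ddg
from .numbering import BWMap, bw_sort_key
from .params import ParameterTable
from .structure_io import ComplexStructure, ConfigurationError

logger = logging.getLogger(__name__)

#: columns of the per-residue ΔΔG table TSV schema
TABLE_COLUMNS = ["complex_id", "chain", "seq_number", "icode", "name3",
                 "bw_label", "contact", "ddg"]

_YHXWXF = re.compile(r"(?=([YH].W.F))")
_XWXF = re.compile(r"(?=(.W.F))")


@dataclass
class ContactRecord:
    receptor_residue: Tuple[str, int, str]
    peptide_residue: Tuple[str, int, str]
    min_heavy_atom_distance: float


@dataclass
class PerResidueDDGTable:
    """Per-complex table of contacting receptor residues and their ΔΔG."""

    complex_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"table {self.complex_id}: missing columns {missing}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["ddg"] = out["ddg"].map(lambda v: f"{v:.4f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PerResidueDDGTable":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"icode": str, "bw_label": str})
        except Exception as exc:
            raise ConfigurationError(f"{path}: cannot parse table: {exc}") from exc
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"{path}: schema violation, missing columns {missing}")
        df["icode"] = df["icode"].fillna("")
        df["bw_label"] = df["bw_label"].fillna("")
        ids = df["complex_id"].unique()
        if len(ids) != 1:
            raise ConfigurationError(f"{path}: expected one complex_id, found {list(ids)}")
        return cls(complex_id=str(ids[0]), df=df)


@dataclass
class ConsensusTable:
    """Cross-complex aggregation keyed by BW label.

    ``df`` has one column per complex (ΔΔG, NaN where the position does not
    contact the peptide in that complex) plus contact_count, ddg_sum,
    ddg_avg and selected; rows sorted ascending by ddg_avg.
    """

    complex_ids: List[str]
    df: pd.DataFrame


@dataclass
class MotifResult:
    sequence: str
    has_yhxwxf: bool
    has_xwxf: bool
    yhxwxf_offsets: List[int] = field(default_factory=list)
    xwxf_offsets: List[int] = field(default_factory=list)


def detect_contacts(cs: ComplexStructure, cutoff: float = 4.5) -> List[ContactRecord]:
    """All (receptor residue, peptide residue) pairs whose minimum heavy-atom
    distance is at or below the cutoff."""
    pep = cs.peptide_residues()
    if not pep:
        raise ConfigurationError(f"{cs.complex_id}: no peptide chain for contact detection")
    records: List[ContactRecord] = []
    pep_coords = [p.coords() for p in pep]
    for rres in cs.receptor_residues():
        rc = rres.coords()
        if rc.size == 0:
            continue
        for pres, pc in zip(pep, pep_coords):
            if pc.size == 0:
                continue
            d = float(cdist(rc, pc).min())
            if d <= cutoff:
                records.append(ContactRecord(rres.res_id, pres.res_id, d))
    return records


def per_complex_table(cs: ComplexStructure, bwmap: BWMap,
                      params: Optional[ParameterTable] = None,
                      cfg: Optional[ScoreConfig] = None,
                      cutoff: float = 4.5,
                      contacts: Optional[List[ContactRecord]] = None) -> PerResidueDDGTable:
    """Per-residue ΔΔG table over all receptor residues in peptide contact."""
    params = params or ParameterTable.default()
    cfg = cfg or ScoreConfig()
    if contacts is None:
        contacts = detect_contacts(cs, cutoff)
    in_contact = {c.receptor_residue for c in contacts}
    pep_typed = [params.type_residue(p) for p in cs.peptide_residues()]
    rows = []
    for rres in cs.receptor_residues():
        if rres.res_id not in in_contact:
            continue
        label = "" if rres.insertion_code else (bwmap.label_of(rres.seq_number) or "")
        ddg = per_residue_ddg(params.type_residue(rres), pep_typed, params, cfg)
        rows.append({
            "complex_id": cs.complex_id, "chain": rres.chain_id,
            "seq_number": rres.seq_number, "icode": rres.insertion_code,
            "name3": rres.name3, "bw_label": label, "contact": 1, "ddg": ddg,
        })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return PerResidueDDGTable(complex_id=cs.complex_id, df=df)


def aggregate_tables(tables: Sequence[PerResidueDDGTable]) -> ConsensusTable:
    """Assemble per-complex ΔΔG values by BW label; compute contact count,
    sum and average over the complexes where the position contacts the
    peptide; sort ascending by average ΔΔG."""
    if not tables:
        raise ConfigurationError("need at least one per-complex table to aggregate")
    complex_ids = [t.complex_id for t in tables]
    if len(set(complex_ids)) != len(complex_ids):
        raise ConfigurationError(f"duplicate complex ids in aggregation: {complex_ids}")
    per_label: Dict[str, Dict[str, float]] = {}
    for t in tables:
        labeled = t.df[t.df["bw_label"] != ""]
        dup = labeled["bw_label"].duplicated()
        if dup.any():
            raise ConfigurationError(
                f"table {t.complex_id}: duplicate bw_label "
                f"{sorted(labeled['bw_label'][dup])}")
        for _, row in labeled.iterrows():
            per_label.setdefault(row["bw_label"], {})[t.complex_id] = float(row["ddg"])

    rows = []
    for label in sorted(per_label, key=bw_sort_key):
        values = per_label[label]
        ddgs = [values[cid] for cid in complex_ids if cid in values]
        row = {"bw_label": label}
        for cid in complex_ids:
            row[cid] = values.get(cid, np.nan)
        row["contact_count"] = len(ddgs)
        row["ddg_sum"] = float(np.sum(ddgs))
        row["ddg_avg"] = float(np.mean(ddgs))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["bw_label", *complex_ids,
                                     "contact_count", "ddg_sum", "ddg_avg"])
    df["selected"] = False
    df = df.sort_values("ddg_avg", kind="mergesort").reset_index(drop=True)
    return ConsensusTable(complex_ids=complex_ids, df=df)


def select_consensus(ct: ConsensusTable, ddg_threshold: float = -1.0,
                     min_count: int = 7, n_complexes: Optional[int] = None,
                     mode: str = "average") -> List[str]:
    """Dual-threshold pocket selection.

    ``average`` mode (default): positions with average ΔΔG strictly below
    the threshold that contact the peptide in at least ``min_count``
    complexes.  ``per_complex`` mode: positions whose ΔΔG is below the
    threshold in at least ``min_count`` individual complexes.  The returned
    labels are sorted ascending by average ΔΔG.
    """
    n = n_complexes if n_complexes is not None else len(ct.complex_ids)
    if min_count > n:
        raise ConfigurationError(f"min_count {min_count} exceeds complex count {n}")
    if mode not in ("average", "per_complex"):
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    df = ct.df
    if mode == "average":
        mask = (df["ddg_avg"] < ddg_threshold) & (df["contact_count"] >= min_count)
    else:
        below = (df[ct.complex_ids] < ddg_threshold).sum(axis=1)
        mask = below >= min_count
    ct.df["selected"] = mask
    return list(df.loc[mask, "bw_label"])


def motif_scan(seq: str) -> MotifResult:
    """Scan a one-letter sequence for the ECL1 motifs.

    [Y/H]xWxF: tyrosine or histidine, any residue, tryptophan, any residue,
    phenylalanine.  xWxF: the relaxed four-residue form.  Matches may
    overlap; offsets are 0-based.
    """
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    seq = seq.upper()
    yh = [m.start() for m in _YHXWXF.finditer(seq)]
    xw = [m.start() for m in _XWXF.finditer(seq)]
    return MotifResult(sequence=seq, has_yhxwxf=bool(yh), has_xwxf=bool(xw),
                       yhxwxf_offsets=yh, xwxf_offsets=xw)


def ingest_external_tables(paths: Iterable) -> List[PerResidueDDGTable]:
    """Load externally produced per-complex tables (e.g. scored docking
    ensembles).  Multiple files sharing a complex_id are treated as an
    ensemble and averaged per position before aggregation."""
    loaded = [PerResidueDDGTable.from_tsv(p) for p in paths]
    by_complex: Dict[str, List[pd.DataFrame]] = {}
    order: List[str] = []
    for t in loaded:
        if t.complex_id not in by_complex:
            order.append(t.complex_id)
        by_complex.setdefault(t.complex_id, []).append(t.df)
    out: List[PerResidueDDGTable] = []
    for cid in order:
        frames = by_complex[cid]
        if len(frames) == 1:
            out.append(PerResidueDDGTable(complex_id=cid, df=frames[0]))
            continue
        cat = pd.concat(frames, ignore_index=True)
        keys = ["chain", "seq_number", "icode", "name3", "bw_label"]
        agg = cat.groupby(keys, sort=False, as_index=False).agg(
            contact=("contact", "max"), ddg=("ddg", "mean"))
        agg.insert(0, "complex_id", cid)
        out.append(PerResidueDDGTable(complex_id=cid, df=agg))
    return out
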