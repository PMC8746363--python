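"""Configuration-driven orchestration: superpose, number, score, aggregate,
select, and report.

A :class:`PipelineConfig` (usually read from YAML) lists the complexes with
their chain roles, x.50 anchors and optional noncanonical-residue maps,
plus the scoring and consensus parameters.  :func:`run_pipeline` executes
the full cross-complex analysis and writes per-complex ΔΔG tables, aligned
structures, the consensus table, an ECL1 motif report and a JSON summary.
Re-running with the same config and seed overwrites deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import (ConsensusTable, MotifResult, PerResidueDDGTable,
                        aggregate_tables, motif_scan, per_complex_table,
                        select_consensus)
from .energy import ScoreConfig
from .numbering import AnchorSet, BWMap, build_bw_map, ecl_segment
from .params import ParameterTable
from .structure_io import (ComplexStructure, ConfigurationError, NoncanonicalMap,
                           assign_roles, canonicalize_noncanonical, read_structure,
                           write_structure)
from .superpose import bundle_axis, penetration_depth, superpose_on_selection

logger = logging.getLogger(__name__)


@dataclass
class ComplexConfig:
    complex_id: str
    structure: str
    receptor_chain: str
    peptide_chains: List[str]
    anchors: AnchorSet
    format: str = "auto"
    noncanonical: Optional[NoncanonicalMap] = None


@dataclass
class PipelineConfig:
    complexes: List[ComplexConfig]
    score: ScoreConfig = field(default_factory=ScoreConfig)
    contact_cutoff: float = 4.5
    ddg_threshold: float = -1.0
    min_count: int = 7
    selection_mode: str = "average"
    reference: Optional[str] = None
    output_dir: str = "out"
    seed: int = 0
    keep_going: bool = False

    def validate(self) -> None:
        if not self.complexes:
            raise ConfigurationError("pipeline config lists no complexes")
        ids = [c.complex_id for c in self.complexes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate complex ids: {ids}")
        if self.min_count > len(self.complexes):
            raise ConfigurationError(
                f"min_count {self.min_count} exceeds {len(self.complexes)} complexes")
        for c in self.complexes:
            if not Path(c.structure).exists():
                raise ConfigurationError(f"{c.complex_id}: missing structure {c.structure}")
            c.anchors.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = Path(path).parent
        complexes = []
        for entry in data.get("complexes", []):
            ncmap = None
            if entry.get("noncanonical"):
                ncmap = NoncanonicalMap.from_dict(entry["noncanonical"])
            structure = str((base / entry["structure"]).resolve()) \
                if not Path(entry["structure"]).is_absolute() else entry["structure"]
            complexes.append(ComplexConfig(
                complex_id=str(entry["id"]),
                structure=structure,
                format=entry.get("format", "auto"),
                receptor_chain=str(entry["receptor_chain"]),
                peptide_chains=[str(c) for c in entry["peptide_chains"]],
                anchors=AnchorSet.from_dict(entry["anchors"]),
                noncanonical=ncmap,
            ))
        consensus = data.get("consensus", {})
        return cls(
            complexes=complexes,
            score=ScoreConfig.from_dict(data.get("score", {})),
            contact_cutoff=float(data.get("contact_cutoff", 4.5)),
            ddg_threshold=float(consensus.get("ddg_threshold", -1.0)),
            min_count=int(consensus.get("min_count", 7)),
            selection_mode=str(consensus.get("mode", "average")),
            reference=data.get("reference"),
            output_dir=str(data.get("output_dir", "out")),
            seed=int(data.get("seed", 0)),
            keep_going=bool(data.get("keep_going", False)),
        )


def color_bin(value: float, tol: float = 1e-9) -> str:
    """Fig-style color bin for a ΔΔG value: saturating blue/red at ±1."""
    if value <= -1.0 + tol:
        return "blue_max"
    if value < -tol:
        return "blue"
    if value <= tol:
        return "white"
    if value < 1.0 - tol:
        return "red"
    return "red_max"


@dataclass
class RunSummary:
    selected_labels: List[str]
    consensus: ConsensusTable
    tables: List[PerResidueDDGTable]
    motifs: Dict[str, MotifResult]
    superposition_rmsd: Dict[str, float]
    depths: Dict[str, List]
    failed: List[str] = field(default_factory=list)


def _prepare_complex(cc: ComplexConfig) -> Tuple[ComplexStructure, BWMap]:
    cs = read_structure(cc.structure, format=cc.format, complex_id=cc.complex_id)
    cs = assign_roles(cs, cc.receptor_chain, cc.peptide_chains)
    if cc.noncanonical is not None:
        cs = canonicalize_noncanonical(cs, cc.noncanonical, strict=False)
    bwmap = build_bw_map(cs.receptor_residues(), cc.anchors)
    return cs, bwmap


def run_pipeline(config: PipelineConfig,
                 params: Optional[ParameterTable] = None) -> RunSummary:
    """End-to-end cross-complex analysis; fail-fast unless keep_going."""
    config.validate()
    params = params or ParameterTable.default()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    loaded: List[Tuple[ComplexConfig, ComplexStructure, BWMap]] = []
    failed: List[str] = []
    for cc in config.complexes:
        try:
            cs, bwmap = _prepare_complex(cc)
            loaded.append((cc, cs, bwmap))
        except Exception:
            if not config.keep_going:
                logger.error("complex %s failed during preparation", cc.complex_id)
                raise
            logger.exception("complex %s skipped (keep-going)", cc.complex_id)
            failed.append(cc.complex_id)
    if not loaded:
        raise ConfigurationError("no complex could be prepared")

    # superpose everything onto the reference complex over shared TM labels
    ref_id = config.reference or loaded[0][0].complex_id
    ref_entry = next((e for e in loaded if e[0].complex_id == ref_id), None)
    if ref_entry is None:
        raise ConfigurationError(f"reference complex {ref_id!r} not in config")
    _, ref_cs, ref_bw = ref_entry
    tm_labels = sorted((lab for lab in ref_bw.reverse if int(lab.split(".")[0]) <= 7),
                       key=lambda l: (int(l.split(".")[0]), int(l.split(".")[1])))

    rmsds: Dict[str, float] = {}
    aligned: List[Tuple[ComplexConfig, ComplexStructure, BWMap]] = []
    for cc, cs, bwmap in loaded:
        if cc.complex_id == ref_id:
            aligned.append((cc, cs, bwmap))
            rmsds[cc.complex_id] = 0.0
            continue
        moved, rmsd = superpose_on_selection(cs, ref_cs, bwmap, ref_bw, tm_labels)
        rmsds[cc.complex_id] = rmsd
        aligned.append((cc, moved, bwmap))

    tables: List[PerResidueDDGTable] = []
    motifs: Dict[str, MotifResult] = {}
    depths: Dict[str, List] = {}
    for cc, cs, bwmap in aligned:
        table = per_complex_table(cs, bwmap, params, config.score,
                                  cutoff=config.contact_cutoff)
        tables.append(table)
        table.to_tsv(outdir / f"{cc.complex_id}_ddg.tsv")
        write_structure(cs, outdir / f"{cc.complex_id}_aligned.pdb")
        try:
            frame = bundle_axis(cs, cc.anchors)
            depths[cc.complex_id] = [
                {"chain": p.chain_id, "depth": round(p.depth, 3),
                 "deepest_atom": list(p.deepest_atom)}
                for p in penetration_depth(cs, frame)]
        except Exception:
            logger.warning("%s: penetration depth unavailable", cc.complex_id)
        if cc.anchors.segment_bounds.get("ECL1"):
            _, seq = ecl_segment(cs, cc.anchors, "ECL1")
            motifs[cc.complex_id] = motif_scan(seq)

    ct = aggregate_tables(tables)
    # min_count is judged against the configured ensemble size even when
    # keep-going dropped complexes, so a drop can only lose positions
    selected = select_consensus(ct, ddg_threshold=config.ddg_threshold,
                                min_count=config.min_count,
                                n_complexes=len(config.complexes),
                                mode=config.selection_mode)
    write_reports(ct, motifs, outdir)

    summary = {
        "software_version": __version__,
        "seed": config.seed,
        "parameters": {
            "contact_cutoff": config.contact_cutoff,
            "ddg_threshold": config.ddg_threshold,
            "min_count": config.min_count,
            "n_complexes": len(tables),
            "selection_mode": config.selection_mode,
            "score_weights": dict(config.score.weights),
        },
        "selected_labels": selected,
        "superposition_rmsd": {k: round(v, 6) for k, v in rmsds.items()},
        "penetration_depth": depths,
        "failed_complexes": failed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunSummary(selected_labels=selected, consensus=ct, tables=tables,
                      motifs=motifs, superposition_rmsd=rmsds, depths=depths,
                      failed=failed)


def write_reports(ct: ConsensusTable, motifs: Dict[str, MotifResult], outdir) -> None:
    """Consensus table (one column per complex, sum, average, color bin,
    selection flag; ascending average order, blanks for non-interacting
    positions) plus the per-receptor ECL1 motif table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = ct.df.copy()
    for cid in ct.complex_ids:
        df[cid] = df[cid].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    df["ddg_sum"] = df["ddg_sum"].map(lambda v: f"{v:.4f}")
    df["color"] = ct.df["ddg_avg"].map(color_bin)
    df["ddg_avg"] = df["ddg_avg"].map(lambda v: f"{v:.4f}")
    df["selected"] = df["selected"].map(lambda v: "1" if v else "0")
    cols = ["bw_label", *ct.complex_ids, "contact_count", "ddg_sum",
            "ddg_avg", "color", "selected"]
    df[cols].to_csv(outdir / "consensus.tsv", sep="\t", index=False)

    rows = []
    for cid, m in motifs.items():
        rows.append({
            "complex_id": cid, "ecl1_sequence": m.sequence,
            "has_yhxwxf": int(m.has_yhxwxf), "has_xwxf": int(m.has_xwxf),
            "yhxwxf_offsets": ",".join(map(str, m.yhxwxf_offsets)),
            "xwxf_offsets": ",".join(map(str, m.xwxf_offsets)),
        })
    pd.DataFrame(rows).to_csv(outdir / "ecl1_motifs.tsv", sep="\t", index=False)
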