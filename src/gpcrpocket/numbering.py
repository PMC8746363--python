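"""Ballesteros–Weinstein generic residue numbering from user-supplied anchors.

Each transmembrane helix t carries an anchor residue defined as t.50 (the
most conserved position of that helix: N1.50, D2.50, R3.50, W4.50, P5.50,
P6.50, P7.50 in class A receptors); other residues in the helix are
numbered t.(50+k) by their author-sequence-number offset from the anchor,
so crystallographic gaps consume labels without shifting anchored ones.
Extracellular loops 1 and 2 use the GPCRdb convention: ECL1 positions are
23.x anchored at 23.50 (the conserved tryptophan), ECL2 positions are 45.x
anchored at 45.50 (the conserved cysteine); positions N-terminal of the
anchor decrement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .structure_io import ComplexStructure, ConfigurationError, ResidueRecord, extract_sequence

logger = logging.getLogger(__name__)

TM_SEGMENTS = tuple(f"TM{i}" for i in range(1, 8))
LOOP_PREFIX = {"ECL1": 23, "ECL2": 45}


class NumberingError(ConfigurationError):
    """Raised when anchors or segment bounds are inconsistent."""


@dataclass
class AnchorSet:
    """x.50 anchors and segment bounds (inclusive author seq numbers)."""

    tm_anchors: Dict[int, int]
    segment_bounds: Dict[str, Tuple[int, int]]
    ecl1_anchor: Optional[int] = None
    ecl2_anchor: Optional[int] = None

    def validate(self) -> None:
        spans: List[Tuple[int, int, str]] = []
        for name, (start, end) in self.segment_bounds.items():
            if start > end:
                raise NumberingError(f"segment {name}: start {start} > end {end}")
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise NumberingError(f"segments {n1} and {n2} overlap")
        for tm, anchor in self.tm_anchors.items():
            if not 1 <= tm <= 7:
                raise NumberingError(f"TM index {tm} outside 1..7")
            self._check_anchor_in(f"TM{tm}", anchor)
        if self.ecl1_anchor is not None:
            self._check_anchor_in("ECL1", self.ecl1_anchor)
        if self.ecl2_anchor is not None:
            self._check_anchor_in("ECL2", self.ecl2_anchor)

    def _check_anchor_in(self, segment: str, anchor: int) -> None:
        bounds = self.segment_bounds.get(segment)
        if bounds is None:
            raise NumberingError(f"anchor given for {segment} but no segment bounds")
        if not bounds[0] <= anchor <= bounds[1]:
            raise NumberingError(
                f"{segment} anchor {anchor} outside bounds {bounds[0]}-{bounds[1]}")

    @classmethod
    def from_dict(cls, data) -> "AnchorSet":
        return cls(
            tm_anchors={int(k): int(v) for k, v in data.get("tm", {}).items()},
            segment_bounds={str(k): (int(v[0]), int(v[1]))
                            for k, v in data.get("segments", {}).items()},
            ecl1_anchor=data.get("ecl1"),
            ecl2_anchor=data.get("ecl2"),
        )

    def to_dict(self) -> dict:
        out = {
            "tm": {int(k): int(v) for k, v in self.tm_anchors.items()},
            "segments": {k: [int(v[0]), int(v[1])] for k, v in self.segment_bounds.items()},
        }
        if self.ecl1_anchor is not None:
            out["ecl1"] = int(self.ecl1_anchor)
        if self.ecl2_anchor is not None:
            out["ecl2"] = int(self.ecl2_anchor)
        return out


@dataclass
class BWMap:
    """Bidirectional residue seq-number <-> BW label mapping."""

    forward: Dict[int, str] = field(default_factory=dict)
    reverse: Dict[str, int] = field(default_factory=dict)

    def add(self, seq_number: int, label: str) -> None:
        if seq_number in self.forward and self.forward[seq_number] != label:
            raise NumberingError(
                f"residue {seq_number} already labeled {self.forward[seq_number]}, "
                f"refusing {label}")
        if label in self.reverse and self.reverse[label] != seq_number:
            raise NumberingError(f"label {label} already assigned")
        self.forward[seq_number] = label
        self.reverse[label] = seq_number

    def merge(self, other: "BWMap") -> "BWMap":
        merged = BWMap(dict(self.forward), dict(self.reverse))
        for seq, label in other.forward.items():
            merged.add(seq, label)
        return merged

    def label_of(self, seq_number: int) -> Optional[str]:
        return self.forward.get(seq_number)

    def residue_of(self, label: str) -> Optional[int]:
        return self.reverse.get(label)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_number\tbw_label\n")
            for seq in sorted(self.forward):
                fh.write(f"{seq}\t{self.forward[seq]}\n")


def bw_sort_key(label: str) -> Tuple[int, int]:
    """Sort key for BW labels: helix/loop prefix, then position."""
    t, n = label.split(".")
    return (int(t), int(n))


def _number_segment(residues: List[ResidueRecord], prefix: int,
                    anchor: int, bounds: Tuple[int, int]) -> BWMap:
    bw = BWMap()
    for res in residues:
        if bounds[0] <= res.seq_number <= bounds[1]:
            if res.insertion_code:
                logger.warning("residue %d%s has insertion code; skipped in numbering",
                               res.seq_number, res.insertion_code)
                continue
            bw.add(res.seq_number, f"{prefix}.{50 + (res.seq_number - anchor)}")
    return bw


def assign_tm_numbers(residues: List[ResidueRecord], anchors: AnchorSet) -> BWMap:
    """Label TM residues t.(50±k) by seq-number offset from the t.50 anchor."""
    anchors.validate()
    bw = BWMap()
    for tm, anchor in sorted(anchors.tm_anchors.items()):
        bounds = anchors.segment_bounds[f"TM{tm}"]
        bw = bw.merge(_number_segment(residues, tm, anchor, bounds))
    return bw


def assign_loop_numbers(residues: List[ResidueRecord], anchors: AnchorSet) -> BWMap:
    """Label ECL1 residues 23.(50±k) and ECL2 residues 45.(50±k)."""
    anchors.validate()
    bw = BWMap()
    for segment, anchor in (("ECL1", anchors.ecl1_anchor), ("ECL2", anchors.ecl2_anchor)):
        if anchor is None:
            continue
        bounds = anchors.segment_bounds[segment]
        bw = bw.merge(_number_segment(residues, LOOP_PREFIX[segment], anchor, bounds))
    return bw


def build_bw_map(residues: List[ResidueRecord], anchors: AnchorSet) -> BWMap:
    """TM plus loop numbering in one map."""
    return assign_tm_numbers(residues, anchors).merge(
        assign_loop_numbers(residues, anchors))


def ecl_segment(cs: ComplexStructure, anchors: AnchorSet,
                segment: str) -> Tuple[List[ResidueRecord], str]:
    """Residues of an extracellular loop in N->C order plus their sequence."""
    if segment not in ("ECL1", "ECL2", "ECL3"):
        raise NumberingError(f"unknown loop segment {segment!r}")
    bounds = anchors.segment_bounds.get(segment)
    if bounds is None:
        raise NumberingError(f"no segment bounds configured for {segment}")
    chain = cs.receptor_chain
    residues = [r for r in cs.residues(chain)
                if bounds[0] <= r.seq_number <= bounds[1]]
    if not residues:
        raise NumberingError(f"{cs.complex_id}: {segment} bounds {bounds} match no residues")
    seq = extract_sequence(cs, chain, bounds[0], bounds[1])
    return residues, seq
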