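"""Rigid-body superposition on the transmembrane region and peptide depth.

Receptors are aligned on the Cα atoms of shared Ballesteros–Weinstein TM
positions (least-squares Kabsch fit restricted to proper rotations).  The
membrane's extracellular boundary is approximated from the TM-helix
geometry: the bundle axis is the mean of per-helix principal axes oriented
toward the extracellular loops, and the boundary plane passes through the
centroid of the most-extracellular Cα of each helix.  Peptide penetration
depth is the signed distance of the deepest peptide heavy atom below that
plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .numbering import AnchorSet, BWMap, TM_SEGMENTS
from .structure_io import ComplexStructure

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Raised for degenerate point sets or unresolvable selections."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and 3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("improper rotation (reflection) rejected")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass
class MembraneFrame:
    """Approximate membrane frame: unit axis pointing extracellular plus a
    point on the extracellular boundary plane."""

    axis: np.ndarray
    boundary_point: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.boundary_point = np.asarray(self.boundary_point, dtype=float)
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise GeometryError(f"membrane axis must be unit length (got {n:.4f})")


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> Tuple[RigidTransform, float]:
    """Least-squares proper-rotation fit of ``mobile`` onto ``reference``.

    Returns the transform minimizing RMSD over rotations+translations and
    the residual RMSD in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise GeometryError("need at least 3 paired 3D points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    a = reference - cr
    b = mobile - cm
    sv = np.linalg.svd(b - b.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = cr - R @ cm
    residual = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((residual ** 2).sum(axis=1).mean()))
    return RigidTransform(R, t), rmsd


def _ca_for_labels(cs: ComplexStructure, bwmap: BWMap,
                   labels: Sequence[str]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    by_seq = {r.seq_number: r for r in cs.receptor_residues() if not r.insertion_code}
    for label in labels:
        seq = bwmap.residue_of(label)
        if seq is None:
            continue
        res = by_seq.get(seq)
        if res is None:
            continue
        ca = res.atom("CA")
        if ca is not None:
            out[label] = ca.coord
    return out


def superpose_on_selection(mobile_cs: ComplexStructure, ref_cs: ComplexStructure,
                           mobile_bw: BWMap, ref_bw: BWMap,
                           selection: Sequence[str]) -> Tuple[ComplexStructure, float]:
    """Move the whole mobile complex onto the reference, pairing Cα atoms of
    shared BW positions.  Unresolved positions are skipped with a warning."""
    mob = _ca_for_labels(mobile_cs, mobile_bw, selection)
    ref = _ca_for_labels(ref_cs, ref_bw, selection)
    common = [lab for lab in selection if lab in mob and lab in ref]
    missing = [lab for lab in selection if lab not in common]
    if missing:
        logger.warning("%s -> %s: %d selected positions unresolved, skipped: %s",
                       mobile_cs.complex_id, ref_cs.complex_id, len(missing),
                       ", ".join(missing[:10]))
    if len(common) < 3:
        raise GeometryError(
            f"{mobile_cs.complex_id}: fewer than 3 common selected positions "
            f"(missing: {', '.join(missing)})")
    transform, rmsd = kabsch_fit(np.stack([mob[l] for l in common]),
                                 np.stack([ref[l] for l in common]))
    return mobile_cs.transformed(transform.rotation, transform.translation), rmsd


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis of a helix's Cα trace (sign arbitrary).

    Estimated from the difference of the two half-trace centroids, which
    lies exactly on the helix axis for an ideal helix and is robust to the
    phase-dependent tilt a plain PCA of a short spiral picks up.
    """
    half = len(coords) // 2
    v = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError("degenerate helix: half-centroids coincide")
    return v / n


def bundle_axis(cs: ComplexStructure, anchors: AnchorSet) -> MembraneFrame:
    """Approximate the membrane frame from TM-helix geometry.

    The axis is the normalized mean of the per-helix Cα principal axes with
    signs made mutually consistent, then oriented so the extracellular-loop
    residues project positively.  The boundary point is the centroid of each
    helix's most-extracellular Cα.
    """
    chain = cs.receptor_chain
    residues = [r for r in cs.residues(chain)]
    helix_coords: List[np.ndarray] = []
    for seg in TM_SEGMENTS:
        bounds = anchors.segment_bounds.get(seg)
        if bounds is None:
            continue
        cas = [r.atom("CA").coord for r in residues
               if bounds[0] <= r.seq_number <= bounds[1] and r.atom("CA") is not None]
        if len(cas) >= 4:
            helix_coords.append(np.stack(cas))
    if len(helix_coords) < 3:
        raise GeometryError(
            f"{cs.complex_id}: fewer than 3 resolvable TM helices for the bundle axis")

    axes = [_helix_axis(c) for c in helix_coords]
    ref_axis = axes[0]
    axes = [a if a @ ref_axis >= 0 else -a for a in axes]
    axis = np.mean(axes, axis=0)
    axis /= np.linalg.norm(axis)

    tm_centroid = np.concatenate(helix_coords).mean(axis=0)
    ecl_coords = []
    for seg in ("ECL1", "ECL2", "ECL3"):
        bounds = anchors.segment_bounds.get(seg)
        if bounds is None:
            continue
        ecl_coords.extend(r.atom("CA").coord for r in residues
                          if bounds[0] <= r.seq_number <= bounds[1]
                          and r.atom("CA") is not None)
    if ecl_coords:
        ecl_centroid = np.mean(ecl_coords, axis=0)
        if (ecl_centroid - tm_centroid) @ axis < 0:
            axis = -axis
    else:
        logger.warning("%s: no ECL residues to orient the bundle axis; "
                       "keeping principal-axis sign", cs.complex_id)

    top_cas = [c[np.argmax(c @ axis)] for c in helix_coords]
    boundary = np.mean(top_cas, axis=0)
    return MembraneFrame(axis=axis, boundary_point=boundary)


@dataclass
class PenetrationResult:
    chain_id: str
    depth: float
    deepest_atom: Tuple[int, str, str]  # (seq_number, residue name, atom name)


def penetration_depth(cs: ComplexStructure, frame: MembraneFrame) -> List[PenetrationResult]:
    """Signed depth of each peptide chain below the extracellular boundary.

    Depth is measured along −axis from the boundary plane; the value is the
    maximum over peptide heavy atoms and is negative if the whole peptide
    sits above the plane (not clamped).
    """
    results = []
    for cid in cs.peptide_chains:
        residues = cs.residues(cid)
        if not residues:
            raise GeometryError(f"{cs.complex_id}: peptide chain {cid} is empty")
        best: Optional[Tuple[float, Tuple[int, str, str]]] = None
        for res in residues:
            for atom in res.atoms:
                depth = float((frame.boundary_point - atom.coord) @ frame.axis)
                if best is None or depth > best[0]:
                    best = (depth, (res.seq_number, res.name3, atom.name))
        assert best is not None
        results.append(PenetrationResult(chain_id=cid, depth=best[0], deepest_atom=best[1]))
    return results
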