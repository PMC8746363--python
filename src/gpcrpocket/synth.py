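"""Self-contained toy receptor–peptide complexes with planted ground truth.

The generator emulates the study conditions of the cross-complex pocket
analysis without any download: a seven-helix transmembrane bundle with
extracellular loops, a bound peptide chain whose "fingers" contact a
planted set of receptor positions, and an ensemble of such complexes
sharing a planted consensus pocket plus per-complex noise contacts.

Geometry is deliberately schematic (ideal helices, backbone + short
pseudo-sidechains, peptide fingers placed by construction rather than by
chemistry) but honors hard contracts that make ground truth unambiguous:

* each planted position has a peptide heavy atom 3.5–4.0 Å away,
* no receptor–peptide atom pair is closer than 3.0 Å,
* every non-target receptor residue stays ≥ 6.5 Å from the peptide,
* planted contacts are energetically favorable by construction (each
  finger packs carbon pairs near the Lennard-Jones minimum against the
  target's pseudo-sidechain and donates one near-linear hydrogen bond),
* all randomness flows from a single seed (byte-identical re-runs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .numbering import AnchorSet, BWMap, bw_sort_key, build_bw_map
from .structure_io import AtomRecord, ComplexStructure, ONE_TO_THREE, ResidueRecord

logger = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])

#: contact window and separation contracts (Å)
CONTACT_MIN = 3.5
CONTACT_MAX = 4.0
CLASH_MIN = 3.0
OTHER_MIN_SEPARATION = 6.5

#: default ECL1 sequences of the generated nine-receptor ensemble; they
#: emulate the motif distribution observed across class A peptide receptors
#: (four carry [Y/H]xWxF, a further four only xWxF, one neither).
DEFAULT_ECL1_SEQUENCES = (
    "AYSWTFA", "SHAWPFT", "TYQWSFA", "AHNWTFS",
    "AQAWAFA", "STDWSFN", "ANEWTFQ", "SQLWDFT",
    "ASTNAQS",
)

#: default planted consensus pocket of the toy ensemble; its composition
#: mirrors the observed pocket (two TM2 positions, one on TM3, three on TM6,
#: five on TM7 and the conserved ECL2 triplet), restricted to positions the
#: toy bundle geometry can expose to a peptide finger
DEFAULT_PLANTED_LABELS = (
    "2.59", "2.63", "3.34", "6.52", "6.55", "6.59",
    "7.34", "7.37", "7.41", "7.45", "7.48", "45.50", "45.51", "45.52",
)


class PlacementError(RuntimeError):
    """Raised when a peptide finger cannot satisfy the placement contracts."""


@dataclass
class BundleSpec:
    """Geometry of the toy transmembrane bundle."""

    n_helices: int = 7
    helix_length: int = 36
    bundle_radius: float = 11.0
    helix_radius: float = 2.3
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    loop_lengths: Dict[str, int] = field(default_factory=lambda: {
        "ICL1": 4, "ECL1": 7, "ICL2": 4, "ECL2": 9, "ICL3": 4, "ECL3": 5,
    })
    loop_spacing: float = 3.8
    ecl1_sequence: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 3:
            raise ValueError("a bundle needs at least 3 helices")
        if self.helix_length < 5 or any(v <= 0 for v in self.loop_lengths.values()):
            raise ValueError("helix and loop lengths must be positive")
        if self.ecl1_sequence is not None and \
                len(self.ecl1_sequence) != self.loop_lengths["ECL1"]:
            raise ValueError("ecl1_sequence length must equal the ECL1 loop length")


@dataclass
class PlantedEnsembleSpec:
    """Study conditions for a planted multi-complex ensemble."""

    n_complexes: int = 9
    planted_labels: Sequence[str] = DEFAULT_PLANTED_LABELS
    planted_contact_fraction: float = 1.0
    noise_labels_per_complex: int = 2
    peptide_length: int = 24
    bundle: BundleSpec = field(default_factory=BundleSpec)
    ecl1_sequences: Sequence[str] = DEFAULT_ECL1_SEQUENCES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_contact_fraction <= 1.0:
            raise ValueError("planted_contact_fraction must lie in [0, 1]")
        if self.n_complexes < 1 or self.noise_labels_per_complex < 0:
            raise ValueError("invalid ensemble size parameters")


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def _frame_to_axis(axis: np.ndarray) -> np.ndarray:
    """Rotation mapping +z onto the given axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if np.allclose(axis, _Z):
        return np.eye(3)
    if np.allclose(axis, -_Z):
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(_Z, axis)
    angle = math.acos(float(np.clip(_Z @ axis, -1.0, 1.0)))
    return _rotation_about(v, angle)


def _backbone_atoms(ca: np.ndarray, tangent: np.ndarray, outward: np.ndarray,
                    name3: str) -> List[AtomRecord]:
    """Schematic backbone (+ Cβ unless glycine) around a Cα position."""
    t = tangent / np.linalg.norm(tangent)
    r = outward / np.linalg.norm(outward)
    b = np.cross(t, r)
    atoms = [
        AtomRecord("N", "N", ca - 1.2 * t - 0.8 * r),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", ca + 1.2 * t - 0.8 * r),
        AtomRecord("O", "O", ca + 1.2 * t - 0.8 * r + 1.23 * b),
    ]
    if name3 != "GLY":
        atoms.append(AtomRecord("CB", "C", ca + 1.53 * r))
    return atoms


def build_ideal_helix(n_res: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                      radius: float = 2.3, rise: float = 1.5, twist: float = 100.0,
                      phase: float = 0.0, chain_id: str = "A", start_seq: int = 1,
                      names: Optional[Sequence[str]] = None) -> List[ResidueRecord]:
    """Ideal α-helix residues (backbone + Cβ pseudo-atoms) along an axis.

    Canonical geometry: 1.5 Å rise and 100° twist per residue, which gives
    the usual ~3.8 Å consecutive Cα–Cα distance at a 2.3 Å helical radius.
    """
    if n_res < 1:
        raise ValueError("helix needs at least one residue")
    origin = np.asarray(origin, dtype=float)
    M = _frame_to_axis(np.asarray(axis, dtype=float))
    residues = []
    for i in range(n_res):
        a = math.radians(phase + i * twist)
        rhat = np.array([math.cos(a), math.sin(a), 0.0])
        ca_local = radius * rhat + np.array([0.0, 0.0, i * rise])
        name = ONE_TO_THREE.get(names[i], names[i]) if names else "ALA"
        atoms = [AtomRecord(rec.name, rec.element, origin + M @ rec.coord)
                 for rec in _backbone_atoms(ca_local, _Z, rhat, name)]
        residues.append(ResidueRecord(chain_id=chain_id, seq_number=start_seq + i,
                                      insertion_code="", name3=name, atoms=atoms))
    return residues


def _loop_path(a: np.ndarray, b: np.ndarray, n_points: int, spacing: float,
               up: float = 1.0) -> np.ndarray:
    """n_points Cα positions on an arched path from a to b with ~equal spacing.

    The arch bulges along ``up``·z (extracellular or intracellular) and
    slightly outward; its height is solved so the total arc length fits
    n_points+1 segments of ``spacing``.
    """
    target_len = spacing * (n_points + 1)
    chord = float(np.linalg.norm(b - a))
    out_xy = (a + b)[:2] / 2.0
    nrm = np.linalg.norm(out_xy)
    outward = np.array([*(out_xy / nrm), 0.0]) if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])

    def sample(height: float, m: int = 400) -> np.ndarray:
        t = np.linspace(0.0, 1.0, m)
        base = a[None, :] + t[:, None] * (b - a)[None, :]
        bump = np.sin(math.pi * t)[:, None] * (height * up * _Z
                                               + 0.25 * height * outward)[None, :]
        return base + bump

    def arc_length(height: float) -> float:
        pts = sample(height)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    lo, hi = 0.0, max(target_len, chord)
    if arc_length(0.0) >= target_len:
        height = 0.0
    else:
        while arc_length(hi) < target_len:
            hi *= 1.5
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if arc_length(mid) < target_len:
                lo = mid
            else:
                hi = mid
        height = 0.5 * (lo + hi)

    pts = sample(height)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    wanted = np.linspace(0.0, total, n_points + 2)[1:-1]
    out = np.stack([np.interp(wanted, cum, pts[:, k]) for k in range(3)], axis=1)
    return out


def build_bundle_receptor(spec: BundleSpec) -> Tuple[ComplexStructure, AnchorSet]:
    """Seven-helix bundle with loops, plus the ground-truth anchor set.

    Helices stand on a circle of ``bundle_radius`` with alternating
    up/down topology (TM1 runs extracellular -> intracellular); each helix
    midpoint is the x.50 anchor, and the ECL1/ECL2 midpoints are the
    23.50/45.50 anchors.  Deterministic for a given spec.
    """
    n = spec.n_helices
    h_len = spec.helix_length
    mid = h_len // 2
    h_span = (h_len - 1) * spec.rise_per_residue
    loop_names = ["ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"]

    ecl1_seq = spec.ecl1_sequence or "A" * spec.loop_lengths["ECL1"]

    residues: List[ResidueRecord] = []
    seq = 1
    segment_bounds: Dict[str, Tuple[int, int]] = {}
    tm_anchors: Dict[int, int] = {}
    loop_anchors: Dict[str, int] = {}
    helix_end_ca: List[np.ndarray] = []
    helix_start_ca: List[np.ndarray] = []

    for k in range(n):
        phi = 2.0 * math.pi * k / n
        center = spec.bundle_radius * np.array([math.cos(phi), math.sin(phi), 0.0])
        dz = 1.0 if k % 2 == 1 else -1.0
        alpha_mid = math.degrees(phi) + 180.0
        start = seq
        for i in range(h_len):
            a = math.radians(alpha_mid + (i - mid) * spec.twist_per_residue)
            rhat = np.array([math.cos(a), math.sin(a), 0.0])
            z = dz * (i - mid) * spec.rise_per_residue
            ca = center + spec.helix_radius * rhat + z * _Z
            atoms = _backbone_atoms(ca, dz * _Z, rhat, "ALA")
            residues.append(ResidueRecord("R", seq, "", "ALA", atoms))
            seq += 1
        segment_bounds[f"TM{k + 1}"] = (start, seq - 1)
        tm_anchors[k + 1] = start + mid
        helix_start_ca.append(residues[start - 1].atom("CA").coord)
        helix_end_ca.append(residues[seq - 2].atom("CA").coord)

        if k < n - 1 and k < len(loop_names):
            loop = loop_names[k]
            m = spec.loop_lengths[loop]
            lstart = seq
            # loop joins this helix's end to the next helix's start
            phi2 = 2.0 * math.pi * (k + 1) / n
            center2 = spec.bundle_radius * np.array([math.cos(phi2), math.sin(phi2), 0.0])
            dz2 = 1.0 if (k + 1) % 2 == 1 else -1.0
            a2 = math.radians(math.degrees(phi2) + 180.0 - mid * spec.twist_per_residue)
            start2 = center2 + spec.helix_radius * np.array([math.cos(a2), math.sin(a2), 0.0]) \
                - dz2 * mid * spec.rise_per_residue * _Z
            up = 1.0 if loop.startswith("ECL") else -1.0
            path = _loop_path(helix_end_ca[-1], start2, m, spec.loop_spacing, up=up)
            for j in range(m):
                ca = path[j].copy()
                nxt = path[min(j + 1, m - 1)] - path[max(j - 1, 0)]
                tangent = nxt / np.linalg.norm(nxt)
                out_xy = ca[:2] / max(np.linalg.norm(ca[:2]), 1e-6)
                up = _Z if loop.startswith("ECL") else -_Z
                # fan the Cβ directions along the loop so sidechains splay
                fan = 0.60 * (2.0 * j - (m - 1)) / max(m - 1, 1)
                outward = up + 0.5 * np.array([*out_xy, 0.0]) + fan * tangent
                name = "ALA"
                if loop == "ECL1":
                    name = ONE_TO_THREE[ecl1_seq[j]]
                atoms = _backbone_atoms(ca, tangent, outward, name)
                residues.append(ResidueRecord("R", seq, "", name, atoms))
                seq += 1
            segment_bounds[loop] = (lstart, seq - 1)
            if loop in ("ECL1", "ECL2"):
                loop_anchors[loop] = lstart + m // 2

    anchors = AnchorSet(
        tm_anchors=tm_anchors,
        segment_bounds=segment_bounds,
        ecl1_anchor=loop_anchors.get("ECL1"),
        ecl2_anchor=loop_anchors.get("ECL2"),
    )
    anchors.validate()
    cs = ComplexStructure(complex_id="bundle", chains={"R": residues},
                          roles={"R": "receptor"})
    return cs, anchors


# ---------------------------------------------------------------------------
# peptide placement


#: donor-to-acceptor distance of the planted hydrogen bond (Å)
_HB_DIST = 3.1


def _finger_atoms(cb_t: np.ndarray, u: np.ndarray, w: np.ndarray
                  ) -> Tuple[List[Tuple[str, str, np.ndarray]],
                             List[Tuple[str, str, np.ndarray]]]:
    """Target pseudo-sidechain and one slim peptide finger residue.

    The target residue (renamed GLN) grows CB->CG->CD->OE1 along its Cβ
    direction ``u`` with NE2 sideways along ``w``.  The finger residue
    stacks head-down along the same axis: its NE2 donates a perfectly
    linear hydrogen bond to the target's OE1 at 3.1 Å, its CG sits in the
    3.5–4.0 Å contact window, and the rest of the residue trails outward
    with a small lateral footprint so nearby non-target residues keep
    their 6.5 Å clearance.
    """
    cg_t = cb_t + 1.50 * u
    cd_t = cb_t + 3.00 * u
    oe1_t = cb_t + 4.23 * u
    ne2_t = cd_t + 1.32 * w
    target_atoms = [("CG", "C", cg_t), ("CD", "C", cd_t),
                    ("OE1", "O", oe1_t), ("NE2", "N", ne2_t)]

    ne2_f = oe1_t + _HB_DIST * u
    cd_f = ne2_f + 1.32 * u
    cg_f = cd_f + 1.50 * (-0.6 * u - 0.8 * w)
    oe1_f = cd_f + 1.23 * w
    cb_f = cg_f + 1.50 * u
    ca_f = cb_f + 1.53 * (0.70 * u + 0.714 * w)
    n_f = ca_f + 1.45 * w
    c_f = ca_f + 1.20 * u - 0.80 * w
    o_f = c_f + 1.23 * u
    finger_atoms = [
        ("N", "N", n_f), ("CA", "C", ca_f), ("C", "C", c_f), ("O", "O", o_f),
        ("CB", "C", cb_f), ("CG", "C", cg_f), ("CD", "C", cd_f),
        ("OE1", "O", oe1_f), ("NE2", "N", ne2_f),
    ]
    return target_atoms, finger_atoms


def _min_dist(coords: np.ndarray, other: np.ndarray) -> float:
    if coords.size == 0 or other.size == 0:
        return math.inf
    d = np.linalg.norm(coords[:, None, :] - other[None, :, :], axis=2)
    return float(d.min())


def place_peptide(receptor: ComplexStructure, anchors: AnchorSet,
                  target_labels: Sequence[str], peptide_length: int = 24,
                  seed: int = 0, rng: Optional[np.random.Generator] = None,
                  max_tries: int = 60) -> ComplexStructure:
    """Attach a peptide chain whose fingers contact the target BW positions.

    Each target gets one finger residue stacked against a pseudo-sidechain
    grown on the target residue; remaining residues (up to
    ``peptide_length``) are stacked above the bundle as inert filler.
    Raises :class:`PlacementError` (suggesting fewer targets) if a finger
    cannot satisfy the distance contracts after bounded retries.
    """
    rng = rng or np.random.default_rng(seed)
    cs = receptor.copy()
    chain = cs.receptor_chain
    residues = cs.residues(chain)
    by_seq = {r.seq_number: r for r in residues}
    bwmap = build_bw_map(residues, anchors)

    targets: List[ResidueRecord] = []
    for label in sorted(target_labels, key=bw_sort_key):
        seq = bwmap.residue_of(label)
        if seq is None or seq not in by_seq:
            raise PlacementError(f"target label {label} is not resolvable in the bundle")
        targets.append(by_seq[seq])
    target_ids = {t.res_id for t in targets}

    peptide: List[ResidueRecord] = []
    placed_coords: List[np.ndarray] = []
    pseq = 1
    for tres, label in zip(targets, sorted(target_labels, key=bw_sort_key)):
        ca = tres.atom("CA").coord
        cb = tres.atom("CB")
        if cb is None:
            raise PlacementError(f"target {label}: residue has no CB to grow from")
        u0 = cb.coord - ca
        u0 /= np.linalg.norm(u0)

        placed = False
        # candidate finger frames: untilted first, then a deterministic grid
        # of growth-axis tilts (chi-angle-like kinks at Cβ), then seeded
        # random extras; the rng is advanced identically on every call so
        # placements stay reproducible for a given seed
        candidates = [(0.0, 0.0, 0.0)]
        candidates += [(float(t), float(a), float(a))
                       for t in (6.0, 12.0, 18.0) for a in range(0, 360, 45)]
        extras = rng.uniform(0.0, 1.0, size=(max_tries, 3))
        candidates += [(2.0 + 16.0 * e[0], 360.0 * e[1], 360.0 * e[2]) for e in extras]
        for tilt, azim, ang in candidates:
            ref = np.array([0.0, 0.0, 1.0]) if abs(u0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            perp = np.cross(u0, ref)
            perp /= np.linalg.norm(perp)
            tilt_axis = _rotation_about(u0, math.radians(azim)) @ perp
            u = _rotation_about(tilt_axis, math.radians(tilt)) @ u0
            lat0 = np.cross(u, ref if abs(u @ ref) < 0.9 else np.array([1.0, 0.0, 0.0]))
            lat0 /= np.linalg.norm(lat0)
            w = _rotation_about(u, math.radians(ang)) @ lat0
            target_atoms, finger_list = _finger_atoms(cb.coord, u, w)
            finger = np.stack([c for (_, _, c) in finger_list])
            new_target = np.stack([c for (_, _, c) in target_atoms])

            ok = True
            # clash guard against every receptor atom, 6.5 Å guard otherwise
            for res in residues:
                rc = res.coords()
                d = _min_dist(finger, rc)
                if d < CLASH_MIN:
                    ok = False
                    break
                if res.res_id not in target_ids and d < OTHER_MIN_SEPARATION:
                    ok = False
                    break
            if ok and placed_coords:
                # the grown target sidechain must not clash with earlier fingers
                if _min_dist(new_target, np.concatenate(placed_coords)) < CLASH_MIN:
                    ok = False
            if ok:
                # at least one peptide atom in the contact window
                d_res = np.linalg.norm(
                    finger[:, None, :]
                    - np.concatenate([tres.coords(), new_target])[None, :, :],
                    axis=2).min(axis=1)
                if not np.any((d_res >= CONTACT_MIN) & (d_res <= CONTACT_MAX)):
                    ok = False
            if not ok:
                continue

            tres.name3 = "GLN"
            for name, elem, coord in target_atoms:
                tres.atoms.append(AtomRecord(name, elem, coord))
            atoms = [AtomRecord(nm, el, c) for (nm, el, c) in finger_list]
            peptide.append(ResidueRecord("P", pseq, "", "GLN", atoms))
            pseq += 1
            placed_coords.append(finger)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"cannot place a finger at {label} without violating the "
                f"distance contracts; try fewer or better-separated targets")

    # inert filler stacked along the bundle axis, above everything
    top = max(a.coord[2] for r in residues for a in r.atoms)
    n_fill = max(0, peptide_length - len(peptide))
    for j in range(n_fill):
        ca = np.array([0.0, 0.0, top + OTHER_MIN_SEPARATION + 0.5 + j * 3.8])
        atoms = _backbone_atoms(ca, _Z, np.array([1.0, 0.0, 0.0]), "ALA")
        peptide.append(ResidueRecord("P", pseq, "", "ALA", atoms))
        pseq += 1

    cs.chains["P"] = peptide
    cs.roles = {chain: "receptor", "P": "peptide"}
    return cs


def write_ensemble(complexes: Sequence[Tuple[ComplexStructure, AnchorSet]],
                   manifest: Dict, outdir) -> None:
    """Write PDBs, a pipeline-ready YAML config, and the manifest."""
    import json
    from pathlib import Path

    import yaml

    from .structure_io import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for cs, anchors in complexes:
        path = outdir / f"{cs.complex_id}.pdb"
        write_structure(cs, path)
        entries.append({
            "id": cs.complex_id,
            "structure": path.name,
            "format": "pdb",
            "receptor_chain": cs.receptor_chain,
            "peptide_chains": cs.peptide_chains,
            "anchors": anchors.to_dict(),
        })
    config = {
        "seed": manifest.get("seed", 0),
        "output_dir": "out",
        "contact_cutoff": 4.5,
        "consensus": {"ddg_threshold": -1.0,
                      "min_count": min(7, len(entries)), "mode": "average"},
        "complexes": entries,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def _random_rigid(rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-15.0, 15.0, size=3)
    return R, t


def generate_planted_ensemble(spec: PlantedEnsembleSpec
                              ) -> Tuple[List[Tuple[ComplexStructure, AnchorSet]], Dict]:
    """Ensemble of complexes sharing the planted pocket plus noise contacts.

    Each planted label contacts the peptide in round(fraction × n)
    complexes; each complex additionally receives ``noise_labels_per_complex``
    contacts at labels drawn without replacement across the whole ensemble,
    so no noise label recurs.  Every complex is finally moved by a random
    rigid transform (recorded in the manifest) to exercise superposition.
    """
    rng = np.random.default_rng(spec.seed)
    planted = sorted(set(spec.planted_labels), key=bw_sort_key)

    # which complexes carry each planted label
    k = int(round(spec.planted_contact_fraction * spec.n_complexes))
    carries: Dict[str, set] = {}
    for label in planted:
        idx = rng.choice(spec.n_complexes, size=k, replace=False)
        carries[label] = set(int(i) for i in idx)

    # candidate pool for globally distinct noise labels: extracellular-half
    # TM positions away from the planted set
    probe_res, anchors0 = build_bundle_receptor(spec.bundle)
    planted_seqs = set()
    bw0 = build_bw_map(probe_res.residues("R"), anchors0)
    for label in planted:
        s = bw0.residue_of(label)
        if s is None:
            raise ValueError(f"planted label {label} not constructible in this bundle")
        planted_seqs.update({s - 1, s, s + 1})
    # ~100° twist per residue means offsets ±2, ±5, ±9, ±13, ±16 from the
    # anchor face away from the bundle pore, where a finger fits
    pool = []
    for tm in range(1, spec.bundle.n_helices + 1):
        for o in (2, 5, 9, 13, 16, -2, -5, -9, -13, -16):
            label = f"{tm}.{50 + o}"
            s = bw0.residue_of(label)
            if s is not None and s not in planted_seqs:
                pool.append(label)
    pool = [str(lab) for lab in rng.permutation(pool)]

    complexes: List[Tuple[ComplexStructure, AnchorSet]] = []
    manifest: Dict = {
        "seed": int(spec.seed),
        "n_complexes": int(spec.n_complexes),
        "planted_labels": planted,
        "planted_contact_fraction": float(spec.planted_contact_fraction),
        "complexes": [],
    }
    for i in range(spec.n_complexes):
        ecl1 = spec.ecl1_sequences[i % len(spec.ecl1_sequences)]
        bundle = BundleSpec(**{**spec.bundle.__dict__, "ecl1_sequence": ecl1})
        receptor, anchors = build_bundle_receptor(bundle)
        present = [lab for lab in planted if i in carries[lab]]

        # draw globally distinct noise labels, redrawing any that cannot be
        # placed alongside the planted fingers
        cs = None
        noise: List[str] = []
        for _ in range(30):
            while len(noise) < spec.noise_labels_per_complex:
                if not pool:
                    raise PlacementError("noise-label pool exhausted; reduce noise count")
                noise.append(pool.pop())
            try:
                cs = place_peptide(receptor, anchors, present + noise,
                                   peptide_length=spec.peptide_length, rng=rng)
                break
            except PlacementError:
                logger.info("complex %d: noise labels %s unplaceable, redrawing", i + 1, noise)
                receptor, anchors = build_bundle_receptor(bundle)  # fresh copy
                noise = []
        if cs is None:
            raise PlacementError("could not place noise fingers after bounded retries")
        cs.complex_id = f"SYN{i + 1}"

        # ground-truth deepest peptide atom in the pre-transform frame
        # (axis +z, boundary = centroid of each TM helix's topmost Cα);
        # ties within 1e-6 are all recorded as valid candidates
        tops = []
        for tm in range(1, spec.bundle.n_helices + 1):
            lo, hi = anchors.segment_bounds[f"TM{tm}"]
            zs = [r.atom("CA").coord[2] for r in cs.residues("R")
                  if lo <= r.seq_number <= hi and r.atom("CA") is not None]
            tops.append(max(zs))
        boundary_z = float(np.mean(tops))
        depths = [(boundary_z - a.coord[2], res.seq_number, res.name3, a.name)
                  for res in cs.residues("P") for a in res.atoms]
        max_depth = max(d[0] for d in depths)
        candidates = [d for d in depths if d[0] > max_depth - 1e-6]
        deepest = candidates[0]

        R, t = _random_rigid(rng)
        moved = cs.transformed(R, t)
        moved.complex_id = cs.complex_id
        complexes.append((moved, anchors))
        manifest["complexes"].append({
            "complex_id": cs.complex_id,
            "ecl1_sequence": ecl1,
            "planted": present,
            "noise": noise,
            "deepest_atom": {"depth": round(float(deepest[0]), 3),
                             "seq_number": int(deepest[1]),
                             "name3": deepest[2], "atom": deepest[3],
                             "tied_atoms": [[int(d[1]), d[3]] for d in candidates]},
            "rotation": [[round(float(v), 6) for v in row] for row in R],
            "translation": [round(float(v), 6) for v in t],
        })
    return complexes, manifest
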