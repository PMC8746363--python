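"""Two-body interface energy terms and the per-residue ΔΔG.

The per-residue ΔΔG of a receptor residue is the weighted sum, over all
peptide residues, of five pairwise (two-body) interaction terms evaluated
between heavy atoms:

* ``fa_atr`` / ``fa_rep`` — the attractive and repulsive branches of a
  12-6 Lennard-Jones potential with combined minimum at the sum of the
  two atomic radii, the repulsive wall linearized below 0.6·d_min and the
  attractive tail smoothly switched to zero between ``lj_switch_start``
  and ``lj_cutoff``;
* ``fa_sol`` — Lazaridis–Karplus Gaussian-exclusion pairwise desolvation;
* ``fa_elec`` — Coulomb electrostatics with a distance-dependent
  dielectric ramping from ``elec_die_min`` to ``elec_die_max`` and shifted
  to vanish at ``elec_cutoff``;
* ``hbond`` — an orientation-dependent hydrogen bond with polynomial wells
  in the donor–acceptor distance and the D–H...A angle.  Polar hydrogens
  are not read from files; the H direction is inferred from the donor's
  bonded heavy atoms (antecedent/bisector rule in the parameter table).

Units are kcal/mol-equivalent score units; no calibration against any
external implementation is claimed.  All terms are exactly zero beyond
their cutoffs and continuous at them, and every pair term is symmetric in
its two residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .params import AtomTypeParams, ParameterTable, TypedResidue
from .structure_io import ResidueRecord

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637

#: ratio of d_min below which the repulsive branch is linearized
_REP_LINEAR_FRACTION = 0.6


@dataclass
class ScoreConfig:
    """Weights, cutoffs and well parameters of the two-body score."""

    weights: Dict[str, float] = field(default_factory=lambda: {
        "fa_atr": 1.0, "fa_rep": 0.55, "fa_sol": 1.0, "fa_elec": 1.0, "hbond": 1.0,
    })
    lj_switch_start: float = 4.5
    lj_cutoff: float = 6.0
    elec_cutoff: float = 5.5
    elec_die_min: float = 4.0
    elec_die_max: float = 80.0
    elec_min_dist: float = 1.45
    hbond_dist_min: float = 2.4
    hbond_dist_ideal: float = 2.8
    hbond_dist_max: float = 3.6
    hbond_angle_min: float = 120.0
    hbond_depth: float = 2.4
    hbond_h_length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lj_switch_start, self.lj_cutoff, self.elec_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.lj_switch_start >= self.lj_cutoff:
            raise ValueError("lj_switch_start must be below lj_cutoff")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not self.hbond_dist_min < self.hbond_dist_ideal < self.hbond_dist_max:
            raise ValueError("hbond distance well must be ordered min < ideal < max")

    @property
    def max_cutoff(self) -> float:
        return max(self.lj_cutoff, self.elec_cutoff, self.hbond_dist_max)

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreConfig":
        cfg = cls()
        for key, value in data.items():
            if key == "weights":
                cfg.weights.update({k: float(v) for k, v in value.items()})
            elif hasattr(cfg, key):
                setattr(cfg, key, float(value))
            else:
                raise ValueError(f"unknown score option {key!r}")
        cfg.__post_init__()
        return cfg


@dataclass
class EnergyBreakdown:
    """Per-term two-body energies for one residue pair (or a sum of pairs)."""

    fa_atr: float = 0.0
    fa_rep: float = 0.0
    fa_sol: float = 0.0
    fa_elec: float = 0.0
    hbond: float = 0.0
    total_weighted: float = 0.0

    @classmethod
    def weighted(cls, cfg: ScoreConfig, **terms: float) -> "EnergyBreakdown":
        eb = cls(**terms)
        eb.total_weighted = sum(cfg.weights.get(name, 0.0) * getattr(eb, name)
                                for name in ("fa_atr", "fa_rep", "fa_sol",
                                             "fa_elec", "hbond"))
        return eb

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            fa_atr=self.fa_atr + other.fa_atr,
            fa_rep=self.fa_rep + other.fa_rep,
            fa_sol=self.fa_sol + other.fa_sol,
            fa_elec=self.fa_elec + other.fa_elec,
            hbond=self.hbond + other.hbond,
            total_weighted=self.total_weighted + other.total_weighted,
        )


def _switch(r, start: float, cutoff: float):
    """Cubic smoothstep from 1 at ``start`` to 0 at ``cutoff`` (vectorizable)."""
    t = np.clip((np.asarray(r, dtype=float) - start) / (cutoff - start), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def lj_pair_energy(r: float, a: AtomTypeParams, b: AtomTypeParams,
                   cfg: ScoreConfig) -> Tuple[float, float]:
    """Attractive/repulsive 12-6 Lennard-Jones branches for one atom pair."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive (got {r})")
    d_min = a.lj_radius + b.lj_radius
    eps = math.sqrt(a.lj_welldepth * b.lj_welldepth)
    if r >= cfg.lj_cutoff:
        return 0.0, 0.0

    def lj(x: float) -> float:
        s6 = (d_min / x) ** 6
        return eps * (s6 * s6 - 2.0 * s6)

    r_lin = _REP_LINEAR_FRACTION * d_min
    if r >= d_min:
        return lj(r) * float(_switch(r, cfg.lj_switch_start, cfg.lj_cutoff)), 0.0
    if r >= r_lin:
        return -eps, lj(r) + eps
    # linear extrapolation of the repulsive wall below 0.6 d_min
    s6 = (d_min / r_lin) ** 6
    e_lin = eps * (s6 * s6 - 2.0 * s6)
    slope = 12.0 * eps / r_lin * (s6 - s6 * s6)  # dE/dr at r_lin (negative)
    return -eps, (e_lin + eps) + slope * (r - r_lin)


def elec_pair_energy(r: float, q_a: float, q_b: float, cfg: ScoreConfig) -> float:
    """Coulomb term with linearly ramping dielectric, shifted to 0 at cutoff."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive (got {r})")
    if q_a == 0.0 or q_b == 0.0 or r >= cfg.elec_cutoff:
        return 0.0
    rr = max(r, cfg.elec_min_dist)
    die = cfg.elec_die_min + (cfg.elec_die_max - cfg.elec_die_min) * (rr / cfg.elec_cutoff)
    e = COULOMB_CONSTANT * q_a * q_b / (die * rr)
    e_cut = COULOMB_CONSTANT * q_a * q_b / (cfg.elec_die_max * cfg.elec_cutoff)
    return (e - e_cut) * float(_switch(rr, cfg.elec_cutoff - 1.0, cfg.elec_cutoff))


def solvation_pair_energy(r: float, a: AtomTypeParams, b: AtomTypeParams,
                          cfg: ScoreConfig) -> float:
    """Lazaridis–Karplus Gaussian-exclusion desolvation, symmetric in (a, b)."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive (got {r})")
    if r >= cfg.lj_cutoff:
        return 0.0

    def excl(i: AtomTypeParams, j: AtomTypeParams) -> float:
        x = (r - i.lj_radius) / i.lk_lambda
        dens = math.exp(-x * x) / (2.0 * math.pi ** 1.5 * i.lk_lambda * r * r)
        return -i.lk_dgfree * dens * j.lk_volume

    e = excl(a, b) + excl(b, a)
    return e * float(_switch(r, cfg.lj_switch_start, cfg.lj_cutoff))


def _hbond_distance_well(d: float, cfg: ScoreConfig) -> float:
    """Piecewise quartic well (1 − t²)²: 1 at the ideal distance, reaching 0
    with zero slope at both window edges."""
    if d < cfg.hbond_dist_min or d > cfg.hbond_dist_max:
        return 0.0
    if d <= cfg.hbond_dist_ideal:
        half = cfg.hbond_dist_ideal - cfg.hbond_dist_min
    else:
        half = cfg.hbond_dist_max - cfg.hbond_dist_ideal
    t = (d - cfg.hbond_dist_ideal) / half
    return (1.0 - t * t) ** 2


def _hbond_angle_factor(theta_deg: float, cfg: ScoreConfig) -> float:
    """Quadratic ramp: 0 at the minimum angle, 1 at linear (180°)."""
    if theta_deg < cfg.hbond_angle_min:
        return 0.0
    t = (theta_deg - cfg.hbond_angle_min) / (180.0 - cfg.hbond_angle_min)
    return t * t


def _donor_h_direction(donor, residue: TypedResidue) -> Optional[np.ndarray]:
    base_coords = [residue.by_name[b].coord for b in donor.bases if b in residue.by_name]
    if not base_coords:
        return None
    v = donor.coord - np.mean(base_coords, axis=0)
    n = np.linalg.norm(v)
    if n < 1e-9:
        return None
    return v / n


def hbond_pair_energy(donor_res: TypedResidue, acceptor_res: TypedResidue,
                      cfg: ScoreConfig) -> float:
    """Sum of hydrogen-bond energies from donors of one residue to acceptors
    of the other.  Donors whose base atoms are missing are skipped with a
    warning (never fatal)."""
    total = 0.0
    for donor in donor_res.atoms:
        if not donor.params.is_donor:
            continue
        direction = _donor_h_direction(donor, donor_res)
        if direction is None:
            logger.warning("donor %s in %s %s: base atoms missing, H-bond skipped",
                           donor.name, donor_res.name3, donor_res.res_id)
            continue
        h_pos = donor.coord + cfg.hbond_h_length * direction
        for acc in acceptor_res.atoms:
            if not acc.params.is_acceptor:
                continue
            d = float(np.linalg.norm(acc.coord - donor.coord))
            w = _hbond_distance_well(d, cfg)
            if w == 0.0:
                continue
            v1 = donor.coord - h_pos
            v2 = acc.coord - h_pos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            cos_t = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
            theta = math.degrees(math.acos(cos_t))
            total += -cfg.hbond_depth * w * _hbond_angle_factor(theta, cfg)
    return total


def _vector_lj(D: np.ndarray, d_min: np.ndarray, eps: np.ndarray,
               cfg: ScoreConfig) -> Tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        s6 = (d_min / D) ** 6
    lj = eps * (s6 * s6 - 2.0 * s6)
    atr = np.where(D < d_min, -eps, lj * _switch(D, cfg.lj_switch_start, cfg.lj_cutoff))
    r_lin = _REP_LINEAR_FRACTION * d_min
    s6l = (1.0 / _REP_LINEAR_FRACTION) ** 6
    e_lin = eps * (s6l * s6l - 2.0 * s6l)
    slope = 12.0 * eps / r_lin * (s6l - s6l * s6l)
    rep = np.where(D < r_lin,
                   (e_lin + eps) + slope * (D - r_lin),
                   np.where(D < d_min, lj + eps, 0.0))
    zero = D >= cfg.lj_cutoff
    return np.where(zero, 0.0, atr), np.where(zero, 0.0, rep)


def _vector_sol(D: np.ndarray, ra, rb, la, lb, ga, gb, va, vb,
                cfg: ScoreConfig) -> np.ndarray:
    def excl(radius, lam, dgfree, vol_other):
        x = (D - radius) / lam
        dens = np.exp(-x * x) / (2.0 * math.pi ** 1.5 * lam * D * D)
        return -dgfree * dens * vol_other

    e = excl(ra[:, None], la[:, None], ga[:, None], vb[None, :]) + \
        excl(rb[None, :], lb[None, :], gb[None, :], va[:, None])
    return np.where(D >= cfg.lj_cutoff, 0.0,
                    e * _switch(D, cfg.lj_switch_start, cfg.lj_cutoff))


def _vector_elec(D: np.ndarray, qa: np.ndarray, qb: np.ndarray,
                 cfg: ScoreConfig) -> np.ndarray:
    qq = qa[:, None] * qb[None, :]
    rr = np.maximum(D, cfg.elec_min_dist)
    die = cfg.elec_die_min + (cfg.elec_die_max - cfg.elec_die_min) * (rr / cfg.elec_cutoff)
    e = COULOMB_CONSTANT * qq / (die * rr)
    e_cut = COULOMB_CONSTANT * qq / (cfg.elec_die_max * cfg.elec_cutoff)
    sw = _switch(rr, cfg.elec_cutoff - 1.0, cfg.elec_cutoff)
    return np.where(D >= cfg.elec_cutoff, 0.0, (e - e_cut) * sw)


def residue_pair_energy(res_a: ResidueRecord | TypedResidue,
                        res_b: ResidueRecord | TypedResidue,
                        params: Optional[ParameterTable] = None,
                        cfg: Optional[ScoreConfig] = None,
                        strict: bool = False) -> EnergyBreakdown:
    """Two-body energy breakdown between two residues.

    Each term is the sum over heavy-atom pairs of the corresponding pair
    interaction; the hydrogen-bond term is evaluated in both donor/acceptor
    directions, so the result is symmetric under argument swap.
    """
    params = params or ParameterTable.default()
    cfg = cfg or ScoreConfig()
    ta = res_a if isinstance(res_a, TypedResidue) else params.type_residue(res_a, strict)
    tb = res_b if isinstance(res_b, TypedResidue) else params.type_residue(res_b, strict)
    if not ta.atoms or not tb.atoms:
        return EnergyBreakdown.weighted(cfg)

    ca = np.stack([a.coord for a in ta.atoms])
    cb = np.stack([a.coord for a in tb.atoms])
    D = cdist(ca, cb)
    if D.min() < cfg.max_cutoff:
        pa = [a.params for a in ta.atoms]
        pb = [b.params for b in tb.atoms]
        ra = np.array([p.lj_radius for p in pa]); rb = np.array([p.lj_radius for p in pb])
        wa = np.array([p.lj_welldepth for p in pa]); wb = np.array([p.lj_welldepth for p in pb])
        la = np.array([p.lk_lambda for p in pa]); lb = np.array([p.lk_lambda for p in pb])
        ga = np.array([p.lk_dgfree for p in pa]); gb = np.array([p.lk_dgfree for p in pb])
        va = np.array([p.lk_volume for p in pa]); vb = np.array([p.lk_volume for p in pb])
        qa = np.array([a.charge for a in ta.atoms]); qb = np.array([b.charge for b in tb.atoms])
        d_min = ra[:, None] + rb[None, :]
        eps = np.sqrt(wa[:, None] * wb[None, :])
        atr, rep = _vector_lj(D, d_min, eps, cfg)
        sol = _vector_sol(D, ra, rb, la, lb, ga, gb, va, vb, cfg)
        elec = _vector_elec(D, qa, qb, cfg)
        hb = hbond_pair_energy(ta, tb, cfg) + hbond_pair_energy(tb, ta, cfg)
        return EnergyBreakdown.weighted(
            cfg, fa_atr=float(atr.sum()), fa_rep=float(rep.sum()),
            fa_sol=float(sol.sum()), fa_elec=float(elec.sum()), hbond=hb)
    return EnergyBreakdown.weighted(cfg)


def export_pair_breakdown(receptor_res: ResidueRecord | TypedResidue,
                          peptide_residues: Iterable[ResidueRecord | TypedResidue],
                          path,
                          params: Optional[ParameterTable] = None,
                          cfg: Optional[ScoreConfig] = None) -> None:
    """Debugging TSV: one row per peptide residue with the term breakdown
    of its two-body energy against the receptor residue."""
    params = params or ParameterTable.default()
    cfg = cfg or ScoreConfig()
    rec = receptor_res if isinstance(receptor_res, TypedResidue) \
        else params.type_residue(receptor_res)
    with open(path, "w") as fh:
        fh.write("peptide_res\tname3\tfa_atr\tfa_rep\tfa_sol\tfa_elec\thbond\ttotal_weighted\n")
        for pep in peptide_residues:
            tp = pep if isinstance(pep, TypedResidue) else params.type_residue(pep)
            eb = residue_pair_energy(rec, tp, params, cfg)
            rid = f"{tp.res_id[0]}{tp.res_id[1]}{tp.res_id[2]}"
            fh.write(f"{rid}\t{tp.name3}\t{eb.fa_atr:.4f}\t{eb.fa_rep:.4f}\t"
                     f"{eb.fa_sol:.4f}\t{eb.fa_elec:.4f}\t{eb.hbond:.4f}\t"
                     f"{eb.total_weighted:.4f}\n")


def per_residue_ddg(receptor_res: ResidueRecord | TypedResidue,
                    peptide_residues: Iterable[ResidueRecord | TypedResidue],
                    params: Optional[ParameterTable] = None,
                    cfg: Optional[ScoreConfig] = None,
                    strict: bool = False) -> float:
    """ΔΔG of one receptor residue: weighted two-body energy summed over all
    peptide residues.  Zero when no peptide atom is within the largest cutoff."""
    params = params or ParameterTable.default()
    cfg = cfg or ScoreConfig()
    total = 0.0
    for pep in peptide_residues:
        total += residue_pair_energy(receptor_res, pep, params, cfg, strict).total_weighted
    return total
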