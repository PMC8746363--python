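import math

import numpy as np
import pytest

from gpcrpocket.energy import (COULOMB_CONSTANT, EnergyBreakdown, ScoreConfig,
                               elec_pair_energy, hbond_pair_energy,
                               lj_pair_energy, per_residue_ddg,
                               residue_pair_energy, solvation_pair_energy)
from gpcrpocket.params import ParameterTable, TypingError
from conftest import make_residue


@pytest.fixture(scope="module")
def carbon(params):
    return params.atom_types["CH2"]


@pytest.fixture(scope="module")
def oxygen(params):
    return params.atom_types["OCbb"]


# --- Lennard-Jones -----------------------------------------------------------

def test_lj_minimum_by_construction(carbon, oxygen, cfg):
    d_min = carbon.lj_radius + oxygen.lj_radius
    eps = math.sqrt(carbon.lj_welldepth * oxygen.lj_welldepth)
    atr, rep = lj_pair_energy(d_min, carbon, oxygen, cfg)
    assert atr == pytest.approx(-eps)
    assert rep == 0.0


def test_lj_zero_beyond_cutoff(carbon, cfg):
    assert lj_pair_energy(cfg.lj_cutoff + 0.1, carbon, carbon, cfg) == (0.0, 0.0)


def test_lj_linearized_wall_matches_closed_form(carbon, oxygen, cfg):
    """At 0.5 d_min the repulsive branch equals the documented linear
    extrapolation from 0.6 d_min, evaluated independently here."""
    d_min = carbon.lj_radius + oxygen.lj_radius
    eps = math.sqrt(carbon.lj_welldepth * oxygen.lj_welldepth)
    r = 0.5 * d_min
    r_lin = 0.6 * d_min
    s6 = (d_min / r_lin) ** 6
    e_lin = eps * (s6 * s6 - 2 * s6)
    slope = 12 * eps / r_lin * (s6 - s6 * s6)
    expected_rep = (e_lin + eps) + slope * (r - r_lin)
    atr, rep = lj_pair_energy(r, carbon, oxygen, cfg)
    assert atr == pytest.approx(-eps)
    assert rep == pytest.approx(expected_rep, rel=1e-12)


def test_lj_domain_error(carbon, cfg):
    with pytest.raises(ValueError):
        lj_pair_energy(0.0, carbon, carbon, cfg)


# --- electrostatics ----------------------------------------------------------

def test_elec_zero_charge_and_cutoff(cfg):
    assert elec_pair_energy(2.0, 0.0, 1.0, cfg) == 0.0
    assert elec_pair_energy(cfg.elec_cutoff + 0.1, 1.0, -1.0, cfg) == 0.0


def test_elec_matches_closed_form(cfg):
    """Unit charges at 2.0 Å: C q1 q2 / (ε(r) r) minus the cutoff shift."""
    r = 2.0
    die = cfg.elec_die_min + (cfg.elec_die_max - cfg.elec_die_min) * r / cfg.elec_cutoff
    expected = COULOMB_CONSTANT * (-1.0) / (die * r) \
        - COULOMB_CONSTANT * (-1.0) / (cfg.elec_die_max * cfg.elec_cutoff)
    got = elec_pair_energy(r, 1.0, -1.0, cfg)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got < 0


def test_elec_sign_and_monotone_magnitude(cfg):
    rs = np.linspace(cfg.elec_min_dist + 0.05, cfg.elec_cutoff - 0.01, 50)
    vals = [elec_pair_energy(r, 1.0, 1.0, cfg) for r in rs]
    assert all(v > 0 for v in vals)
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


# --- solvation ---------------------------------------------------------------

def test_solvation_symmetry_and_cutoff(carbon, oxygen, cfg):
    assert solvation_pair_energy(10.0, carbon, oxygen, cfg) == 0.0
    a = solvation_pair_energy(3.2, carbon, oxygen, cfg)
    b = solvation_pair_energy(3.2, oxygen, carbon, cfg)
    assert a == pytest.approx(b, rel=1e-12)


def test_solvation_matches_lk_expression(carbon, cfg):
    """Carbon–carbon contact at d_min equals the Lazaridis–Karplus
    Gaussian-exclusion expression evaluated independently."""
    r = 2 * carbon.lj_radius

    def lk_one(i, j):
        x = (r - i.lj_radius) / i.lk_lambda
        return -i.lk_dgfree * math.exp(-x * x) \
            / (2 * math.pi ** 1.5 * i.lk_lambda * r * r) * j.lk_volume

    expected = lk_one(carbon, carbon) * 2  # switch is 1 below lj_switch_start
    assert r < cfg.lj_switch_start
    assert solvation_pair_energy(r, carbon, carbon, cfg) == pytest.approx(expected, rel=1e-12)


# --- hydrogen bond -----------------------------------------------------------

def _donor_acceptor(params, d, theta_deg):
    """Backbone N-H...O=C pair with donor-acceptor distance d and D-H...A
    angle theta, built in the plane."""
    ca = np.array([0.0, -1.5, 0.0])
    n = np.array([0.0, 0.0, 0.0])  # H direction inferred as N - CA = +y
    h = n + np.array([0.0, 1.0, 0.0])
    # acceptor in-plane with |N-A| = d and D-H...A angle = theta (closed form)
    t = math.radians(theta_deg)
    r_ha = math.cos(t) + math.sqrt(d * d - math.sin(t) ** 2)
    acc = h + r_ha * np.array([math.sin(t), -math.cos(t), 0.0])
    assert abs(np.linalg.norm(acc - n) - d) < 1e-9
    donor = make_residue("ALA", [("N", "N", n), ("CA", "C", ca)])
    acceptor = make_residue("ALA", [("O", "O", acc)], chain_id="B")
    return params.type_residue(donor), params.type_residue(acceptor)


def test_hbond_outside_window_is_zero(params, cfg):
    d, a = _donor_acceptor(params, 4.0, 180.0)
    assert hbond_pair_energy(d, a, cfg) == 0.0


def test_hbond_ideal_geometry_hits_well_depth(params, cfg):
    d, a = _donor_acceptor(params, cfg.hbond_dist_ideal, 180.0)
    assert hbond_pair_energy(d, a, cfg) == pytest.approx(-cfg.hbond_depth, abs=1e-4)


def test_hbond_matches_polynomial_wells(params, cfg):
    """(3.0 Å, 150°) equals the product of the two wells evaluated directly."""
    d, a = _donor_acceptor(params, 3.0, 150.0)
    half = cfg.hbond_dist_max - cfg.hbond_dist_ideal
    w_dist = (1 - ((3.0 - cfg.hbond_dist_ideal) / half) ** 2) ** 2
    w_ang = ((150.0 - cfg.hbond_angle_min) / (180.0 - cfg.hbond_angle_min)) ** 2
    expected = -cfg.hbond_depth * w_dist * w_ang
    assert hbond_pair_energy(d, a, cfg) == pytest.approx(expected, abs=2e-3)


def test_hbond_missing_base_skips_with_warning(params, cfg, caplog):
    donor = make_residue("ALA", [("N", "N", (0, 0, 0))])  # no CA base
    acceptor = make_residue("ALA", [("O", "O", (0, 2.8, 0))], chain_id="B")
    with caplog.at_level("WARNING"):
        val = hbond_pair_energy(params.type_residue(donor),
                                params.type_residue(acceptor), cfg)
    assert val == 0.0
    assert any("base atoms missing" in r.message for r in caplog.records)


# --- cutoff continuity (all terms) ------------------------------------------

def test_terms_continuous_at_cutoffs(params, carbon, cfg):
    delta = 1e-4
    atr, rep = lj_pair_energy(cfg.lj_cutoff - delta, carbon, carbon, cfg)
    assert abs(atr) < 1e-6 and abs(rep) < 1e-6
    assert abs(elec_pair_energy(cfg.elec_cutoff - delta, 1.0, 1.0, cfg)) < 1e-6
    assert abs(solvation_pair_energy(cfg.lj_cutoff - delta, carbon, carbon, cfg)) < 1e-6
    d, a = _donor_acceptor(params, cfg.hbond_dist_max - delta, 179.0)
    assert abs(hbond_pair_energy(d, a, cfg)) < 1e-6


# --- residue-level operations ------------------------------------------------

def random_gln_pair(seed, separation=4.5):
    """Two glutamine-like residues with full sidechains at a random mutual
    orientation, a few Å apart."""
    rng = np.random.default_rng(seed)
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
             ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")]

    def one(chain, offset):
        specs = []
        base = rng.normal(scale=1.2, size=(len(names), 3))
        for (nm, el), xyz in zip(names, base):
            specs.append((nm, el, xyz + offset))
        return make_residue("GLN", specs, chain_id=chain)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return one("A", np.zeros(3)), one("B", separation * direction)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_residue_pair_energy_equals_bruteforce(params, cfg, seed):
    """The vectorized residue-pair energy must equal an independent double
    loop over atom pairs using the scalar pair operations."""
    res_a, res_b = random_gln_pair(seed)
    eb = residue_pair_energy(res_a, res_b, params, cfg)

    ta = params.type_residue(res_a)
    tb = params.type_residue(res_b)
    atr = rep = sol = elec = 0.0
    for x in ta.atoms:
        for y in tb.atoms:
            r = float(np.linalg.norm(x.coord - y.coord))
            a_, r_ = lj_pair_energy(r, x.params, y.params, cfg)
            atr += a_
            rep += r_
            sol += solvation_pair_energy(r, x.params, y.params, cfg)
            elec += elec_pair_energy(r, x.charge, y.charge, cfg)
    hb = hbond_pair_energy(ta, tb, cfg) + hbond_pair_energy(tb, ta, cfg)
    assert eb.fa_atr == pytest.approx(atr, abs=1e-9)
    assert eb.fa_rep == pytest.approx(rep, abs=1e-9)
    assert eb.fa_sol == pytest.approx(sol, abs=1e-9)
    assert eb.fa_elec == pytest.approx(elec, abs=1e-9)
    assert eb.hbond == pytest.approx(hb, abs=1e-9)


def test_residue_pair_symmetry_and_weights(params, cfg):
    res_a, res_b = random_gln_pair(7)
    eb1 = residue_pair_energy(res_a, res_b, params, cfg)
    eb2 = residue_pair_energy(res_b, res_a, params, cfg)
    for term in ("fa_atr", "fa_rep", "fa_sol", "fa_elec", "hbond", "total_weighted"):
        assert getattr(eb1, term) == pytest.approx(getattr(eb2, term), abs=1e-9)
    expected_total = sum(cfg.weights[t] * getattr(eb1, t)
                         for t in ("fa_atr", "fa_rep", "fa_sol", "fa_elec", "hbond"))
    assert eb1.total_weighted == pytest.approx(expected_total, abs=1e-12)


def test_distant_residues_are_zero(params, cfg):
    res_a, res_b = random_gln_pair(9, separation=30.0)
    eb = residue_pair_energy(res_a, res_b, params, cfg)
    assert eb == EnergyBreakdown()


@pytest.mark.parametrize("seed", [11, 12])
def test_rigid_motion_invariance(params, cfg, seed):
    from test_superpose import random_rotation
    res_a, res_b = random_gln_pair(seed)
    before = residue_pair_energy(res_a, res_b, params, cfg).total_weighted
    rng = np.random.default_rng(seed + 100)
    R0 = random_rotation(rng)
    t0 = rng.normal(size=3) * 20
    for res in (res_a, res_b):
        for atom in res.atoms:
            atom.coord = R0 @ atom.coord + t0
    after = residue_pair_energy(res_a, res_b, params, cfg).total_weighted
    assert after == pytest.approx(before, abs=1e-9)


def test_per_residue_ddg_sums_pairs(params, cfg):
    rec, pep1 = random_gln_pair(21)
    _, pep2 = random_gln_pair(22)
    expected = residue_pair_energy(rec, pep1, params, cfg).total_weighted \
        + residue_pair_energy(rec, pep2, params, cfg).total_weighted
    assert per_residue_ddg(rec, [pep1, pep2], params, cfg) == pytest.approx(expected, abs=1e-9)
    far, _ = random_gln_pair(23, separation=50.0)
    assert per_residue_ddg(far, [pep1], params, cfg) != 0  # sanity: nearby
    assert per_residue_ddg(rec, [], params, cfg) == 0.0


def test_atr_only_weights_nonpositive(params):
    cfg = ScoreConfig(weights={"fa_atr": 1.0, "fa_rep": 0.0, "fa_sol": 0.0,
                               "fa_elec": 0.0, "hbond": 0.0})
    for seed in range(6):
        rec, pep = random_gln_pair(seed, separation=3.5 + seed * 0.5)
        assert per_residue_ddg(rec, [pep], params, cfg) <= 0.0


def test_untypeable_atom_strict_vs_lenient(params, cfg, caplog):
    bad = make_residue("ALA", [("CA", "C", (0, 0, 0)), ("XQ", "C", (1, 0, 0))])
    with pytest.raises(TypingError, match="XQ"):
        params.type_residue(bad, strict=True)
    with caplog.at_level("WARNING"):
        typed = params.type_residue(bad, strict=False)
    assert [a.name for a in typed.atoms] == ["CA"]


def test_export_pair_breakdown(tmp_path, params, cfg):
    rec, pep = random_gln_pair(31)
    path = tmp_path / "pairs.tsv"
    from gpcrpocket.energy import export_pair_breakdown
    export_pair_breakdown(rec, [pep], path, params, cfg)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("peptide_res\t")
    total = float(lines[1].split("\t")[-1])
    assert total == pytest.approx(
        residue_pair_energy(rec, pep, params, cfg).total_weighted, abs=1e-3)
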