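import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrpocket.consensus import (ContactRecord, PerResidueDDGTable,
                                  TABLE_COLUMNS, aggregate_tables,
                                  detect_contacts, ingest_external_tables,
                                  motif_scan, per_complex_table,
                                  select_consensus)
from gpcrpocket.numbering import build_bw_map
from gpcrpocket.structure_io import ComplexStructure, ConfigurationError
from conftest import make_residue


def toy_complex(gap):
    """Receptor residue and a peptide residue with closest atoms ``gap`` apart."""
    rec = make_residue("ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.53, 0, 0))])
    pep = make_residue("ALA", [("CA", "C", (1.53 + gap + 1.0, 0, 0)),
                               ("CB", "C", (1.53 + gap, 0, 0))], chain_id="P")
    return ComplexStructure("toy", {"A": [rec], "P": [pep]},
                            roles={"A": "receptor", "P": "peptide"})


def test_contact_cutoff_boundary():
    assert len(detect_contacts(toy_complex(4.0), 4.5)) == 1
    assert len(detect_contacts(toy_complex(5.0), 4.5)) == 0
    rec = detect_contacts(toy_complex(4.0), 4.5)[0]
    assert rec.min_heavy_atom_distance == pytest.approx(4.0)


def test_no_peptide_chain_errors():
    cs = ComplexStructure("toy", {"A": [make_residue("ALA", [("CA", "C", (0, 0, 0))])]},
                          roles={"A": "receptor"})
    with pytest.raises(ConfigurationError):
        detect_contacts(cs)


def test_planted_contacts_detected_exactly(planted_complex):
    """The generator's planted positions are exactly the contacting ones."""
    cs, anchors = planted_complex
    bw = build_bw_map(cs.receptor_residues(), anchors)
    got = {bw.label_of(c.receptor_residue[1]) for c in detect_contacts(cs, 4.5)}
    from gpcrpocket.synth import DEFAULT_PLANTED_LABELS
    assert got == set(DEFAULT_PLANTED_LABELS)


def test_per_complex_table(planted_complex, params, cfg):
    cs, anchors = planted_complex
    bw = build_bw_map(cs.receptor_residues(), anchors)
    table = per_complex_table(cs, bw, params, cfg)
    contacts = detect_contacts(cs, 4.5)
    assert len(table.df) == len({c.receptor_residue for c in contacts})
    assert (table.df["ddg"] < 0).all()  # planted contacts are favorable
    assert (table.df["contact"] == 1).all()

    empty = per_complex_table(toy_complex(8.0), bw, params, cfg)
    assert len(empty.df) == 0


def _table(cid, rows):
    df = pd.DataFrame([{"complex_id": cid, "chain": "R", "seq_number": i + 1,
                        "icode": "", "name3": "ALA", "bw_label": lab,
                        "contact": 1, "ddg": ddg}
                       for i, (lab, ddg) in enumerate(rows)])
    if df.empty:
        df = pd.DataFrame(columns=TABLE_COLUMNS)
        df["complex_id"] = [cid][:0]
    return PerResidueDDGTable(complex_id=cid, df=df)


def test_aggregate_arithmetic():
    t1 = _table("C1", [("2.60", -2.0)])
    t2 = _table("C2", [("2.60", -1.0), ("3.32", -0.5)])
    t3 = _table("C3", [("3.32", -1.5)])
    ct = aggregate_tables([t1, t2, t3])
    row = ct.df.set_index("bw_label").loc["2.60"]
    assert row["contact_count"] == 2
    assert row["ddg_sum"] == pytest.approx(-3.0)
    assert row["ddg_avg"] == pytest.approx(-1.5)
    assert np.isnan(row["C3"])
    # single table: average equals each row's own ddg
    ct1 = aggregate_tables([t1])
    assert ct1.df["ddg_avg"].tolist() == ct1.df["C1"].tolist()
    # sorted ascending by average
    assert ct.df["ddg_avg"].is_monotonic_increasing


def test_aggregate_duplicate_label_errors():
    bad = _table("C1", [("2.60", -2.0), ("2.60", -1.0)])
    with pytest.raises(ConfigurationError, match="duplicate"):
        aggregate_tables([bad])


def random_tables(seed, n_complexes=5, n_labels=12):
    rng = np.random.default_rng(seed)
    labels = [f"{rng.integers(1, 8)}.{rng.integers(30, 70)}" for _ in range(n_labels)]
    labels = list(dict.fromkeys(labels))
    tables = []
    for c in range(n_complexes):
        rows = [(lab, float(rng.normal(-1.0, 1.0)))
                for lab in labels if rng.random() < 0.7]
        tables.append(_table(f"C{c}", rows))
    return tables


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_aggregate_and_select_equal_bruteforce(seed):
    """Aggregation and dual-threshold selection against independent
    brute-force enumeration over labels."""
    tables = random_tables(seed)
    ct = aggregate_tables(tables)
    selected = select_consensus(ct, ddg_threshold=-1.0, min_count=3)

    values = {}
    for t in tables:
        for _, row in t.df.iterrows():
            values.setdefault(row["bw_label"], {})[t.complex_id] = row["ddg"]
    expected = set()
    for lab, per in values.items():
        if len(per) >= 3 and np.mean(list(per.values())) < -1.0:
            expected.add(lab)
        row = ct.df.set_index("bw_label").loc[lab]
        assert row["contact_count"] == len(per)
        assert row["ddg_sum"] == pytest.approx(sum(per.values()))
        assert row["ddg_avg"] == pytest.approx(np.mean(list(per.values())))
    assert set(selected) == expected
    # per-complex mode against brute force
    sel_pc = select_consensus(ct, ddg_threshold=-1.0, min_count=3, mode="per_complex")
    expected_pc = {lab for lab, per in values.items()
                   if sum(v < -1.0 for v in per.values()) >= 3}
    assert set(sel_pc) == expected_pc


def test_aggregate_split_identity():
    """Splitting a consensus table into per-complex tables and re-aggregating
    reproduces it exactly."""
    tables = random_tables(9)
    ct = aggregate_tables(tables)
    rebuilt = []
    for cid in ct.complex_ids:
        rows = [(row["bw_label"], row[cid]) for _, row in ct.df.iterrows()
                if not np.isnan(row[cid])]
        rebuilt.append(_table(cid, rows))
    ct2 = aggregate_tables(rebuilt)
    pd.testing.assert_frame_equal(ct.df, ct2.df)


def test_select_edge_cases():
    empty = aggregate_tables([_table("C1", [("2.60", -2.0)])])
    empty.df = empty.df.iloc[0:0]
    assert select_consensus(empty, min_count=1) == []
    ct = aggregate_tables([_table("C1", [("2.60", -2.0)])])
    with pytest.raises(ConfigurationError):
        select_consensus(ct, min_count=2)
    # strict inequality at the threshold
    ct2 = aggregate_tables([_table("C1", [("2.60", -1.0)])])
    assert select_consensus(ct2, ddg_threshold=-1.0, min_count=1) == []


def test_motif_examples():
    both = motif_scan("HAWQF")
    assert both.has_yhxwxf and both.has_xwxf
    assert both.yhxwxf_offsets == [0] and both.xwxf_offsets == [1]
    relaxed = motif_scan("QAWAF")
    assert not relaxed.has_yhxwxf and relaxed.has_xwxf
    neither = motif_scan("AAAAA")
    assert not neither.has_yhxwxf and not neither.has_xwxf
    with pytest.raises(ValueError):
        motif_scan("")


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet=string.ascii_uppercase, min_size=1, max_size=20))
def test_motif_implication(seq):
    """[Y/H]xWxF always contains xWxF: the strict motif implies the relaxed."""
    res = motif_scan(seq)
    if res.has_yhxwxf:
        assert res.has_xwxf
        assert {o + 1 for o in res.yhxwxf_offsets} <= set(res.xwxf_offsets)


def test_ingest_roundtrip_and_ensemble_mean(tmp_path):
    t = _table("C1", [("2.60", -2.0), ("3.32", -0.25)])
    path = tmp_path / "c1.tsv"
    t.to_tsv(path)
    back, = ingest_external_tables([path])
    assert back.complex_id == "C1"
    assert back.df["ddg"].tolist() == pytest.approx(t.df["ddg"].tolist())

    # two models of the same complex are averaged per position
    a = _table("M", [("2.60", -1.0)])
    b = _table("M", [("2.60", -3.0)])
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.to_tsv(pa)
    b.to_tsv(pb)
    merged, = ingest_external_tables([pa, pb])
    assert merged.df["ddg"].iloc[0] == pytest.approx(-2.0)

    bad = tmp_path / "bad.tsv"
    bad.write_text("complex_id\tchain\nC1\tR\n")
    with pytest.raises(ConfigurationError, match="schema"):
        ingest_external_tables([bad])
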