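import numpy as np
import pytest

from ippca import (
    ParseError,
    StructuralError,
    UsageError,
    center_normalize,
    encode_presence,
    encode_table,
    export_structure_inputs,
    read_genotypes,
    run_ippca,
    write_assignments,
    write_genotypes_tsv,
)
from ippca.engine import IppcaConfig

from conftest import make_table


PED_MINIMAL = "F1 ind1 0 0 1 0 A A A G\nF2 ind2 0 0 2 0 G G 0 0\n"
STRUCTURE_EQUIV = (
    "snpA snpB\n"
    "ind1 1 1\nind1 1 2\n"
    "ind2 2 -9\nind2 2 -9\n"
)


def test_read_ped_minimal(tmp_path):
    """Two individuals, two SNPs, one missing call; file order preserved."""
    p = tmp_path / "mini.ped"
    p.write_text(PED_MINIMAL)
    t = read_genotypes(p, "ped")
    assert t.individual_ids == ["ind1", "ind2"]
    assert t.n_markers == 2
    assert t.call_symbols(0, 0) == ("A", "A")
    assert t.call_symbols(0, 1) == ("A", "G")
    assert t.call_symbols(1, 1) == (None, None)
    assert t.is_missing().sum() == 1


def test_ped_map_marker_ids(tmp_path):
    p = tmp_path / "mini.ped"
    p.write_text(PED_MINIMAL)
    (tmp_path / "mini.map").write_text("1 snpA 0 100\n1 snpB 0 200\n")
    t = read_genotypes(p, "ped")
    assert t.marker_ids == ["snpA", "snpB"]


def test_structure_matches_equivalent_ped(tmp_path):
    """The two-row STRUCTURE dialect and PED encode the same table."""
    ped = tmp_path / "mini.ped"
    ped.write_text(PED_MINIMAL)
    st = tmp_path / "mini.str"
    st.write_text(STRUCTURE_EQUIV)
    t_ped = read_genotypes(ped, "ped")
    t_str = read_genotypes(st, "structure")
    assert t_str.individual_ids == t_ped.individual_ids
    assert np.array_equal(t_str.is_missing(), t_ped.is_missing())
    # same genotype partition at each marker despite renamed alleles
    for j in range(2):
        for i in range(2):
            a = set(t_ped.call_symbols(i, j))
            b = set(t_str.call_symbols(i, j))
            assert (None in a) == (None in b)
    ep, _ = encode_presence(t_ped)
    es, _ = encode_presence(t_str)
    assert ep.sum() == es.sum()


def test_tsv_round_trip(tmp_path, two_pop_table):
    path = tmp_path / "panel.tsv"
    sub = two_pop_table.subset(range(10))
    write_genotypes_tsv(sub, path)
    back = read_genotypes(path, "tsv")
    assert back.individual_ids == sub.individual_ids
    assert back.marker_ids == sub.marker_ids
    assert back.labels == sub.labels
    pa, ca = encode_presence(sub)
    pb, cb = encode_presence(back)
    # allele discovery order is data-dependent; compare columns by key
    cols_a = {key: tuple(pa[:, k]) for k, key in enumerate(ca)}
    cols_b = {key: tuple(pb[:, k]) for k, key in enumerate(cb)}
    assert set(cols_b) <= set(cols_a)
    for key in cols_b:
        assert cols_a[key] == cols_b[key]
    for key in set(cols_a) - set(cols_b):  # alleles unseen in the subset
        assert set(cols_a[key]) == {0.0}


def test_microsatellite_allele_set_discovered():
    """A 5-allele microsatellite marker yields a 5-symbol allele set."""
    t = make_table([[("150", "154")], [("150", "158")], [("162", "166")], [("154", "154")]])
    assert len(t.marker_alleles[0]) == 5
    P, cols = encode_presence(t)
    assert P.shape == (4, 5)


def test_parse_errors_name_the_line(tmp_path):
    bad = tmp_path / "bad.ped"
    bad.write_text("F1 ind1 0 0 1 0 A A\nF2 ind2 0 0 1 0 A\n")
    with pytest.raises(ParseError, match="bad.ped:2"):
        read_genotypes(bad, "ped")
    ragged = tmp_path / "ragged.tsv"
    ragged.write_text("id\tm1\tm2\ni1\tA/A\tA/G\ni2\tG/G\n")
    with pytest.raises(StructuralError, match="ragged.tsv:3"):
        read_genotypes(ragged, "tsv")
    with pytest.raises(UsageError):
        read_genotypes(tmp_path / "nope.tsv", "tsv")


def test_encode_presence_biallelic():
    """AA/AG/GG become rows (1,0)/(1,1)/(0,1) in columns (A, G)."""
    t = make_table([[("A", "A")], [("A", "G")], [("G", "G")]])
    P, cols = encode_presence(t)
    assert cols == [("m1", "A"), ("m1", "G")]
    assert np.array_equal(P, [[1, 0], [1, 1], [0, 1]])


def test_encode_missing_is_all_zero():
    t = make_table([[("A", "G")], [None]])
    P, _ = encode_presence(t)
    assert np.array_equal(P[1], [0, 0])


def test_encode_microsatellite_presence_sets():
    """Hand-enumerated presence rows for a 3-allele marker."""
    t = make_table([[("1", "2")], [("1", "1")], [("2", "3")]])
    P, cols = encode_presence(t)
    assert [a for _, a in cols] == ["1", "2", "3"]
    assert np.array_equal(P, [[1, 1, 0], [1, 0, 0], [0, 1, 1]])


def test_all_missing_marker_dropped_with_warning():
    t = make_table([[("A", "A"), None], [("A", "G"), None]])
    with pytest.warns(UserWarning, match="no observed alleles"):
        P, cols = encode_presence(t)
    assert P.shape == (2, 2)  # only m1's two allele columns remain


def test_center_normalize_hand_computed():
    """Column (1,1,0,0): q = 0.5, centered +-0.5, scaled by sqrt(0.25) -> +-1."""
    P = np.array([[1.0], [1.0], [0.0], [0.0]])
    enc = center_normalize(P)
    assert np.allclose(enc.values[:, 0], [1, 1, -1, -1])
    assert enc.column_freq[0] == 0.5


def test_center_normalize_degenerate_and_zero_sums():
    P = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    enc = center_normalize(P)
    assert np.all(enc.values[:, 0] == 0.0)  # all-ones column zeroed
    assert np.all(enc.values[:, 2] == 0.0)  # all-zeros column zeroed
    assert np.allclose(enc.values.sum(axis=0), 0.0)
    assert np.all(np.isfinite(enc.values))


def test_column_count_is_sum_of_allele_counts(two_pop_table):
    enc = encode_table(two_pop_table.subset(range(20)))
    expected = sum(len(a) for a in two_pop_table.marker_alleles)
    assert enc.n == expected
    assert np.allclose(enc.values.sum(axis=0), 0.0, atol=1e-9)


def test_write_assignments_and_leaf_order(tmp_path, two_pop_table, two_pop_tree):
    tsv = tmp_path / "assign.tsv"
    tree_json = tmp_path / "tree.json"
    write_assignments(two_pop_tree, two_pop_table, tsv, tree_json)
    lines = tsv.read_text().splitlines()
    assert lines[0] == "individual_id\tsubpopulation\tlabel"
    assert len(lines) == two_pop_table.n_individuals + 1
    labels = {ln.split("\t")[1] for ln in lines[1:]}
    assert labels == {f"SP{k + 1}" for k in range(two_pop_tree.K)}
    # depth-first discovery order: SP1 holds the lowest original index
    assert two_pop_tree.assignment[two_pop_table.individual_ids[0]] == "SP1"
    assert tree_json.exists()


def test_export_structure_round_trip(tmp_path, two_pop_table, two_pop_tree):
    """Re-reading an exported STRUCTURE file recovers the selected subset."""
    out = tmp_path / "sel.str"
    leaves = [two_pop_tree.leaves()[0].leaf_label]
    export_structure_inputs(two_pop_tree, two_pop_table, leaves, out)
    selected = [
        i for i in two_pop_table.individual_ids if two_pop_tree.assignment[i] in set(leaves)
    ]
    lines = out.read_text().splitlines()
    assert len(lines) == 1 + 2 * len(selected)  # header + two rows per diploid
    back = read_genotypes(out, "structure")
    assert back.individual_ids == selected
    assert back.marker_ids == two_pop_table.marker_ids
    sub = two_pop_table.subset(
        [two_pop_table.individual_ids.index(i) for i in selected]
    )
    assert np.array_equal(back.is_missing(), sub.is_missing())
    pa, _ = encode_presence(sub)
    pb, _ = encode_presence(back)
    assert pa.sum() == pb.sum()


def test_export_structure_errors(tmp_path, two_pop_table, two_pop_tree):
    with pytest.raises(UsageError, match="empty"):
        export_structure_inputs(two_pop_tree, two_pop_table, [], tmp_path / "x")
    with pytest.raises(UsageError, match="unknown leaf"):
        export_structure_inputs(two_pop_tree, two_pop_table, ["SP99"], tmp_path / "x")
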