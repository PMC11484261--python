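"""Contig table reading, normalization and round trips."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from dualtcr.contigs import (
    read_contigs,
    strip_allele,
    write_contigs,
)
from dualtcr.errors import SchemaError
from conftest import make_contig

TENX_HEADER = (
    "barcode,is_cell,contig_id,high_confidence,chain,v_gene,d_gene,j_gene,"
    "c_gene,full_length,productive,cdr3,cdr3_nt,reads,umis"
)


def _tenx_csv(rows):
    return io.StringIO("\n".join([TENX_HEADER, *rows]) + "\n")


def test_reads_well_formed_tenx_rows():
    rows = [
        "AAACCTGAGT-1,True,c1,True,TRA,TRAV1,None,TRAJ33,TRAC,True,True,CAVR,TGTGCTGTG,100,4",
        "AAACCTGAGT-1,True,c2,True,TRB,TRBV2,TRBD1,TRBJ1-1,TRBC1,True,False,CASS,TGCAGTAGT,80,3",
        "AAACCTGAGC-1,False,c3,True,Multi,None,None,None,None,True,None,None,None,10,1",
    ]
    records = read_contigs(_tenx_csv(rows), "tenx_csv", "S1")
    assert len(records) == 3
    r1, r2, r3 = records
    assert r1.is_cell and r1.productive is True and r1.chain == "TRA"
    assert r1.sample_id == "S1" and r1.umis == 4
    assert r2.productive is False and r2.d_gene == "TRBD1"
    assert not r3.is_cell and r3.v_gene is None


def test_productive_none_parses_as_undetermined():
    # assemblers emit "None" (and some versions "Non") when a rearrangement
    # cannot be classified; both must map to the undetermined state
    for spelling in ("None", "Non", ""):
        rows = [f"BC-1,True,c1,True,TRA,TRAV1,,TRAJ3,TRAC,True,{spelling},CA,TGTGC,9,2"]
        (rec,) = read_contigs(_tenx_csv(rows), "tenx_csv", "S")
        assert rec.productive is None


def test_boolean_spellings_accepted():
    rows = ["BC-1,TRUE,c1,false,TRA,TRAV1,,TRAJ3,TRAC,True,true,CA,TGTGC,9,2"]
    (rec,) = read_contigs(_tenx_csv(rows), "tenx_csv", "S")
    assert rec.is_cell is True and rec.high_confidence is False


def test_missing_required_column_names_the_column():
    bad = io.StringIO("barcode,is_cell\nBC-1,True\n")
    with pytest.raises(SchemaError, match="high_confidence"):
        read_contigs(bad, "tenx_csv", "S")


def test_unparseable_row_reports_row_number():
    rows = [
        "BC-1,True,c1,True,TRA,TRAV1,,TRAJ3,TRAC,True,True,CA,TGTGC,9,2",
        "BC-2,maybe,c2,True,TRA,TRAV1,,TRAJ3,TRAC,True,True,CA,TGTGC,9,2",
    ]
    with pytest.raises(SchemaError, match="row 2"):
        read_contigs(_tenx_csv(rows), "tenx_csv", "S")


def test_airr_mapping_and_allele_stripping():
    airr = io.StringIO(
        "cell_id\tsequence_id\tlocus\tv_call\td_call\tj_call\tjunction\t"
        "junction_aa\tproductive\tduplicate_count\n"
        "BC-1\tseq1\tTRB\tTRBV20-1*01\tTRBD1*01\tTRBJ2-7*01\tTGCAGT\tCS\tT\t5\n"
    )
    (rec,) = read_contigs(airr, "airr_tsv", "S2")
    assert rec.barcode == "BC-1"
    assert rec.v_gene == "TRBV20-1"  # allele suffix stripped
    assert rec.j_gene == "TRBJ2-7"
    assert rec.cdr3_nt == "TGCAGT"
    assert rec.umis == 5
    # dialect lacks the 10x QC flags: they default to confident cell calls
    assert rec.is_cell is True and rec.high_confidence is True


@pytest.mark.parametrize(
    "raw,stripped",
    [("TRBV20-1*01", "TRBV20-1"), ("TRAV1-2", "TRAV1-2"), (None, None)],
)
def test_strip_allele(raw, stripped):
    assert strip_allele(raw) == stripped


@pytest.mark.parametrize("dialect", ["tenx_csv", "airr_tsv"])
def test_round_trip_identity(tmp_path, dialect):
    records = [
        make_contig(chain="TRA", productive=p, umis=u)
        for p, u in [(True, 3), (False, 1), (None, 7)]
    ] + [make_contig(chain="TRB", v_gene="TRBV9", j_gene="TRBJ1-1")]
    path = tmp_path / f"contigs.{dialect}"
    write_contigs(records, path, dialect)
    back = read_contigs(path, dialect, "S1")
    assert len(back) == len(records)
    # fields every dialect supports must survive unchanged
    for orig, rt in zip(records, back):
        for f in ("barcode", "contig_id", "chain", "v_gene", "j_gene",
                  "cdr3_nt", "productive", "umis"):
            assert getattr(rt, f) == getattr(orig, f), f


def test_empty_record_list_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_contigs([], path, "tenx_csv")
    assert read_contigs(path, "tenx_csv", "S") == []
    assert path.read_text().strip().startswith("barcode,")


def test_tenx_airr_tenx_loses_only_qc_flags(tmp_path):
    """Cross-dialect round trip: AIRR cannot carry is_cell/high_confidence."""
    rec = make_contig(is_cell=False, high_confidence=False, chain="TRB",
                      v_gene="TRBV9", j_gene="TRBJ1-1")
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.csv"
    write_contigs([rec], p1, "airr_tsv")
    (via_airr,) = read_contigs(p1, "airr_tsv", "S1")
    write_contigs([via_airr], p2, "tenx_csv")
    (back,) = read_contigs(p2, "tenx_csv", "S1")
    assert back.is_cell is True and back.high_confidence is True  # lost, documented
    for f in ("barcode", "contig_id", "chain", "v_gene", "j_gene", "cdr3_nt",
              "productive", "umis"):
        assert getattr(back, f) == getattr(rec, f)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["TRA", "TRB", "TRG"]),
            st.booleans(),
            st.sampled_from([True, False, None]),
            st.integers(min_value=0, max_value=10_000),
        ),
        max_size=20,
    )
)
def test_round_trip_property_tenx(rows):
    """Write/read is the identity on supported fields for arbitrary records."""
    records = [
        make_contig(chain=chain, is_cell=is_cell, productive=productive, umis=umis)
        for chain, is_cell, productive, umis in rows
    ]
    buf = io.StringIO()
    write_contigs(records, buf, "tenx_csv")
    buf.seek(0)
    back = read_contigs(buf, "tenx_csv", "S1")
    assert [
        (r.barcode, r.chain, r.is_cell, r.productive, r.umis) for r in back
    ] == [(r.barcode, r.chain, r.is_cell, r.productive, r.umis) for r in records]


def test_negative_counts_rejected():
    with pytest.raises(SchemaError, match="umis"):
        make_contig(umis=-1)
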