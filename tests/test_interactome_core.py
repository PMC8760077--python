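import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapline.errors import ValidationError
from trapline import interactome_core as ic

from conftest import record, table


# ---------------------------------------------------------------------------
# drop_single_peptide
# ---------------------------------------------------------------------------


def test_single_peptide_removed():
    t = table([record("P1", unique_peptides=1, psms=1)])
    assert len(ic.drop_single_peptide(t)) == 0


def test_two_peptides_kept():
    t = table([record("P1", unique_peptides=2)])
    assert ic.drop_single_peptide(t).accessions() == ["P1"]


def test_drop_single_peptide_empty_table():
    t = table([])
    assert len(ic.drop_single_peptide(t)) == 0


def test_drop_single_peptide_idempotent(small_table):
    once = ic.drop_single_peptide(small_table)
    assert ic.drop_single_peptide(once) == once


# ---------------------------------------------------------------------------
# subtract_background
# ---------------------------------------------------------------------------


def control_table(records):
    return table(records, sample_id="ctrl", bait="control", condition="trap")


def test_protein_with_three_control_peptides_removed():
    t = table([record("P1")])
    ctrl = control_table([record("P1", unique_peptides=3)])
    assert len(ic.subtract_background(t, ctrl)) == 0


def test_protein_with_two_control_peptides_kept():
    t = table([record("P1")])
    ctrl = control_table([record("P1", unique_peptides=2)])
    assert ic.subtract_background(t, ctrl).accessions() == ["P1"]


def test_protein_absent_from_control_kept():
    t = table([record("P1")])
    ctrl = control_table([record("P9", unique_peptides=5)])
    assert ic.subtract_background(t, ctrl).accessions() == ["P1"]


def test_empty_control_warns_and_is_noop(caplog):
    t = table([record("P1")])
    ctrl = control_table([])
    with caplog.at_level("WARNING"):
        out = ic.subtract_background(t, ctrl)
    assert out.accessions() == ["P1"]
    assert "empty" in caplog.text


# ---------------------------------------------------------------------------
# aggregate_replicates
# ---------------------------------------------------------------------------


def test_aggregate_sum_of_psms():
    tables = [
        table([record("P1", psms=p, unique_peptides=2)],
              sample_id=f"s{i}", replicate=i + 1)
        for i, p in enumerate([4, 6, 5])
    ]
    out = ic.aggregate_replicates(tables, "sum")
    assert out.get("P1").psms == 15
    assert out.get("P1").unique_peptides == 6


def test_aggregate_single_table_identity(small_table):
    out = ic.aggregate_replicates([small_table])
    assert out.records == small_table.records


def test_aggregate_disjoint_union_missing_as_zero():
    t1 = table([record("P1", psms=4)], sample_id="a")
    t2 = table([record("P2", psms=6)], sample_id="b", replicate=2)
    out = ic.aggregate_replicates([t1, t2], "sum")
    assert out.get("P1").psms == 4
    assert out.get("P2").psms == 6


def test_aggregate_ms_score_by_maximum():
    t1 = table([record("P1", ms_score=50.0)], sample_id="a")
    t2 = table([record("P1", ms_score=80.0)], sample_id="b", replicate=2)
    assert ic.aggregate_replicates([t1, t2]).get("P1").ms_score == 80.0


def test_aggregate_mixed_conditions_is_error():
    t1 = table([record("P1")], condition="trap")
    t2 = table([record("P1")], condition="reference")
    with pytest.raises(ValidationError, match="condition"):
        ic.aggregate_replicates([t1, t2])


def test_aggregate_mean_rounded():
    tables = [
        table([record("P1", psms=p, unique_peptides=2)],
              sample_id=f"s{i}", replicate=i + 1)
        for i, p in enumerate([4, 6, 5])
    ]
    assert ic.aggregate_replicates(tables, "mean_rounded").get("P1").psms == 5


# ---------------------------------------------------------------------------
# enrichment_ratio
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("trap,ref,expected", [
    (10, 4, 2.5),
    (4, None, 4.0),   # absent reference: divide by pseudocount 1
    (4, 0, 4.0),      # zero reference treated like absent
    (0, 7, 0.0),
    (0, None, 0.0),
])
def test_enrichment_ratio_values(trap, ref, expected):
    assert ic.enrichment_ratio(trap, ref) == pytest.approx(expected)


def test_enrichment_ratio_both_absent_is_error():
    with pytest.raises(ValidationError):
        ic.enrichment_ratio(None, None)


@given(st.integers(0, 500), st.integers(0, 500))
def test_ratio_finite_and_monotone_in_trap(psm_trap, psm_ref):
    r = ic.enrichment_ratio(psm_trap, psm_ref)
    assert r >= 0 and r == r  # finite, not NaN
    assert ic.enrichment_ratio(psm_trap + 1, psm_ref) > r


# ---------------------------------------------------------------------------
# build_enrichment
# ---------------------------------------------------------------------------


def test_build_enrichment_ratio_composition():
    trap = table([record("P1", psms=10)])
    ref = table([record("P1", psms=4)], condition="reference", sample_id="r")
    records, ref_only = ic.build_enrichment(trap, ref)
    assert records[0].ratio == pytest.approx(2.5)
    assert ref_only == []


def test_build_enrichment_pseudocount_for_missing_reference():
    trap = table([record("P2", psms=5)])
    ref = table([], condition="reference", sample_id="r")
    records, _ = ic.build_enrichment(trap, ref)
    assert records[0].ratio == pytest.approx(5.0)
    assert records[0].psm_ref is None


def test_build_enrichment_empty_trap():
    trap = table([])
    ref = table([record("P1")], condition="reference", sample_id="r")
    records, ref_only = ic.build_enrichment(trap, ref)
    assert records == []
    assert ref_only == ["P1"]


def test_build_enrichment_flag_mode_annotates():
    trap = table([
        record("P1", unique_peptides=1, psms=1),
        record("P2"),
        record("P3"),
    ])
    ref = table([], condition="reference", sample_id="r")
    ctrl = control_table([record("P3", unique_peptides=4)])
    records, _ = ic.build_enrichment(trap, ref, control=ctrl, flag_mode=True)
    flags = {r.accession: r.filter_flags for r in records}
    assert flags["P1"] == {ic.SINGLE_PEPTIDE}
    assert flags["P2"] == frozenset()
    assert flags["P3"] == {ic.CONTROL_BACKGROUND}


# ---------------------------------------------------------------------------
# prioritize
# ---------------------------------------------------------------------------


def enr(acc, ratio, score, flags=frozenset()):
    return ic.EnrichmentRecord(acc, f"G{acc}", int(ratio * 4), 4, ratio, score,
                               frozenset(flags))


def test_prioritize_ratio_first_ordering():
    out = ic.prioritize([enr("A", 2.0, 100.0), enr("B", 3.0, 100.0)],
                        min_ratio=0, strategy="ratio_first")
    assert [r.accession for r in out] == ["B", "A"]


def test_prioritize_score_first_ordering():
    out = ic.prioritize([enr("A", 3.0, 50.0), enr("B", 2.0, 100.0)],
                        min_ratio=0, strategy="score_first")
    assert [r.accession for r in out] == ["B", "A"]


def test_prioritize_threshold_excludes():
    out = ic.prioritize([enr("A", 1.5, 100.0), enr("B", 2.5, 100.0)],
                        min_ratio=2.0)
    assert [r.accession for r in out] == ["B"]


def test_prioritize_tie_broken_by_accession():
    out = ic.prioritize([enr("Z", 2.0, 10.0), enr("A", 2.0, 10.0)], min_ratio=0)
    assert [r.accession for r in out] == ["A", "Z"]


def test_prioritize_never_emits_flagged():
    out = ic.prioritize([enr("A", 5.0, 100.0, {ic.SINGLE_PEPTIDE})])
    assert out == []


# ---------------------------------------------------------------------------
# compare_baits
# ---------------------------------------------------------------------------


def test_compare_baits_joint_row():
    rows = ic.compare_baits([enr("P", 5.0, 10.0)], [enr("P", 1.0, 10.0)])
    (row,) = rows
    assert (row.ratio_wt, row.ratio_mut) == (5.0, 1.0)
    assert row.present_wt and row.present_mut


def test_compare_baits_wt_only():
    (row,) = ic.compare_baits([enr("P", 4.0, 10.0)], [])
    assert row.ratio_wt == 4.0
    assert row.ratio_mut is None
    assert row.present_wt and not row.present_mut


def test_compare_baits_disjoint_inputs():
    rows = ic.compare_baits([enr("A", 2.0, 1.0)], [enr("B", 3.0, 1.0)])
    assert [(r.present_wt, r.present_mut) for r in rows] == [
        (True, False), (False, True)
    ]


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

row_strategy = st.tuples(
    st.integers(1, 8),     # unique peptides
    st.integers(1, 40),    # psms
    st.booleans(),         # present in control?
    st.integers(0, 6),     # control unique peptides
)


def build_tables(rows):
    records, control_records = [], []
    for i, (up, psms, in_control, ctrl_up) in enumerate(rows):
        acc = f"P{i:03d}"
        records.append(record(acc, unique_peptides=up, psms=psms))
        if in_control and ctrl_up > 0:
            control_records.append(
                record(acc, unique_peptides=ctrl_up, psms=ctrl_up * 2)
            )
    return table(records), table(
        control_records, sample_id="ctrl", bait="control"
    )


@given(st.lists(row_strategy, max_size=50))
@settings(max_examples=60, deadline=None)
def test_filter_order_commutes(rows):
    t, ctrl = build_tables(rows)
    a = ic.subtract_background(ic.drop_single_peptide(t), ctrl)
    b = ic.drop_single_peptide(ic.subtract_background(t, ctrl))
    assert a == b


def cascade_oracle(rows, max_control_unique=2):
    """Independent per-row re-evaluation of the filter predicates."""
    survivors = set()
    for i, (up, psms, in_control, ctrl_up) in enumerate(rows):
        acc = f"P{i:03d}"
        if up <= 1:
            continue
        if in_control and ctrl_up > max_control_unique:
            continue
        survivors.add(acc)
    return survivors


@given(st.lists(row_strategy, max_size=50))
@settings(max_examples=60, deadline=None)
def test_cascade_equals_brute_force_oracle(rows):
    t, ctrl = build_tables(rows)
    filtered = ic.subtract_background(ic.drop_single_peptide(t), ctrl)
    assert set(filtered.accessions()) == cascade_oracle(rows)


@given(st.lists(row_strategy, max_size=30))
@settings(max_examples=30, deadline=None)
def test_flag_mode_agrees_with_deletion_mode(rows):
    t, ctrl = build_tables(rows)
    deleted = ic.subtract_background(ic.drop_single_peptide(t), ctrl)
    flags = ic.filter_flags(t, ctrl)
    unflagged = {acc for acc, f in flags.items() if not f}
    assert unflagged == set(deleted.accessions())
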