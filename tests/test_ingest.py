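"""Demultiplexing, trimming, binning and pre-filtering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pyrodenoise as pn
from pyrodenoise import ingest

from conftest import make_table, wrap_read

FWD = "TGGTGCATGGCCGTTCTTAG"
REV = "GGTCTGTGATGCCCTTAGAT"
MIDS = {("ACGAGTGC", "ACGTCTGA"): "S1", ("AGCACTGT", "ACGTCTGA"): "S2"}


@pytest.fixture
def spec():
    return pn.PrimerSpec(FWD, REV, MIDS, min_length=4)


def test_exact_match_accepted_and_trimmed(spec):
    read = pn.RawRead("r1", wrap_read("ACGTACGT", "ACGAGTGC", "ACGTCTGA", spec))
    out = pn.accept_and_trim(read, spec)
    assert isinstance(out, pn.Accepted)
    assert out.sequence == "ACGTACGT"
    assert out.sample == "S1"
    assert FWD not in out.sequence and pn.revcomp(REV) not in out.sequence


def test_substitution_in_forward_primer_rejects(spec):
    bad_primer = "A" + FWD[1:] if FWD[0] != "A" else "C" + FWD[1:]
    read = pn.RawRead("r1", "ACGAGTGC" + bad_primer + "ACGTACGT"
                      + pn.revcomp(REV) + pn.revcomp("ACGTCTGA"))
    out = pn.accept_and_trim(read, spec)
    assert isinstance(out, pn.Rejected)
    assert out.reason == ingest.NO_FORWARD_PRIMER


def test_missing_reverse_primer_rejects(spec):
    read = pn.RawRead("r1", "ACGAGTGC" + FWD + "ACGTACGTACGT")
    out = pn.accept_and_trim(read, spec)
    assert out.reason == ingest.NO_REVERSE_PRIMER


def test_unknown_mid_pair_rejects(spec):
    read = pn.RawRead("r1", wrap_read("ACGTACGT", "ACGAGTGC", "TTTTTTTT", spec))
    out = pn.accept_and_trim(read, spec)
    assert out.reason == ingest.UNKNOWN_MID


def test_short_insert_rejects(spec):
    read = pn.RawRead("r1", wrap_read("ACG", "ACGAGTGC", "ACGTCTGA", spec))
    assert pn.accept_and_trim(read, spec).reason == ingest.TOO_SHORT


def test_truncation_mode_skips_reverse_search():
    spec = pn.PrimerSpec(FWD, REV, MIDS, truncate_at=6)
    read = pn.RawRead("r1", "ACGAGTGC" + FWD + "ACGTACGTACGT")  # no reverse primer
    out = pn.accept_and_trim(read, spec)
    assert isinstance(out, pn.Accepted)
    assert out.sequence == "ACGTAC"
    assert out.sample == "S1"


def test_trimming_is_idempotent(spec):
    read = pn.RawRead("r1", wrap_read("ACGTACGTAA", "ACGAGTGC", "ACGTCTGA", spec))
    trimmed = pn.accept_and_trim(read, spec).sequence
    again = pn.accept_and_trim(pn.RawRead("r2", trimmed), spec)
    assert isinstance(again, pn.Rejected)


@settings(max_examples=50, derandomize=True, database=None)
@given(st.text(alphabet="ACGT", min_size=4, max_size=40))
def test_wrapped_insert_roundtrips(insert):
    spec = pn.PrimerSpec(FWD, REV, MIDS, min_length=4)
    read = pn.RawRead("r", wrap_read(insert, "AGCACTGT", "ACGTCTGA", spec))
    out = pn.accept_and_trim(read, spec)
    assert isinstance(out, pn.Accepted)
    # the recovered insert must contain the original (a chance internal
    # primer/MID occurrence can only extend the match, never corrupt it)
    assert insert in out.sequence or out.sequence in read.bases


def test_accept_reject_partition(spec):
    rng = random.Random(0)
    reads = []
    for i in range(50):
        insert = "".join(rng.choice("ACGT") for _ in range(20))
        if i % 3 == 0:
            reads.append(pn.RawRead(f"r{i}", insert))  # no primers at all
        else:
            reads.append(pn.RawRead(f"r{i}", wrap_read(insert, "ACGAGTGC", "ACGTCTGA", spec)))
    accepted, rejected = pn.demultiplex(reads, spec)
    assert len(accepted) + len(rejected) == len(reads)
    assert all(r.reason for r in rejected)


def test_abundance_table_counting():
    accepted = [pn.Accepted(f"r{i}", "S1", "AAA") for i in range(3)]
    accepted.append(pn.Accepted("r4", "S2", "AAA"))
    table = pn.build_abundance_table(accepted)
    assert len(table) == 1
    seq_id = table.ids_by_rank[0]
    assert table.total(seq_id) == 4
    assert table.sample_counts(seq_id) == {"S1": 3, "S2": 1}


def test_abundance_table_empty_and_binning():
    assert len(pn.build_abundance_table([])) == 0
    table = pn.build_abundance_table(
        [pn.Accepted("a", "S1", "AAAA"), pn.Accepted("b", "S1", "AAAT")]
    )
    assert len(table) == 2  # one-base difference -> distinct rows


def test_table_order_independence(spec):
    rng = random.Random(1)
    inserts = ["".join(rng.choice("ACGT") for _ in range(15)) for _ in range(10)]
    reads = [
        pn.RawRead(f"r{i}", wrap_read(inserts[i % len(inserts)], "ACGAGTGC", "ACGTCTGA", spec))
        for i in range(40)
    ]
    accepted1, _ = pn.demultiplex(reads, spec)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    accepted2, _ = pn.demultiplex(shuffled, spec)
    t1 = pn.build_abundance_table(accepted1)
    t2 = pn.build_abundance_table(accepted2)
    assert t1.to_frame().equals(t2.to_frame())


def test_prefilter_rules(spec):
    table = make_table(
        {
            "AAAACCCCGGGG": {"S1": 1},                  # global singleton
            "AAAACCCCGGGT": {"S1": 1, "S2": 2},          # local singleton, retained
            "AAAANCCCGGGG": {"S1": 5},                   # ambiguous base
            "AAAA" + FWD + "GGGG": {"S1": 5},            # residual primer
        },
        samples=["S1", "S2"],
    )
    filtered, log = pn.prefilter(table, spec)
    kept = {filtered.sequence(i) for i in filtered.ids_by_rank}
    assert kept == {"AAAACCCCGGGT"}
    reasons = {table.sequence(i): r for i, r in log}
    assert reasons["AAAACCCCGGGG"] == ingest.GLOBAL_SINGLETON
    assert reasons["AAAANCCCGGGG"] == ingest.AMBIGUOUS_BASE
    assert reasons["AAAA" + FWD + "GGGG"] == ingest.MULTIPLE_PRIMER


def test_no_singleton_survives_prefilter(spec):
    rng = random.Random(2)
    rows = {}
    for i in range(30):
        seq = "".join(rng.choice("ACGT") for _ in range(25))
        rows[seq] = {"S1": rng.choice([1, 1, 2, 5])}
    filtered, _ = pn.prefilter(make_table(rows, samples=["S1"]), spec)
    assert all(filtered.total(i) >= 2 for i in filtered.ids_by_rank)


def test_fasta_parse_errors(tmp_path):
    bad = tmp_path / "dup.fasta"
    bad.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(pn.ParseError, match="a"):
        pn.read_fasta(bad)
    empty_seq = tmp_path / "empty.fasta"
    empty_seq.write_text(">x\n\n>y\nACGT\n")
    with pytest.raises(pn.ParseError, match="x"):
        pn.read_fasta(empty_seq)


def test_mid_map_roundtrip(tmp_path):
    path = tmp_path / "mids.tsv"
    ingest.write_mid_map(MIDS, path)
    assert ingest.read_mid_map(path) == MIDS
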