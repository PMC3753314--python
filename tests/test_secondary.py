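"""Per-sample error-type tests: thresholds, indel/substitution/chimera flags."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pyrodenoise as pn
from pyrodenoise import secondary


@pytest.mark.parametrize(
    "a,n,x,expected",
    [
        (1000, 1, 0.02, 20.0),
        (1000, 3, 0.02, 0.008),
        (50, 2, 0.5, 12.5),
    ],
)
def test_substitution_threshold_values(a, n, x, expected):
    assert pn.substitution_threshold(a, n, x) == pytest.approx(expected)


@pytest.mark.parametrize(
    "b,s,y,expected",
    [
        (200, 1, 0.15, 30.0),
        (200, 2, 0.15, 4.5),
        (10, 3, 0.15, 0.03375),
    ],
)
def test_chimera_threshold_values(b, s, y, expected):
    assert pn.chimera_threshold(b, s, y) == pytest.approx(expected)


def test_threshold_preconditions():
    with pytest.raises(ValueError):
        pn.substitution_threshold(10, 0, 0.02)
    with pytest.raises(ValueError):
        pn.chimera_threshold(10, 0, 0.15)


@settings(max_examples=200, derandomize=True, database=None)
@given(
    a=st.integers(1, 10**6),
    n=st.integers(1, 20),
    x=st.floats(0.001, 0.999),
)
def test_substitution_threshold_monotonicity(a, n, x):
    t = pn.substitution_threshold(a, n, x)
    assert pn.substitution_threshold(a, n + 1, x) < t
    assert pn.substitution_threshold(a, n, min(x * 1.5, 1.0)) >= t


@settings(max_examples=200, derandomize=True, database=None)
@given(
    b=st.integers(1, 10**6),
    s=st.integers(1, 20),
    y=st.floats(0.001, 0.999),
)
def test_chimera_threshold_monotonicity(b, s, y):
    t = pn.chimera_threshold(b, s, y)
    assert pn.chimera_threshold(b, s + 1, y) < t
    assert pn.chimera_threshold(b, s, min(y * 1.5, 1.0)) >= t


def _rand_seq(rng, n=60):
    return "".join(rng.choice("ACGT") for _ in range(n))


def test_single_sequence_sample_is_valid(params):
    flags = pn.validate_sample("S1", {"u1": 5}, {"u1": "ACGTACGTAC"}, params)
    assert flags == [pn.SampleFlag("u1", "S1", secondary.VALID, observed=5)]


def test_substitution_variant_flagged(params):
    rng = random.Random(0)
    parent = _rand_seq(rng, 100)
    daughter = parent[:40] + ("A" if parent[40] != "A" else "C") + parent[41:]
    flags = pn.validate_sample(
        "S1", {"p": 1000, "d": 10}, {"p": parent, "d": daughter}, params
    )
    by_id = {f.sequence_id: f for f in flags}
    assert by_id["p"].status == secondary.VALID
    assert by_id["d"].status == secondary.INVALID
    assert by_id["d"].firing_test == secondary.SUBSTITUTION
    assert by_id["d"].threshold == pytest.approx(20.0)  # 1000 * 0.02

    # at or above the threshold the variant survives ('fewer than' is strict)
    flags = pn.validate_sample(
        "S1", {"p": 1000, "d": 20}, {"p": parent, "d": daughter}, params
    )
    assert {f.sequence_id: f.status for f in flags}["d"] == secondary.VALID


def test_indel_pair_flags_lower_ranked(params):
    rng = random.Random(1)
    parent = _rand_seq(rng, 60) + "TTT" + _rand_seq(rng, 20)
    shorter = parent[:61] + parent[62:]  # one base removed from the homopolymer
    flags = pn.validate_sample(
        "S1", {"p": 200, "d": 30}, {"p": parent, "d": shorter}, params
    )
    by_id = {f.sequence_id: f for f in flags}
    assert by_id["d"].firing_test == secondary.INDEL
    assert by_id["p"].status == secondary.VALID


def test_indel_plus_substitution_does_not_fire_indel(params):
    rng = random.Random(2)
    parent = _rand_seq(rng, 60) + "TTT" + _rand_seq(rng, 20)
    variant = list(parent[:61] + parent[62:])
    variant[10] = "A" if variant[10] != "A" else "C"
    flags = pn.validate_sample(
        "S1", {"p": 200, "d": 30}, {"p": parent, "d": "".join(variant)}, params
    )
    by_id = {f.sequence_id: f for f in flags}
    assert by_id["d"].firing_test != secondary.INDEL
    assert by_id["d"].status == secondary.VALID  # neither pure test applies


def test_single_read_is_ambiguous_regardless(params):
    rng = random.Random(3)
    parent = _rand_seq(rng, 100)
    daughter = parent[:10] + ("A" if parent[10] != "A" else "C") + parent[11:]
    flags = pn.validate_sample(
        "S1", {"p": 1000, "d": 1}, {"p": parent, "d": daughter}, params
    )
    assert {f.sequence_id: f.status for f in flags}["d"] == secondary.AMBIGUOUS


def test_chimera_daughter_flagged(params):
    # parents diverged by scattered substitutions, one-breakpoint hybrid
    rng = random.Random(4)
    p1 = _rand_seq(rng, 100)
    p2 = list(p1)
    for pos in rng.sample(range(100), 10):
        p2[pos] = "ACGT"[("ACGT".index(p2[pos]) + 1) % 4]
    p2 = "".join(p2)
    d = p1[:50] + p2[50:]
    flags = pn.validate_sample(
        "S1", {"a": 500, "b": 200, "d": 5}, {"a": p1, "b": p2, "d": d}, params
    )
    by_id = {f.sequence_id: f for f in flags}
    assert by_id["d"].firing_test == secondary.CHIMERA
    assert by_id["d"].threshold == pytest.approx(200 * 0.15)  # b * y**1
    # an abundant daughter at/above b*y survives the chimera test
    flags = pn.validate_sample(
        "S1", {"a": 500, "b": 200, "d": 30}, {"a": p1, "b": p2, "d": d}, params
    )
    assert {f.sequence_id: f.status for f in flags}["d"] == secondary.VALID


def test_most_abundant_sequence_never_flagged(params):
    rng = random.Random(5)
    seqs = {f"u{i}": _rand_seq(rng, 50) for i in range(6)}
    counts = {f"u{i}": 100 - 10 * i for i in range(6)}
    flags = pn.validate_sample("S1", counts, seqs, params)
    top = max(counts, key=lambda i: (counts[i], i))
    assert {f.sequence_id: f.status for f in flags}[top] == secondary.VALID


def test_validate_sample_order_independent(params):
    rng = random.Random(6)
    seqs = {f"u{i}": _rand_seq(rng, 50) for i in range(8)}
    counts = {f"u{i}": rng.randint(2, 80) for i in range(8)}
    ref = pn.validate_sample("S1", counts, seqs, params)
    items = list(counts.items())
    rng.shuffle(items)
    permuted = pn.validate_sample("S1", dict(items), seqs, params)
    assert sorted(ref, key=lambda f: f.sequence_id) == sorted(
        permuted, key=lambda f: f.sequence_id
    )


def test_flags_never_cross_samples(params):
    rng = random.Random(7)
    parent = _rand_seq(rng, 80)
    daughter = parent[:20] + ("A" if parent[20] != "A" else "C") + parent[21:]
    t1 = pn.AbundanceTable(
        {parent: {"S1": 500, "S2": 50}, daughter: {"S1": 5, "S2": 40}},
        samples=["S1", "S2"],
    )
    t2 = pn.AbundanceTable(
        {parent: {"S1": 500, "S2": 999}, daughter: {"S1": 5, "S2": 1}},
        samples=["S1", "S2"],
    )
    f1 = [f for f in pn.secondary_validate(t1, params) if f.sample == "S1"]
    f2 = [f for f in pn.secondary_validate(t2, params) if f.sample == "S1"]
    key = lambda f: (f.sequence_id, f.status, f.firing_test)
    assert sorted(map(key, f1)) == sorted(map(key, f2))
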