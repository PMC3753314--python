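"""Secondary validation: per-sample error-type tests.

Groups are ignored here.  Within each sample, sequences are ranked by read
abundance (ties broken lexicographically).  Sequences with a single read in
the sample are 'ambiguous' - neither valid nor invalid there.  Every other
sequence is tested against the sequences ranked above it:

indel test
    If a pair differs only by indels, the lower-ranked member is a
    potential pyrosequencing error and is flagged invalid in the sample.

substitution test
    If a pair differs only by base substitutions, the lower-ranked member
    is flagged invalid when it has fewer than a*x**n reads, where a is the
    more abundant member's reads in the sample, n the number of mismatches
    and x the substitution proportion (default 0.02).

chimera test
    For each daughter and each pair of sequences ranked above it, the
    daughter is aligned against the two parents.  If it mismatches both
    parents anywhere the chimera probability is zero; otherwise the number
    s of switches between matching one parent and the other is counted and
    the daughter is flagged invalid when it has fewer than b*y**s reads,
    where b is the less abundant parent's reads and y the chimera
    proportion (default 0.15).

All thresholds use strict 'fewer than' comparisons and are never rounded.
Flags are strictly per-sample; a sequence flagged here may still be
validated in other samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

from .align import align_triple, chimera_scan, classify_pair
from .ingest import AbundanceTable
from .preliminary import ErrorParams

VALID = "valid"
INVALID = "invalid"
AMBIGUOUS = "ambiguous"

INDEL = "indel"
SUBSTITUTION = "substitution"
CHIMERA = "chimera"


@dataclass(frozen=True)
class SampleFlag:
    sequence_id: str
    sample: str
    status: str  # valid | invalid | ambiguous
    firing_test: Optional[str] = None  # indel | substitution | chimera
    parents: tuple[str, ...] = ()
    threshold: Optional[float] = None
    observed: Optional[int] = None


def substitution_threshold(a: int, n: int, x: float) -> float:
    """Read-count threshold a*x**n below which a substitution variant is invalid."""
    if a < 1:
        raise ValueError("parent read count a must be >= 1")
    if n < 1:
        raise ValueError("mismatch count n must be >= 1 (identical sequences cannot "
                         "coexist as distinct rows)")
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    return a * x ** n


def chimera_threshold(b: int, s: int, y: float) -> float:
    """Read-count threshold b*y**s below which a chimera candidate is invalid."""
    if b < 1:
        raise ValueError("parent read count b must be >= 1")
    if s < 1:
        raise ValueError("a daughter with no switches is not a chimera candidate")
    if not 0 < y <= 1:
        raise ValueError("y must be in (0, 1]")
    return b * y ** s


def validate_sample(
    sample: str,
    counts: Mapping[str, int],
    sequences: Mapping[str, str],
    params: ErrorParams,
    max_parent_pairs: Optional[int] = None,
) -> list[SampleFlag]:
    """Flag every sequence present in one sample as valid/invalid/ambiguous.

    ``counts`` maps sequence id -> reads in this sample (only ids with >= 1
    read); ``sequences`` maps id -> nucleotide string.  ``max_parent_pairs``
    caps the number of parent pairs tried per daughter in the chimera scan
    (None = all pairs ranked above the daughter).
    """
    present = [i for i in counts if counts[i] > 0]
    ranked = sorted(present, key=lambda i: (-counts[i], sequences[i]))
    flags: dict[str, SampleFlag] = {}

    eligible = [i for i in ranked if counts[i] >= 2]
    for i in ranked:
        if counts[i] == 1:
            flags[i] = SampleFlag(i, sample, AMBIGUOUS, observed=1)

    # pair tests: indel, then substitution, against every higher-ranked sequence
    for j_idx, j in enumerate(eligible):
        for i in eligible[:j_idx]:
            diff = classify_pair(sequences[i], sequences[j])
            if diff.identical:
                raise ValueError(f"duplicate sequences in sample {sample}: {i}, {j}")
            if diff.indel_only:
                flags[j] = SampleFlag(j, sample, INVALID, INDEL, (i,), None, counts[j])
                break
            if diff.subs_only:
                cutoff = substitution_threshold(counts[i], diff.n_sub, params.sub_x)
                if counts[j] < cutoff:
                    flags[j] = SampleFlag(
                        j, sample, INVALID, SUBSTITUTION, (i,), cutoff, counts[j]
                    )
                    break

    # chimera test over parent pairs ranked above each remaining daughter
    for k_idx, d in enumerate(eligible):
        if d in flags or k_idx < 2:
            continue
        pairs = sorted(
            combinations(range(k_idx), 2),
            key=lambda ij: (-(counts[eligible[ij[0]]] + counts[eligible[ij[1]]]), ij),
        )
        if max_parent_pairs is not None:
            pairs = pairs[:max_parent_pairs]
        for ia, ib in pairs:
            p1, p2 = eligible[ia], eligible[ib]
            b = counts[p2]  # less abundant parent (ranked lower)
            if counts[d] >= b * params.chi_y:
                continue  # cannot fall below b*y**s for any s >= 1
            s = chimera_scan(align_triple(sequences[p1], sequences[p2], sequences[d]))
            if s is None or s < 1:
                continue
            cutoff = chimera_threshold(b, s, params.chi_y)
            if counts[d] < cutoff:
                flags[d] = SampleFlag(d, sample, INVALID, CHIMERA, (p1, p2), cutoff, counts[d])
                break

    out = []
    for i in ranked:
        if i in flags:
            out.append(flags[i])
        else:
            out.append(SampleFlag(i, sample, VALID, observed=counts[i]))
    return out


def secondary_validate(
    table: AbundanceTable,
    params: ErrorParams,
    max_parent_pairs: Optional[int] = None,
) -> list[SampleFlag]:
    """Run the per-sample tests over every sample of a filtered table."""
    sequences = {i: table.sequence(i) for i in table.ids_by_rank}
    flags: list[SampleFlag] = []
    for sample in table.samples:
        counts = {
            i: table.sample_count(i, sample)
            for i in table.ids_by_rank
            if table.sample_count(i, sample) > 0
        }
        if counts:
            flags.extend(
                validate_sample(sample, counts, sequences, params, max_parent_pairs)
            )
    return flags
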