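"""Deterministic nucleotide alignment primitives.

All error-type tests in secondary validation are defined on alignments:
pairwise alignments classify a pair of sequences as differing by
substitutions only or by indels only, and three-way (parent/parent/daughter)
alignments drive the chimera breakpoint scan.  Reproducibility of every
validation decision therefore requires a bit-reproducible aligner; this
module provides one built on Bio.Align.PairwiseAligner (global mode,
match +1 / mismatch -1 / linear gap -1) plus an internal Needleman-Wunsch
that aligns a daughter sequence against the two-parent profile.

Terminal-gap columns (columns inside the leading or trailing gap run of any
sequence in the alignment) are excluded from substitution counts and from
pairwise distances throughout, so prematurely terminated reads are compared
only over the region they actually cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from numba import njit

GAP = "-"

_ENCODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5, GAP: 0}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=262144)
def global_align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the gapped strings.

    The first optimal alignment reported by PairwiseAligner is used, which
    is deterministic for a fixed library version.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def terminal_mask(rows: tuple[str, ...] | list[str]) -> list[bool]:
    """True for columns inside any sequence's leading/trailing gap run."""
    n = len(rows[0])
    mask = [False] * n
    for row in rows:
        i = 0
        while i < n and row[i] == GAP:
            mask[i] = True
            i += 1
        j = n - 1
        while j >= 0 and row[j] == GAP:
            mask[j] = True
            j -= 1
    return mask


@dataclass(frozen=True)
class PairDiff:
    """Column-level difference summary of a pairwise alignment.

    ``n_sub`` and ``n_indel`` count internal (non-terminal) substitution and
    gap columns; ``n_terminal`` counts terminal-gap columns, i.e. length
    differences at the ends; ``n_columns`` is the number of internal columns.
    """

    n_sub: int
    n_indel: int
    n_terminal: int
    n_columns: int

    @property
    def identical(self) -> bool:
        return self.n_sub == 0 and self.n_indel == 0 and self.n_terminal == 0

    @property
    def indel_only(self) -> bool:
        """Differs by indels only (terminal truncation counts as an indel)."""
        return self.n_sub == 0 and (self.n_indel + self.n_terminal) > 0

    @property
    def subs_only(self) -> bool:
        return self.n_sub > 0 and self.n_indel == 0 and self.n_terminal == 0

    @property
    def distance(self) -> float:
        """Edits per internal alignment column; 1.0 when nothing aligns."""
        if self.n_columns == 0:
            return 1.0
        return (self.n_sub + self.n_indel) / self.n_columns


@lru_cache(maxsize=262144)
def classify_pair(a: str, b: str) -> PairDiff:
    sa, sb = global_align(a, b)
    term = terminal_mask((sa, sb))
    n_sub = n_indel = n_term = n_cols = 0
    for ca, cb, t in zip(sa, sb, term):
        if t:
            n_term += 1
            continue
        n_cols += 1
        if ca == GAP or cb == GAP:
            n_indel += 1
        elif ca != cb:
            n_sub += 1
    return PairDiff(n_sub, n_indel, n_term, n_cols)


def pair_distance(a: str, b: str) -> float:
    """Pairwise distance: edits / alignment columns, terminal gaps excluded."""
    return classify_pair(a, b).distance


# --- daughter-vs-profile dynamic programme -------------------------------

@njit(cache=False)
def _profile_dp(prof1, prof2, d):  # pragma: no cover - exercised via align_triple
    p = prof1.shape[0]
    n = d.shape[0]
    cost = np.empty((p + 1, n + 1), np.int32)
    ptr = np.empty((p + 1, n + 1), np.int8)
    cost[0, 0] = 0
    ptr[0, 0] = -1
    for j in range(1, n + 1):
        cost[0, j] = j
        ptr[0, j] = 2
    for i in range(1, p + 1):
        cost[i, 0] = i
        ptr[i, 0] = 1
    for i in range(1, p + 1):
        c1 = prof1[i - 1]
        c2 = prof2[i - 1]
        for j in range(1, n + 1):
            dc = d[j - 1]
            m = 0 if (dc == c1 or dc == c2) else 1
            best = cost[i - 1, j - 1] + m
            move = 0
            up = cost[i - 1, j] + 1
            if up < best:
                best = up
                move = 1
            left = cost[i, j - 1] + 1
            if left < best:
                best = left
                move = 2
            cost[i, j] = best
            ptr[i, j] = move
    return ptr


def _encode(s: str) -> np.ndarray:
    return np.array([_ENCODE.get(c, 6) for c in s], dtype=np.int8)


MATCH_ALL = "match_all"
D_MATCHES_P1 = "d_matches_p1_only"
D_MATCHES_P2 = "d_matches_p2_only"
D_MATCHES_NEITHER = "d_matches_neither"


@dataclass(frozen=True)
class TripleAlignment:
    """Three-way alignment of two parents and a daughter.

    ``aligned_p1``/``aligned_p2``/``aligned_d`` are equal-length gapped
    strings; ungapping each recovers the corresponding input exactly.
    """

    aligned_p1: str
    aligned_p2: str
    aligned_d: str

    def __post_init__(self):
        if not (len(self.aligned_p1) == len(self.aligned_p2) == len(self.aligned_d)):
            raise ValueError("triple alignment rows differ in length")

    @property
    def terminal(self) -> list[bool]:
        return terminal_mask((self.aligned_p1, self.aligned_p2, self.aligned_d))

    def columns(self):
        return zip(self.aligned_p1, self.aligned_p2, self.aligned_d)

    def column_classes(self) -> list[str]:
        """Per-column relation of the daughter to the two parents."""
        out = []
        for c1, c2, cd in self.columns():
            if cd == c1 and cd == c2:
                out.append(MATCH_ALL)
            elif cd == c1:
                out.append(D_MATCHES_P1)
            elif cd == c2:
                out.append(D_MATCHES_P2)
            else:
                out.append(D_MATCHES_NEITHER)
        return out

    def parent_diff(self) -> PairDiff:
        """Difference summary of the two parents within this alignment."""
        term = terminal_mask((self.aligned_p1, self.aligned_p2))
        n_sub = n_indel = n_term = n_cols = 0
        for (c1, c2, _), t in zip(self.columns(), term):
            if c1 == GAP and c2 == GAP:
                continue  # daughter insertion column
            if t:
                n_term += 1
                continue
            n_cols += 1
            if c1 == GAP or c2 == GAP:
                n_indel += 1
            elif c1 != c2:
                n_sub += 1
        return PairDiff(n_sub, n_indel, n_term, n_cols)


@lru_cache(maxsize=65536)
def align_triple(p1: str, p2: str, d: str) -> TripleAlignment:
    """Align parents pairwise, then the daughter against their profile.

    Each column of the daughter alignment costs 0 when the daughter base
    matches either parent's base in that column, 1 otherwise; gaps cost 1.
    Ties are broken diagonal > gap-in-daughter > insertion, which makes the
    result deterministic.
    """
    if not (p1 and p2 and d):
        raise ValueError("cannot align empty sequences")
    sa1, sa2 = global_align(p1, p2)
    ptr = _profile_dp(_encode(sa1), _encode(sa2), _encode(d))
    i, j = len(sa1), len(d)
    r1, r2, rd = [], [], []
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            r1.append(sa1[i - 1])
            r2.append(sa2[i - 1])
            rd.append(d[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            r1.append(sa1[i - 1])
            r2.append(sa2[i - 1])
            rd.append(GAP)
            i -= 1
        else:
            r1.append(GAP)
            r2.append(GAP)
            rd.append(d[j - 1])
            j -= 1
    return TripleAlignment("".join(reversed(r1)), "".join(reversed(r2)), "".join(reversed(rd)))


def chimera_scan(tri: TripleAlignment) -> int | None:
    """Count parent switches of the daughter along the alignment.

    Scans left to right over non-terminal columns.  Returns ``None`` when
    the daughter mismatches both parents at any point (not a chimera
    candidate); otherwise the number of transitions between runs of
    p1-matching and p2-matching informative columns.  Columns matching both
    parents are uninformative and skipped.  A daughter gap aligned to
    exactly one parent's gap is informative for that parent.
    """
    labels = []
    for (c1, c2, cd), t in zip(tri.columns(), tri.terminal):
        if t:
            continue
        if cd == c1 and cd == c2:
            continue
        if cd == c1:
            labels.append(1)
        elif cd == c2:
            labels.append(2)
        else:
            return None
    return sum(1 for k in range(1, len(labels)) if labels[k] != labels[k - 1])
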