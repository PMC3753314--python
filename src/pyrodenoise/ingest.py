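"""Read filtering, demultiplexing and abundance-table construction.

The first pipeline stage accepts raw FASTA reads only when they contain an
exact match to the user-defined forward MID+primer at the 5' end and to the
reverse-complemented reverse primer (followed by the reverse MID) near the
3' end.  No quality scores and no fuzzy matching are used: a read either
carries the expected flanking structure byte-for-byte or it is rejected
with a reason code.  Accepted reads are trimmed of primers and MIDs, binned
by identical trimmed sequence and assigned to their sample of origin via
the MID pair.  The resulting unique-sequence x sample count table is then
pre-filtered: sequences containing ambiguous bases (N), sequences still
containing a primer, and global singletons (one read in the whole dataset)
are removed.  Local singletons - one read in a sample but several in the
dataset - are retained.

For amplicons too long for the read to reach the reverse primer, a
truncation mode (``truncate_at``) skips the reverse primer/MID search and
cuts the read at a fixed length after forward trimming; samples must then
be resolvable from the forward MID alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# rejection reason codes (read level)
NO_FORWARD_PRIMER = "no_forward_primer"
NO_REVERSE_PRIMER = "no_reverse_primer"
UNKNOWN_MID = "unknown_mid"
TOO_SHORT = "too_short"

# rejection reason codes (sequence level, prefilter)
AMBIGUOUS_BASE = "ambiguous_base"
MULTIPLE_PRIMER = "multiple_primer"
GLOBAL_SINGLETON = "global_singleton"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


class ConfigError(ValueError):
    """Raised for invalid primer/MID/design configuration."""


@dataclass(frozen=True)
class RawRead:
    read_id: str
    bases: str


@dataclass(frozen=True)
class Accepted:
    read_id: str
    sample: str
    sequence: str


@dataclass(frozen=True)
class Rejected:
    read_id: str
    reason: str


@dataclass(frozen=True)
class PrimerSpec:
    """Forward/reverse primers plus the MID-pair -> sample map.

    ``mid_map`` keys are (forward MID, reverse MID) pairs as they appear in
    the amplicon construct: forward MID at the very 5' end, reverse MID
    reverse-complemented after the reverse-complemented reverse primer.
    Empty MID strings are allowed for unmultiplexed data.
    """

    forward_primer: str
    reverse_primer: str
    mid_map: Mapping[tuple[str, str], str]
    min_length: int = 0
    truncate_at: Optional[int] = None

    def __post_init__(self):
        if not self.forward_primer or not self.reverse_primer:
            raise ConfigError("primers must be non-empty")
        if self.min_length < 0:
            raise ConfigError("min_length must be non-negative")
        if self.truncate_at is not None and self.truncate_at <= 0:
            raise ConfigError("truncate_at must be positive")
        if not self.mid_map:
            raise ConfigError("mid_map must contain at least one MID pair")
        if self.truncate_at is not None:
            seen: dict[str, str] = {}
            for (fmid, _), sample in self.mid_map.items():
                if fmid in seen and seen[fmid] != sample:
                    raise ConfigError(
                        "truncation mode needs the forward MID alone to resolve "
                        f"the sample, but {fmid!r} is shared by several samples"
                    )
                seen[fmid] = sample

    @property
    def _forward_mids(self) -> tuple[str, ...]:
        # longest first so a MID that is a prefix of another cannot shadow it
        return tuple(sorted({f for f, _ in self.mid_map}, key=lambda m: (-len(m), m)))

    @property
    def _reverse_primer_rc(self) -> str:
        return revcomp(self.reverse_primer)

    def sample_for_forward_mid(self, fmid: str) -> str:
        for (f, _), sample in self.mid_map.items():
            if f == fmid:
                return sample
        raise KeyError(fmid)


def accept_and_trim(read: RawRead, spec: PrimerSpec) -> Accepted | Rejected:
    """Demultiplex and trim a single read, or reject it with a reason."""
    seq = read.bases
    fmid = None
    for candidate in spec._forward_mids:
        if seq.startswith(candidate + spec.forward_primer):
            fmid = candidate
            break
    if fmid is None:
        return Rejected(read.read_id, NO_FORWARD_PRIMER)
    rest = seq[len(fmid) + len(spec.forward_primer):]

    if spec.truncate_at is not None:
        trimmed = rest[: spec.truncate_at]
        sample = spec.sample_for_forward_mid(fmid)
    else:
        pos = rest.rfind(spec._reverse_primer_rc)
        if pos < 0:
            return Rejected(read.read_id, NO_REVERSE_PRIMER)
        trimmed = rest[:pos]
        tail = rest[pos + len(spec._reverse_primer_rc):]
        rmid = revcomp(tail)
        if (fmid, rmid) not in spec.mid_map:
            return Rejected(read.read_id, UNKNOWN_MID)
        sample = spec.mid_map[(fmid, rmid)]

    if not trimmed or len(trimmed) < spec.min_length:
        return Rejected(read.read_id, TOO_SHORT)
    return Accepted(read.read_id, sample, trimmed)


def demultiplex(
    reads: Iterable[RawRead], spec: PrimerSpec
) -> tuple[list[Accepted], list[Rejected]]:
    accepted: list[Accepted] = []
    rejected: list[Rejected] = []
    for read in reads:
        result = accept_and_trim(read, spec)
        if isinstance(result, Accepted):
            accepted.append(result)
        else:
            rejected.append(result)
    return accepted, rejected


class AbundanceTable:
    """Unique trimmed sequences x samples read-count matrix.

    Rows are keyed by stable sequence ids assigned in rank order (descending
    dataset reads, ties broken lexicographically by sequence), so the most
    abundant sequence is ``U000001``.  Subsetting (e.g. by the pre-filter)
    preserves ids.
    """

    def __init__(
        self,
        counts_by_sequence: Mapping[str, Mapping[str, int]],
        samples: Optional[Iterable[str]] = None,
        _ids: Optional[Mapping[str, str]] = None,
    ):
        if samples is None:
            seen: list[str] = []
            for per_sample in counts_by_sequence.values():
                for s in per_sample:
                    if s not in seen:
                        seen.append(s)
            samples = seen
        self.samples: tuple[str, ...] = tuple(samples)
        totals = {seq: sum(c.values()) for seq, c in counts_by_sequence.items()}
        for seq, total in totals.items():
            if any(c < 0 for c in counts_by_sequence[seq].values()):
                raise ValueError("negative read count")
            if total == 0:
                raise ValueError(f"sequence with zero reads: {seq[:30]}...")
        order = sorted(counts_by_sequence, key=lambda s: (-totals[s], s))
        if _ids is None:
            _ids = {seq: f"U{i + 1:06d}" for i, seq in enumerate(order)}
        self._order = order
        self.seq_to_id = {seq: _ids[seq] for seq in order}
        self.id_to_seq = {i: s for s, i in self.seq_to_id.items()}
        self._counts = {
            self.seq_to_id[seq]: {s: int(c) for s, c in counts_by_sequence[seq].items() if c}
            for seq in order
        }
        self._totals = {self.seq_to_id[seq]: totals[seq] for seq in order}

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._counts

    @property
    def ids_by_rank(self) -> list[str]:
        return [self.seq_to_id[s] for s in self._order]

    def sequence(self, seq_id: str) -> str:
        return self.id_to_seq[seq_id]

    def total(self, seq_id: str) -> int:
        return self._totals[seq_id]

    def sample_count(self, seq_id: str, sample: str) -> int:
        return self._counts[seq_id].get(sample, 0)

    def sample_counts(self, seq_id: str) -> dict[str, int]:
        return dict(self._counts[seq_id])

    def samples_present(self, seq_id: str) -> list[str]:
        return [s for s in self.samples if self._counts[seq_id].get(s, 0) > 0]

    def subset(self, keep_ids: Iterable[str]) -> "AbundanceTable":
        keep = set(keep_ids)
        counts = {
            self.id_to_seq[i]: dict(self._counts[i]) for i in self._counts if i in keep
        }
        ids = {self.id_to_seq[i]: i for i in self._counts if i in keep}
        return AbundanceTable(counts, samples=self.samples, _ids=ids)

    # -- i/o ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seq_id in self.ids_by_rank:
            row = {
                "sequence_id": seq_id,
                "sequence": self.id_to_seq[seq_id],
                "total_reads": self._totals[seq_id],
            }
            for s in self.samples:
                row[s] = self._counts[seq_id].get(s, 0)
            rows.append(row)
        columns = ["sequence_id", "sequence", "total_reads", *self.samples]
        return pd.DataFrame(rows, columns=columns)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        frame = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        samples = [c for c in frame.columns if c not in ("sequence_id", "sequence", "total_reads")]
        counts = {}
        ids = {}
        for _, row in frame.iterrows():
            counts[row["sequence"]] = {s: int(row[s]) for s in samples if row[s]}
            ids[row["sequence"]] = row["sequence_id"]
        return cls(counts, samples=samples, _ids=ids)


def build_abundance_table(
    accepted: Iterable[Accepted], samples: Optional[Iterable[str]] = None
) -> AbundanceTable:
    counts: dict[str, dict[str, int]] = {}
    seen_samples: list[str] = []
    for rec in accepted:
        per_sample = counts.setdefault(rec.sequence, {})
        per_sample[rec.sample] = per_sample.get(rec.sample, 0) + 1
        if rec.sample not in seen_samples:
            seen_samples.append(rec.sample)
    if samples is None:
        samples = sorted(seen_samples)
    return AbundanceTable(counts, samples=samples)


def prefilter(
    table: AbundanceTable, spec: PrimerSpec
) -> tuple[AbundanceTable, list[tuple[str, str]]]:
    """Drop N-containing, primer-containing and globally-singleton rows.

    Returns the filtered table and a (sequence_id, reason) rejection log.
    A row failing several filters is logged once, with reasons checked in
    the order ambiguous base, residual primer, global singleton.
    """
    rev_rc = revcomp(spec.reverse_primer)
    keep: list[str] = []
    log: list[tuple[str, str]] = []
    for seq_id in table.ids_by_rank:
        seq = table.sequence(seq_id)
        if "N" in seq:
            log.append((seq_id, AMBIGUOUS_BASE))
        elif spec.forward_primer in seq or rev_rc in seq:
            log.append((seq_id, MULTIPLE_PRIMER))
        elif table.total(seq_id) < 2:
            log.append((seq_id, GLOBAL_SINGLETON))
        else:
            keep.append(seq_id)
    return table.subset(keep), log


# --- file readers ---------------------------------------------------------

def read_fasta(path: str | Path) -> list[RawRead]:
    """Load raw reads; uppercases, maps U->T, checks ids unique and non-empty."""
    reads: list[RawRead] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        bases = str(record.seq).upper().replace("U", "T")
        if not bases:
            raise ParseError(f"record {record.id!r} has an empty sequence")
        if record.id in seen:
            raise ParseError(f"duplicate read id {record.id!r}")
        seen.add(record.id)
        reads.append(RawRead(record.id, bases))
    return reads


def read_mid_map(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a sample/forward_mid/reverse_mid TSV into a mid_map."""
    mid_map: dict[tuple[str, str], str] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample", "forward_mid", "reverse_mid"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConfigError(f"MID map must have columns {sorted(required)}")
        for row in reader:
            key = (row["forward_mid"].strip().upper(), row["reverse_mid"].strip().upper())
            if key in mid_map:
                raise ConfigError(f"duplicate MID pair {key}")
            mid_map[key] = row["sample"].strip()
    if not mid_map:
        raise ConfigError("empty MID map")
    return mid_map


def write_mid_map(mid_map: Mapping[tuple[str, str], str], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["sample", "forward_mid", "reverse_mid"])
        for (fmid, rmid), sample in mid_map.items():
            writer.writerow([sample, fmid, rmid])


def write_rejected_reads(rejected: Iterable[Rejected], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["read_id", "reason"])
        for rec in rejected:
            writer.writerow([rec.read_id, rec.reason])
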