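"""Assignment of filtered unique sequences to groups.

Two modes are supported.  Best-hit mode partitions sequences by the
accession of their best database hit, supplied as an externally produced
TSV (any search tool can generate it; hit scores are stored but never used,
and no-hit sequences are dropped as non-target).  Precluster mode is
self-contained: greedy abundance-sorted single-linkage preclustering at a
fixed radius (default 2% pairwise distance, terminal gaps excluded), in
which each sequence joins the first group whose seed lies within the
radius, or founds a new group.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .align import pair_distance
from .ingest import AbundanceTable, ConfigError

NO_HIT = "NA"


@dataclass(frozen=True)
class SequenceGroup:
    group_id: str
    members: tuple[str, ...]  # sequence ids, descending dataset reads

    @property
    def seed(self) -> str:
        return self.members[0]


def group_by_besthit(
    table: AbundanceTable, hits: Mapping[str, Optional[str]]
) -> tuple[list[SequenceGroup], set[str]]:
    """Partition by best-hit accession; no-hit sequences are dropped.

    ``hits`` must cover every sequence id in the table, with ``None`` (or
    the ``"NA"`` token from :func:`read_hits_tsv`) marking no-hit entries.
    """
    missing = [i for i in table.ids_by_rank if i not in hits]
    if missing:
        raise ConfigError(f"hit table missing {len(missing)} sequence ids, e.g. {missing[0]}")
    by_accession: dict[str, list[str]] = {}
    dropped: set[str] = set()
    for seq_id in table.ids_by_rank:  # rank order => members come out ranked
        accession = hits[seq_id]
        if accession is None or accession == NO_HIT:
            dropped.add(seq_id)
        else:
            by_accession.setdefault(accession, []).append(seq_id)
    groups = [SequenceGroup(acc, tuple(members)) for acc, members in by_accession.items()]
    groups.sort(key=lambda g: g.group_id)
    return groups, dropped


def group_by_preclustering(
    table: AbundanceTable, radius: float = 0.02, full_linkage: bool = False
) -> list[SequenceGroup]:
    """Greedy abundance-ordered single-linkage preclustering.

    Sequences are processed in descending dataset-read order (ties broken
    lexicographically by sequence, as everywhere in the package).  By
    default a sequence joins the first group whose *seed* is within
    ``radius``; with ``full_linkage`` it joins the first group with *any*
    member within the radius (transitive single linkage).  No sequence is
    dropped.
    """
    if not 0 < radius < 0.5:
        raise ValueError("radius must be in (0, 0.5)")
    groups: list[list[str]] = []
    for seq_id in table.ids_by_rank:
        seq = table.sequence(seq_id)
        placed = False
        for members in groups:
            candidates = members if full_linkage else members[:1]
            if any(pair_distance(seq, table.sequence(m)) <= radius for m in candidates):
                members.append(seq_id)
                placed = True
                break
        if not placed:
            groups.append([seq_id])
    return [
        SequenceGroup(f"PC{i + 1:05d}", tuple(members)) for i, members in enumerate(groups)
    ]


def read_hits_tsv(path: str | Path) -> dict[str, Optional[str]]:
    """TSV columns sequence_id, accession[, bitscore]; accession NA = no hit."""
    hits: dict[str, Optional[str]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "sequence_id" not in reader.fieldnames \
                or "accession" not in reader.fieldnames:
            raise ConfigError("hit table must have columns sequence_id, accession")
        for row in reader:
            accession = row["accession"].strip()
            hits[row["sequence_id"].strip()] = None if accession == NO_HIT else accession
    return hits


def write_groups_tsv(groups: Iterable[SequenceGroup], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["group_id", "sequence_id", "rank_in_group"])
        for group in groups:
            for rank, seq_id in enumerate(group.members, start=1):
                writer.writerow([group.group_id, seq_id, rank])
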