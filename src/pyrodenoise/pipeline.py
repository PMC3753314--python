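"""Final validation and end-to-end pipeline orchestration.

After every sample has been processed, valid and invalid observations are
collated per sequence.  A sequence is retained when it was provisionally
accepted in preliminary validation AND its per-sample valid observations
satisfy the replication design: either at least ``min_valid_obs`` valid
observations overall (default 1), or - when the samples are partitioned
into replicate blocks - a valid observation in every sample of at least one
block.  Ambiguous observations (single reads in a sample) never count as
valid; invalid observations are not vetoes.

The replication design also fixes the theoretical detection floor: a valid
observation needs at least two reads in its sample, so the minimum dataset
reads is twice the number of samples that must simultaneously hold valid
observations, but never below the preliminary-validation rare-sequence
floor (3 reads multi-sample, 2 single-sample).

Rejected sequences are never silently discarded: every export includes the
rejected set with the rule or test that removed each sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import grouping as grouping_mod
from . import ingest as ingest_mod
from .ingest import AbundanceTable, ConfigError, PrimerSpec, RawRead
from .preliminary import ErrorParams, PrelimStatus, preliminary_validate, provisional_set
from .secondary import AMBIGUOUS, INVALID, VALID, SampleFlag, secondary_validate


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class ReplicationDesign:
    """How valid observations across samples convert into a final decision.

    mode
        "MS" (multi-sample rules) or "SS" (single-sample relaxation).
    min_valid_obs
        Number of valid per-sample observations required (k-of-all rule).
    blocks
        Optional partition of samples into replicate blocks; when given, a
        sequence must be valid in every sample of at least one block (e.g.
        all three sequencing replicates from at least one center) and
        ``min_valid_obs`` is ignored.
    """

    mode: str = "MS"
    min_valid_obs: int = 1
    blocks: Optional[tuple[tuple[str, ...], ...]] = None

    def __post_init__(self):
        if self.mode.upper() not in ("MS", "SS"):
            raise ConfigError(f"mode must be MS or SS, got {self.mode!r}")
        object.__setattr__(self, "mode", self.mode.upper())
        if self.min_valid_obs < 1:
            raise ConfigError("min_valid_obs must be >= 1")
        if self.blocks is not None:
            blocks = tuple(tuple(b) for b in self.blocks)
            if not blocks or any(not b for b in blocks):
                raise ConfigError("blocks must be non-empty")
            flat = [s for b in blocks for s in b]
            if len(flat) != len(set(flat)):
                raise ConfigError("blocks must not share samples")
            object.__setattr__(self, "blocks", blocks)

    def required_simultaneous_samples(self) -> int:
        """Samples that must hold valid observations at the same time."""
        if self.blocks is not None:
            return min(len(b) for b in self.blocks)
        return self.min_valid_obs


def detection_floor(
    design: ReplicationDesign, params: Optional[ErrorParams] = None
) -> tuple[int, int]:
    """Theoretical minimum (dataset reads, per-sample reads) for validation.

    A valid per-sample observation requires >= 2 reads, so the dataset floor
    is 2 x the number of simultaneously valid samples the design demands,
    clamped from below by the preliminary-validation rare-sequence floor.
    """
    if params is None:
        params = ErrorParams()
    min_sample = 2
    required = design.required_simultaneous_samples()
    rare_floor = params.rare_min_reads_ms if design.mode == "MS" else params.rare_min_reads_ss
    return max(min_sample * required, rare_floor), min_sample


@dataclass(frozen=True)
class SequenceDecision:
    retained: bool
    n_valid: int
    n_invalid: int
    n_ambiguous: int
    reason: str


@dataclass
class ValidationLedger:
    """Per-(sequence, sample) statuses plus per-sequence final decisions."""

    status: dict[tuple[str, str], str]
    decisions: dict[str, SequenceDecision]

    @property
    def retained(self) -> list[str]:
        return [i for i, d in self.decisions.items() if d.retained]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_id": i,
                "retained": d.retained,
                "n_valid": d.n_valid,
                "n_invalid": d.n_invalid,
                "n_ambiguous": d.n_ambiguous,
                "reason": d.reason,
            }
            for i, d in self.decisions.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["sequence_id", "retained", "n_valid", "n_invalid", "n_ambiguous", "reason"],
        )


def finalize(
    flags: Iterable[SampleFlag],
    prelim: Iterable[str],
    design: ReplicationDesign,
    samples: Sequence[str],
) -> ValidationLedger:
    """Collate per-sample flags into final retain/reject decisions."""
    if design.blocks is not None:
        unknown = {s for b in design.blocks for s in b} - set(samples)
        if unknown:
            raise ConfigError(f"design references unknown samples: {sorted(unknown)}")
    prelim = set(prelim)
    status: dict[tuple[str, str], str] = {}
    by_seq: dict[str, list[SampleFlag]] = {}
    for flag in flags:
        status[(flag.sequence_id, flag.sample)] = flag.status
        by_seq.setdefault(flag.sequence_id, []).append(flag)

    decisions: dict[str, SequenceDecision] = {}
    for seq_id in sorted(set(by_seq) | prelim):
        seq_flags = by_seq.get(seq_id, [])
        n_valid = sum(f.status == VALID for f in seq_flags)
        n_invalid = sum(f.status == INVALID for f in seq_flags)
        n_ambiguous = sum(f.status == AMBIGUOUS for f in seq_flags)
        if seq_id not in prelim:
            retained, reason = False, "not_provisional"
        elif design.blocks is not None:
            valid_samples = {f.sample for f in seq_flags if f.status == VALID}
            retained = any(all(s in valid_samples for s in block) for block in design.blocks)
            reason = "retained" if retained else "no_complete_block"
        else:
            retained = n_valid >= design.min_valid_obs
            reason = "retained" if retained else "insufficient_valid_observations"
        decisions[seq_id] = SequenceDecision(retained, n_valid, n_invalid, n_ambiguous, reason)
    return ValidationLedger(status, decisions)


@dataclass
class StageCounts:
    raw_reads: int = 0
    accepted_reads: int = 0
    unique_sequences: int = 0
    filtered_sequences: int = 0
    preliminary_valid: int = 0
    final_valid: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class PipelineResult:
    table: AbundanceTable            # all unique sequences
    filtered: AbundanceTable         # after the pre-filters
    rejected_reads: list
    filter_log: list[tuple[str, str]]
    groups: list
    dropped: set[str]
    prelim: dict[str, PrelimStatus]
    flags: list[SampleFlag]
    ledger: ValidationLedger
    counts: StageCounts

    @property
    def validated_ids(self) -> list[str]:
        retained = set(self.ledger.retained)
        return [i for i in self.filtered.ids_by_rank if i in retained]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    reads: Iterable[RawRead] | str | Path,
    spec: PrimerSpec,
    params: Optional[ErrorParams] = None,
    design: Optional[ReplicationDesign] = None,
    grouping: str = "precluster",
    hits: Optional[Mapping[str, Optional[str]]] = None,
    radius: float = 0.02,
    full_linkage: bool = False,
    max_parent_pairs: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Execute filtering, grouping, preliminary, secondary and final validation.

    ``reads`` may be a FASTA path or an iterable of :class:`RawRead`.
    ``grouping`` is ``"precluster"`` (internal single-linkage) or
    ``"besthit"`` (requires ``hits``).  When ``out_dir`` is given, all
    tables, logs and FASTA exports are written there.
    """
    params = params or ErrorParams()
    design = design or ReplicationDesign()

    if isinstance(reads, (str, Path)):
        reads = _stage("read_fasta")(ingest_mod.read_fasta, reads)
    else:
        reads = list(reads)
    counts = StageCounts(raw_reads=len(reads))

    accepted, rejected = _stage("demultiplex")(ingest_mod.demultiplex, reads, spec)
    counts.accepted_reads = len(accepted)
    table = _stage("abundance_table")(ingest_mod.build_abundance_table, accepted)
    counts.unique_sequences = len(table)
    filtered, filter_log = _stage("prefilter")(ingest_mod.prefilter, table, spec)
    counts.filtered_sequences = len(filtered)

    dropped: set[str] = set()
    if grouping == "besthit":
        if hits is None:
            raise ConfigError("besthit grouping requires a hit table")
        groups, dropped = _stage("grouping")(grouping_mod.group_by_besthit, filtered, hits)
    elif grouping == "precluster":
        groups = _stage("grouping")(
            grouping_mod.group_by_preclustering, filtered, radius, full_linkage
        )
    else:
        raise ConfigError(f"unknown grouping mode {grouping!r}")

    prelim = _stage("preliminary_validation")(
        preliminary_validate, groups, filtered, params, design.mode
    )
    counts.preliminary_valid = len(provisional_set(prelim))

    flags = _stage("secondary_validation")(
        secondary_validate, filtered, params, max_parent_pairs
    )

    ledger = _stage("final_validation")(
        finalize, flags, provisional_set(prelim), design, filtered.samples
    )
    counts.final_valid = len(ledger.retained)

    result = PipelineResult(
        table, filtered, rejected, filter_log, groups, dropped, prelim, flags, ledger, counts
    )
    _assert_floor(result, design, params)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _assert_floor(result: PipelineResult, design: ReplicationDesign, params: ErrorParams):
    """Every retained sequence must sit on or above the detection floor."""
    min_dataset, min_sample = detection_floor(design, params)
    required = design.required_simultaneous_samples()
    for seq_id in result.validated_ids:
        total = result.filtered.total(seq_id)
        n_good = sum(
            1 for s in result.filtered.samples
            if result.filtered.sample_count(seq_id, s) >= min_sample
        )
        if total < min_dataset or n_good < required:
            raise PipelineError(
                f"internal error: retained sequence {seq_id} below the detection floor"
            )


# --- exports --------------------------------------------------------------

def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result.table.write_tsv(out / "unique_sequences.tsv")
    result.filtered.write_tsv(out / "abundance_table.tsv")
    ingest_mod.write_rejected_reads(result.rejected_reads, out / "rejected_reads.tsv")
    pd.DataFrame(result.filter_log, columns=["sequence_id", "reason"]).to_csv(
        out / "filtered_sequences.tsv", sep="\t", index=False
    )
    grouping_mod.write_groups_tsv(result.groups, out / "groups.tsv")

    pd.DataFrame(
        [
            {"sequence_id": i, "group_id": st.group_id, "status": st.status, "rule": st.rule}
            for i, st in result.prelim.items()
        ]
    ).to_csv(out / "preliminary_validation.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "sequence_id": f.sequence_id,
                "sample": f.sample,
                "status": f.status,
                "firing_test": f.firing_test or "",
                "parents": ",".join(f.parents),
                "threshold": "" if f.threshold is None else f.threshold,
                "observed": "" if f.observed is None else f.observed,
            }
            for f in result.flags
        ]
    ).to_csv(out / "sample_flags.tsv", sep="\t", index=False)

    result.ledger.to_frame().to_csv(out / "final_validation.tsv", sep="\t", index=False)
    result.counts.to_frame().to_csv(out / "stage_counts.tsv", sep="\t", index=False)

    write_validated_fasta(result, out / "validated.fasta")
    _write_rejected_fasta(result, out / "rejected_sequences.fasta")
    feature_table(result).to_csv(out / "feature_table.tsv", sep="\t")


def write_validated_fasta(result: PipelineResult, path: str | Path) -> None:
    """Validated sequences; headers carry dataset and per-sample read counts."""
    with open(path, "w") as handle:
        for seq_id in result.validated_ids:
            counts = result.filtered.sample_counts(seq_id)
            parts = [f"total={result.filtered.total(seq_id)}"]
            parts += [f"{s}={c}" for s, c in sorted(counts.items())]
            handle.write(f">{seq_id} {' '.join(parts)}\n{result.filtered.sequence(seq_id)}\n")


def _write_rejected_fasta(result: PipelineResult, path: str | Path) -> None:
    retained = set(result.validated_ids)
    with open(path, "w") as handle:
        for seq_id in result.filtered.ids_by_rank:
            if seq_id in retained:
                continue
            if seq_id in result.dropped:
                reason = "no_hit"
            elif seq_id in result.prelim and not result.prelim[seq_id].accepted:
                reason = result.prelim[seq_id].rule
            elif seq_id in result.ledger.decisions:
                reason = result.ledger.decisions[seq_id].reason
            else:
                reason = "not_evaluated"
            handle.write(f">{seq_id} reason={reason}\n{result.filtered.sequence(seq_id)}\n")


def feature_table(result: PipelineResult) -> pd.DataFrame:
    """Sample x validated-sequence count matrix for downstream OTU tools."""
    data = {
        seq_id: [result.filtered.sample_count(seq_id, s) for s in result.filtered.samples]
        for seq_id in result.validated_ids
    }
    return pd.DataFrame(data, index=list(result.filtered.samples))
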