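"""Preliminary validation from cross-sample abundance distributions.

Within each group the most abundant sequence is provisionally accepted
unless it is only ever a local singleton, or it is rare (fewer than
``rare_dataset_bound`` reads in the dataset) and confined to a single
sample.  Equivalently, a rare sequence must have at least three reads
(multi-sample mode), be present in more than one sample, and have multiple
reads in at least one sample.  Every additional group member is retained if
it occurs in samples where the top sequence is absent, or co-occurs with
the top sequence at a relative frequency of at least ``freq_cutoff`` (0.50
by default) in at least one sample - errors of the top sequence are
expected at much lower relative frequencies.

The single-sample variant (mode ``"SS"``) waives the multi-sample
requirement for rare sequences, so two reads suffice instead of three.

If a group's top-ranked sequence fails the top-sequence rules, the next
ranked member is promoted and re-evaluated, so one bad seed does not
annihilate the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .grouping import SequenceGroup
from .ingest import AbundanceTable

PROVISIONAL = "provisional"
REJECTED = "rejected"

# rule labels recorded in the provisional-validation log
LOCAL_SINGLETON_ONLY = "local_singleton_only"
RARE_SINGLE_SAMPLE = "rare_single_sample"
RARE_TOO_FEW_READS = "rare_too_few_reads"
TOP_ACCEPTED = "top_accepted"
DIFFERENT_SAMPLES = "different_samples"
COOCCUR_FREQUENCY = "cooccur_frequency"
BELOW_FREQUENCY_CUTOFF = "below_frequency_cutoff"


def _normalize_mode(mode: str) -> str:
    m = mode.upper()
    if m not in ("MS", "SS"):
        raise ValueError(f"mode must be 'MS' or 'SS', got {mode!r}")
    return m


@dataclass(frozen=True)
class ErrorParams:
    """Tunable constants of the error model.

    freq_cutoff
        Minimum relative frequency (vs the group's top sequence, per
        sample) at which a co-occurring sequence is considered independent
        rather than a probable error.
    rare_dataset_bound
        Dataset read count below which a sequence is "rare" and subject to
        the rare-sequence floors.
    rare_min_reads_ms / rare_min_reads_ss
        Minimum dataset reads for a rare sequence in multi-sample /
        single-sample mode.
    sub_x
        Base of the substitution threshold a*x**n.
    chi_y
        Base of the chimera threshold b*y**s.
    """

    freq_cutoff: float = 0.50
    rare_dataset_bound: int = 10
    rare_min_reads_ms: int = 3
    rare_min_reads_ss: int = 2
    sub_x: float = 0.02
    chi_y: float = 0.15

    def __post_init__(self):
        for name in ("freq_cutoff", "sub_x", "chi_y"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("rare_dataset_bound", "rare_min_reads_ms", "rare_min_reads_ss"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.rare_min_reads_ss > self.rare_min_reads_ms:
            raise ValueError("rare_min_reads_ss must not exceed rare_min_reads_ms")


@dataclass(frozen=True)
class PrelimStatus:
    status: str  # provisional | rejected
    rule: str
    group_id: str

    @property
    def accepted(self) -> bool:
        return self.status == PROVISIONAL


def _check_top_rules(
    seq_id: str, table: AbundanceTable, params: ErrorParams, mode: str
) -> tuple[bool, str]:
    counts = table.sample_counts(seq_id)
    total = table.total(seq_id)
    if max(counts.values()) <= 1:
        return False, LOCAL_SINGLETON_ONLY
    if total < params.rare_dataset_bound:
        if mode == "MS":
            if len(counts) == 1:
                return False, RARE_SINGLE_SAMPLE
            if total < params.rare_min_reads_ms:
                return False, RARE_TOO_FEW_READS
        else:
            if total < params.rare_min_reads_ss:
                return False, RARE_TOO_FEW_READS
    return True, TOP_ACCEPTED


def validate_top_sequence(
    group: SequenceGroup, table: AbundanceTable, params: ErrorParams, mode: str = "MS"
) -> tuple[bool, str]:
    """Provisional decision for the group's most abundant sequence."""
    if not group.members:
        raise ValueError("empty group")
    return _check_top_rules(group.members[0], table, params, _normalize_mode(mode))


def validate_additional_sequence(
    seq_id: str,
    top_id: str,
    table: AbundanceTable,
    params: ErrorParams,
    mode: str = "MS",
) -> tuple[bool, str]:
    """Provisional decision for a lower-ranked group member against the top.

    The rare-sequence floors apply to additional sequences exactly as to the
    top sequence, so every provisionally valid sequence satisfies the same
    minimum-read requirements.
    """
    mode = _normalize_mode(mode)
    ok, rule = _check_top_rules(seq_id, table, params, mode)
    if not ok:
        return False, rule
    counts = table.sample_counts(seq_id)
    top_counts = table.sample_counts(top_id)
    if any(top_counts.get(sample, 0) == 0 for sample in counts):
        return True, DIFFERENT_SAMPLES
    if any(
        counts[sample] >= params.freq_cutoff * top_counts[sample]
        for sample in counts
        if top_counts.get(sample, 0) > 0
    ):
        return True, COOCCUR_FREQUENCY
    return False, BELOW_FREQUENCY_CUTOFF


def validate_group(
    group: SequenceGroup, table: AbundanceTable, params: ErrorParams, mode: str = "MS"
) -> dict[str, PrelimStatus]:
    """Run preliminary validation over one group, with top promotion."""
    mode = _normalize_mode(mode)
    statuses: dict[str, PrelimStatus] = {}
    top_id: str | None = None
    for seq_id in group.members:
        if top_id is None:
            ok, rule = _check_top_rules(seq_id, table, params, mode)
            if ok:
                top_id = seq_id
        else:
            ok, rule = validate_additional_sequence(seq_id, top_id, table, params, mode)
        statuses[seq_id] = PrelimStatus(PROVISIONAL if ok else REJECTED, rule, group.group_id)
    return statuses


def preliminary_validate(
    groups: Iterable[SequenceGroup],
    table: AbundanceTable,
    params: ErrorParams,
    mode: str = "MS",
) -> dict[str, PrelimStatus]:
    statuses: dict[str, PrelimStatus] = {}
    for group in groups:
        statuses.update(validate_group(group, table, params, mode))
    return statuses


def provisional_set(statuses: Mapping[str, PrelimStatus]) -> set[str]:
    return {seq_id for seq_id, st in statuses.items() if st.accepted}
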