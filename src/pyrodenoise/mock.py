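"""Synthetic mock-community generator with ground truth.

Emulates a replicated positive-control experiment: a small assemblage of
clone sequences mixed at dilution-group ratios, amplified in independent
replicate PCRs, each replicate barcoded with its own MID pair, and read
out with injected substitution, homopolymer-indel and chimeric errors at
configurable per-read rates.  Every emitted read is wrapped with the
forward MID+primer and the reverse-complemented reverse primer+MID, so the
output exercises the whole pipeline from demultiplexing onwards, and every
read is traceable to its source clone(s) and error events through the
recorded truth.

The default design mirrors a 16-clone assemblage in three dilution groups:
eight abundant clones, six at a tenth of that concentration, and a pair of
near-identical clones (two substitutions apart, emulating the two alleles
of a heterozygous individual) at half the concentration of the middle
group, amplified in five replicate PCRs of 2000 reads each.

Errors are injected per final read, not per PCR cycle: that reproduces the
abundance profiles the validation thresholds act on without simulating
amplification lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .ingest import PrimerSpec, RawRead, revcomp

BASES = "ACGT"

DEFAULT_FORWARD_PRIMER = "TGGTGCATGGCCGTTCTTAG"
DEFAULT_REVERSE_PRIMER = "GGTCTGTGATGCCCTTAGAT"

_FORWARD_MIDS = ("ACGAGTGC", "AGCACTGT", "ATCAGACG", "ATATCGCG", "CGTGTCTC",
                 "CTCGCGTG", "TAGTATCA", "TCTCTATG", "TGATACGT", "TACTGAGC")
_REVERSE_MID = "ACGTCTGA"


@dataclass(frozen=True)
class SpikedVariant:
    """A deliberate systematic error mixed in at clone-like concentration.

    The variant is the parent clone's sequence with a single substitution
    applied; ``concentration`` is its relative concentration factor on the
    same scale as the clone dilution factors, so abundance relative to the
    parent is concentration_variant / concentration_parent.
    """

    parent: str
    position: int
    base: str
    concentration: float


@dataclass(frozen=True)
class MockDesign:
    clones: tuple[tuple[str, str], ...]           # (clone_id, sequence)
    concentrations: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 5
    reads_per_replicate: int = 2000
    sub_rate: float = 0.001       # per base per read
    indel_rate: float = 0.001     # per homopolymer run (len >= 2) per read
    chimera_rate: float = 0.01    # per read
    seed: int = 0
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    spikes: tuple[SpikedVariant, ...] = ()
    extra_reads: tuple[tuple[str, int, int], ...] = ()  # (clone_id, replicate, n)

    def __post_init__(self):
        ids = [c for c, _ in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError("clone ids must be unique")
        for cid, seq in self.clones:
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"clone {cid} is not a plain nucleotide sequence")
        for cid in self.concentrations:
            if cid not in ids:
                raise ValueError(f"concentration given for unknown clone {cid}")
        if any(v <= 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be positive")
        for rate in (self.sub_rate, self.indel_rate, self.chimera_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must be in [0, 1)")
        if self.n_replicates < 1 or self.n_replicates > len(_FORWARD_MIDS):
            raise ValueError(f"n_replicates must be in 1..{len(_FORWARD_MIDS)}")

    def concentration(self, clone_id: str) -> float:
        return self.concentrations.get(clone_id, 1.0)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1:02d}" for i in range(self.n_replicates))

    def primer_spec(self, min_length: int = 0) -> PrimerSpec:
        return PrimerSpec(
            self.forward_primer,
            self.reverse_primer,
            {(_FORWARD_MIDS[i], _REVERSE_MID): s for i, s in enumerate(self.samples)},
            min_length=min_length,
        )


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample: str
    clones: tuple[str, ...]           # one entry, or two for a chimera
    events: tuple[tuple[str, int], ...]  # (event type, position in template)


@dataclass
class MockTruth:
    reads: list[ReadTruth]
    # unique trimmed sequence -> label; real clones win over coincidental errors
    sequence_labels: dict[str, str]

    def clone_sequences(self) -> set[str]:
        return {s for s, label in self.sequence_labels.items() if label.startswith("clone:")}


@dataclass
class MockDataset:
    design: MockDesign
    reads: list[RawRead]
    truth: MockTruth

    @property
    def primer_spec(self) -> PrimerSpec:
        return self.design.primer_spec()

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for read in self.reads:
                handle.write(f">{read.read_id}\n{read.bases}\n")

    def write_mid_map(self, path: str | Path) -> None:
        from .ingest import write_mid_map

        write_mid_map(self.primer_spec.mid_map, path)

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\tsample\tclones\tevents\n")
            for t in self.truth.reads:
                events = ";".join(f"{kind}@{pos}" for kind, pos in t.events)
                handle.write(f"{t.read_id}\t{t.sample}\t{'+'.join(t.clones)}\t{events}\n")


def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, length) of each homopolymer run of at least ``min_len``."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def random_clones(
    rng: np.random.Generator, n: int, length: int, prefix: str = "CL"
) -> list[tuple[str, str]]:
    clones = []
    seen = set()
    while len(clones) < n:
        seq = "".join(rng.choice(list(BASES), size=length))
        if seq in seen:
            continue
        seen.add(seq)
        clones.append((f"{prefix}{len(clones) + 1:02d}", seq))
    return clones


def default_design(
    seed: int = 7,
    n_replicates: int = 5,
    reads_per_replicate: int = 2000,
    clone_length: int = 150,
    sub_rate: float = 0.001,
    indel_rate: float = 0.001,
    chimera_rate: float = 0.01,
    **overrides,
) -> MockDesign:
    """The 16-clone, three-dilution-group reference design."""
    rng = np.random.default_rng(seed)
    group1 = random_clones(rng, 8, clone_length, prefix="G1-")
    group2 = random_clones(rng, 6, clone_length, prefix="G2-")
    # near-identical allele pair at half the group-2 concentration
    hz_a = "".join(rng.choice(list(BASES), size=clone_length))
    positions = rng.choice(clone_length, size=2, replace=False)
    hz_b = list(hz_a)
    for pos in positions:
        hz_b[pos] = BASES[(BASES.index(hz_b[pos]) + 1) % 4]
    clones = tuple(group1 + group2 + [("HZ-A", hz_a), ("HZ-B", "".join(hz_b))])
    conc = {cid: 1.0 for cid, _ in group1}
    conc.update({cid: 0.1 for cid, _ in group2})
    conc.update({"HZ-A": 0.05, "HZ-B": 0.05})
    return MockDesign(
        clones=clones,
        concentrations=conc,
        n_replicates=n_replicates,
        reads_per_replicate=reads_per_replicate,
        sub_rate=sub_rate,
        indel_rate=indel_rate,
        chimera_rate=chimera_rate,
        seed=seed,
        **overrides,
    )


def with_spiked_substitution(
    design: MockDesign, parent: str, relative_abundance: float, position: int = 10
) -> MockDesign:
    """Add a single-substitution variant of ``parent`` at a fixed relative abundance."""
    parents = dict(design.clones)
    if parent not in parents:
        raise KeyError(parent)
    base = parents[parent][position]
    alt = BASES[(BASES.index(base) + 1) % 4]
    spike = SpikedVariant(
        parent, position, alt, relative_abundance * design.concentration(parent)
    )
    return replace(design, spikes=design.spikes + (spike,))


def _spike_sequence(design: MockDesign, spike: SpikedVariant) -> str:
    parent_seq = dict(design.clones)[spike.parent]
    seq = list(parent_seq)
    seq[spike.position] = spike.base
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, design: MockDesign):
    """Apply per-read substitution and homopolymer-indel errors."""
    events = []
    chars = list(seq)
    if design.sub_rate > 0:
        hit = np.flatnonzero(rng.random(len(chars)) < design.sub_rate)
        for pos in hit:
            old = chars[pos]
            chars[pos] = BASES[(BASES.index(old) + rng.integers(1, 4)) % 4]
            events.append(("substitution", int(pos)))
    if design.indel_rate > 0:
        # indels are placed at homopolymer runs, the dominant pyrosequencing mode
        offset = 0
        for start, length in homopolymer_runs(seq):
            if rng.random() < design.indel_rate:
                pos = start + offset
                if rng.random() < 0.5 and length > 1:
                    del chars[pos]
                    offset -= 1
                    events.append(("deletion", start))
                else:
                    chars.insert(pos, seq[start])
                    offset += 1
                    events.append(("insertion", start))
    return "".join(chars), events


def generate(design: MockDesign) -> MockDataset:
    """Emit reads, MID wrapping and ground truth; reproducible from the seed."""
    rng = np.random.default_rng(design.seed)
    units: list[tuple[str, str, float, bool]] = [
        (cid, seq, design.concentration(cid), False) for cid, seq in design.clones
    ]
    for k, spike in enumerate(design.spikes):
        units.append(
            (f"spike{k + 1}:{spike.parent}", _spike_sequence(design, spike),
             spike.concentration, True)
        )
    weights = np.array([u[2] for u in units], dtype=float)
    probs = weights / weights.sum()
    clone_index = {u[0]: i for i, u in enumerate(units)}

    spec = design.primer_spec()
    rev_tail = revcomp(design.reverse_primer)
    mids = {s: (f, r) for (f, r), s in spec.mid_map.items()}

    reads: list[RawRead] = []
    truths: list[ReadTruth] = []
    origin: dict[str, list[tuple[str, ...]]] = {}

    def emit(sample: str, serial: int, template: str, sources: tuple[str, ...], events):
        seq, mut_events = _mutate(rng, template, design)
        fmid, rmid = mids[sample]
        read_id = f"{sample}_{serial:06d}"
        bases = fmid + design.forward_primer + seq + rev_tail + revcomp(rmid)
        reads.append(RawRead(read_id, bases))
        truths.append(ReadTruth(read_id, sample, sources, tuple(events) + tuple(mut_events)))
        origin.setdefault(seq, []).append(sources)

    for sample in design.samples:
        counts = rng.multinomial(design.reads_per_replicate, probs)
        serial = 0
        for (unit_id, template, _, is_spike), n in zip(units, counts):
            for _ in range(int(n)):
                serial += 1
                if not is_spike and design.chimera_rate > 0 and rng.random() < design.chimera_rate:
                    # two-parent hybrid with one breakpoint in the interior
                    others = [u for u in units if u[0] != unit_id and not u[3]]
                    ow = np.array([u[2] for u in others])
                    partner = others[rng.choice(len(others), p=ow / ow.sum())]
                    cut = int(rng.integers(1, min(len(template), len(partner[1]))))
                    hybrid = template[:cut] + partner[1][cut:]
                    emit(sample, serial, hybrid, (unit_id, partner[0]),
                         [("chimera_breakpoint", cut)])
                else:
                    label = ("spiked_substitution",) if is_spike else ()
                    emit(sample, serial, template,
                         (unit_id,), [(lbl, -1) for lbl in label])

    for clone_id, replicate, n in design.extra_reads:
        template = dict(design.clones)[clone_id]
        sample = design.samples[replicate]
        for k in range(n):
            # exact, error-free copies injected on top of the multinomial draw
            fmid, rmid = mids[sample]
            read_id = f"{sample}_extra{len(reads) + 1:06d}"
            reads.append(RawRead(
                read_id, fmid + design.forward_primer + template + rev_tail + revcomp(rmid)
            ))
            truths.append(ReadTruth(read_id, sample, (clone_id,), ()))
            origin.setdefault(template, []).append((clone_id,))

    labels = _label_sequences(design, origin)
    return MockDataset(design, reads, MockTruth(truths, labels))


def _label_sequences(design: MockDesign, origin) -> dict[str, str]:
    clone_seqs = {seq: cid for cid, seq in design.clones}
    spike_seqs = {_spike_sequence(design, s): s.parent for s in design.spikes}
    labels: dict[str, str] = {}
    for seq, sources in origin.items():
        if seq in clone_seqs:
            labels[seq] = f"clone:{clone_seqs[seq]}"
        elif seq in spike_seqs:
            labels[seq] = f"spiked_substitution:{spike_seqs[seq]}"
        else:
            chimeric = [s for s in sources if len(s) == 2]
            if len(chimeric) * 2 > len(sources):
                a, b = chimeric[0]
                labels[seq] = f"chimera:{a}+{b}"
            else:
                labels[seq] = f"error:{sources[0][0]}"
    return labels


def expected_error_abundance(design: MockDesign, clone_id: str, error_type: str) -> float:
    """Closed-form expected dataset-wide read count for one error class.

    'substitution': reads carrying at least one substitution (first order,
    rate x length x clone reads); 'indel': rate x homopolymer runs x clone
    reads; 'chimera': clone reads diverted into chimeras.
    """
    seqs = dict(design.clones)
    if clone_id not in seqs:
        raise KeyError(f"unknown clone {clone_id!r}")
    weights = sum(design.concentration(c) for c, _ in design.clones) + sum(
        s.concentration for s in design.spikes
    )
    total = design.n_replicates * design.reads_per_replicate
    clone_reads = total * design.concentration(clone_id) / weights
    seq = seqs[clone_id]
    if error_type == "substitution":
        return clone_reads * design.sub_rate * len(seq)
    if error_type == "indel":
        return clone_reads * design.indel_rate * len(homopolymer_runs(seq))
    if error_type == "chimera":
        return clone_reads * design.chimera_rate
    raise ValueError(f"unknown error type {error_type!r}")
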