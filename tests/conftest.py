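import pytest

import pyrodenoise as pn


@pytest.fixture
def params():
    return pn.ErrorParams()


def make_table(rows: dict[str, dict[str, int]], samples=None) -> pn.AbundanceTable:
    """Build an abundance table directly from {sequence: {sample: count}}."""
    return pn.AbundanceTable(rows, samples=samples)


def wrap_read(seq: str, fmid: str, rmid: str, spec: pn.PrimerSpec) -> str:
    """Assemble a raw read: MID + primer + insert + rc(primer) + rc(MID)."""
    return (
        fmid + spec.forward_primer + seq
        + pn.revcomp(spec.reverse_primer) + pn.revcomp(rmid)
    )


@pytest.fixture(scope="session")
def mock_dataset():
    """The default 16-clone, 5-replicate mock at full scale (10^4 reads)."""
    return pn.generate(pn.default_design(seed=7))


@pytest.fixture(scope="session")
def mock_result(mock_dataset):
    """Full pipeline run on the default mock under the 4-of-5 replicate design."""
    return pn.run_pipeline(
        mock_dataset.reads,
        mock_dataset.primer_spec,
        design=pn.ReplicationDesign("MS", 4),
    )
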