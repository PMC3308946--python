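import pytest

from edcas.editing_model import default_reference
from edcas.preprocess import DemuxConfig, QcThresholds
from edcas.site_calling import AlignmentParams


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def demux_cfg():
    return DemuxConfig()


@pytest.fixture(scope="session")
def qc():
    return QcThresholds()


@pytest.fixture(scope="session")
def aln_params():
    return AlignmentParams()


def make_trimmed_read(ref, code, read_id="r"):
    """Sense-oriented amplicon insert: flank5 + edited cassette + flank3."""
    from edcas.io_formats import Read

    seq = ref.amplicon_flank5 + ref.edited_sequence(code) + ref.amplicon_flank3
    return Read(id=read_id, sequence=seq)
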