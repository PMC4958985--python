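import pytest

from covpat.alignment_io import Alignment


@pytest.fixture
def toy6() -> Alignment:
    """Six 2-column records: three AT and three GC — two perfect pairs."""
    return Alignment(
        ids=("s1", "s2", "s3", "s4", "s5", "s6"),
        seqs=("AT", "AT", "AT", "GC", "GC", "GC"),
    )


def make_alignment(seqs, prefix="s", **kw) -> Alignment:
    return Alignment(
        ids=tuple(f"{prefix}{i}" for i in range(len(seqs))),
        seqs=tuple(seqs),
        **kw,
    )
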