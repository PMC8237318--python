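import textwrap

import pytest

from dagsh import parse_pipeline


@pytest.fixture
def parse_xml():
    """Parse a dedented inline pipeline document."""

    def _parse(xml: str):
        return parse_pipeline(textwrap.dedent(xml))

    return _parse


@pytest.fixture
def workdir(tmp_path):
    d = tmp_path / "work"
    d.mkdir()
    return d
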