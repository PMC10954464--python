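import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable


@pytest.fixture()
def tmp_text(tmp_path):
    """Write text content to a temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
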