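import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import plain_header  # noqa: E402


@pytest.fixture
def header():
    return plain_header()
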