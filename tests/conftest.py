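import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ethoscore import builtin_template


@pytest.fixture
def fst():
    return builtin_template("FST")


@pytest.fixture
def nor():
    return builtin_template("NOR")


@pytest.fixture
def epm():
    return builtin_template("EPM")
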