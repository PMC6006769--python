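import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from reptronkit.rep_scanner import RepRuleSet


@pytest.fixture(scope="session")
def default_rules() -> RepRuleSet:
    return RepRuleSet()


@pytest.fixture(scope="session")
def short_only_rules() -> RepRuleSet:
    return RepRuleSet(allow_long=False)
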