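import json
import logging
from pathlib import Path

import pytest

from idoct import validation

logging.getLogger("idoct").setLevel(logging.ERROR)

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def benchmark():
    """The packaged synthetic benchmark, run once per session.

    Seed 1; 400 normative + 200 patients; the full 18-task registry with
    default generator settings; 999 CCA permutations.
    """
    return validation.benchmark_run(seed=1, cca_n_perm=999)


@pytest.fixture(scope="session")
def toy_fixture():
    """3-participant x 2-condition toy table with hand-computed intermediates."""
    return json.loads((FIXTURES / "idoct_toy.json").read_text())
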