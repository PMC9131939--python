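import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles helper

from mirhub import circuit, seedmatch  # noqa: E402

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture(scope="session")
def let7() -> seedmatch.MatureMiRNA:
    return seedmatch.MatureMiRNA("let-7", LET7)


@pytest.fixture(scope="session")
def default_model() -> circuit.CircuitModel:
    return circuit.build_default_circuit()


@pytest.fixture(scope="session")
def case_runs(default_model):
    """OFF and ON induction-case trajectories of the default circuit."""
    off, off_label = circuit.run_case(default_model, "off_case1")
    on, on_label = circuit.run_case(default_model, "on_case2")
    return {"off": (off, off_label), "on": (on, on_label)}
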