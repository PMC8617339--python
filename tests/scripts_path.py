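"""Helper to import the standalone acceptance script from the test suite."""

import importlib.util
from pathlib import Path

SCRIPTS = Path(__file__).resolve().parents[1] / "scripts"


def load_acceptance_compute():
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", SCRIPTS / "acceptance.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod.compute
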