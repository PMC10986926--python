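"""Load the acceptance script as a module so tests can reuse its loaders."""

import importlib.util
from pathlib import Path

_path = Path(__file__).resolve().parent.parent / "scripts" / "acceptance.py"
_spec = importlib.util.spec_from_file_location("acceptance_script", _path)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)

free_living_targets = _mod.free_living_targets
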