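"""Named parameter presets.

One preset per simulated experiment (plus the nominal visuomotor set and
the saccadic-system set), shipped as a JSON document.  Table entries the
source simulations mark as irrelevant for a given experiment are filled
with the nominal value, except the learning-transfer rate which is set to
0 where it plays no role, so that disabling it is exact.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .model_core import ModelParams

__all__ = ["available_presets", "load_preset", "preset_table"]


@lru_cache(maxsize=1)
def preset_table() -> dict[str, dict]:
    text = (resources.files("doadapt") / "presets" / "presets.json").read_text()
    return json.loads(text)


def available_presets() -> list[str]:
    return list(preset_table())


def load_preset(name: str) -> ModelParams:
    """Look up a preset by name and return it as ModelParams."""
    table = preset_table()
    if name not in table:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(table)}")
    return ModelParams(**table[name])
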