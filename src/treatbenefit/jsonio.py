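"""Deterministic JSON output.

Floats are serialized at 10 significant digits and keys are sorted, so
identical inputs and seeds produce byte-identical result files across
platforms.
"""

from __future__ import annotations

import json
import math


def _round_floats(obj):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def dumps_json(obj) -> str:
    return json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n"


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_json(obj))
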