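#!/usr/bin/env python
"""Regenerate the shipped default clock model (deterministic, seed 7).

    python scripts/calibrate_default.py

writes src/circakit/data/default_model.json; equivalent to
`circakit model calibrate --seed 7 --out ...`.
"""

import json
from pathlib import Path

from circakit.clockmodel import calibrate_default_model

model = calibrate_default_model(seed=7)
out = Path(__file__).resolve().parent.parent / "src/circakit/data/default_model.json"
with open(out, "w") as fh:
    json.dump(model.to_dict(), fh, indent=1)
print(f"wrote {out}")
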