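#!/usr/bin/env python
"""Secondary-structure inference from the backbone chemical shifts.

Computes per-residue secondary shifts against the random-coil reference,
the windowed propensity score, and calls strand/helix segments. On the
study-condition fixture the expected outcome is three beta-strands at
residues 8-12, 15-18 and 26-29.
"""

import json
from pathlib import Path

from memtrap.pipeline import stage_ss

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    result = stage_ss(ROOT / "synthetic" / "shifts.tsv", ROOT / "ss")
    print(f"{result['n_assigned']} of 37 residues assigned")
    segs = json.loads((ROOT / "ss" / "ss_segments.json").read_text())
    for s in segs["segments"]:
        print(f"  {s['type']:6s} residues {s['start']}-{s['end']}")
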