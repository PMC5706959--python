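#!/usr/bin/env python
"""Generate the study-condition synthetic inputs for every later step.

Writes a ThT plate (3 conditions x 3 replicates, 4-min readings over
48 h), a 29-row backbone shift table over the 37-residue hIAPP sequence,
the four HMQC intensity tables (reference + ND, Gd, 5-DSA probes), and
the bead-chain/bead-slab coordinate pair - each with its ground-truth
table - under results/synthetic/.
"""

from pathlib import Path

from memtrap.pipeline import stage_simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2017

if __name__ == "__main__":
    produced = stage_simulate(SEED, OUT)
    print(f"seed {SEED}: wrote {len(produced)} input files to {OUT}")
    for key, path in sorted(produced.items()):
        print(f"  {key:18s} {Path(path).name}")
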