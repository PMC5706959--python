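# Full-structure secondary-shift reference offsets (ppm) used to normalize
# per-residue scores into the [-1, +1] propensity scale: a residue sitting at
# the helix reference for every nucleus scores +1, at the strand reference -1.
# Values are consensus magnitudes of fully-formed helix/strand secondary
# shifts for backbone 13Ca and 13Cb ("ssp-consensus-v1").
# columns: nucleus	refH	refE
nucleus	refH	refE
CA	2.8	-1.5
CB	-0.5	2.3
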