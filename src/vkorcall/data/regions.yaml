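# Region annotation for VKOR residue ranges (1-based, inclusive), used to
# explain why a mutation outside the ligand neighborhood is not docking-
# suitable.  The boundaries are configuration, not structure-derived fact:
# they approximate the VKOR topology (transmembrane four-helix bundle, an
# ER-luminal region whose cap domain covers the binding pocket, and short
# cytoplasmic segments) and can be replaced per structure.
cytoplasmic interface: [[1, 10], [92, 100]]
ER-luminal region: [[24, 50]]
cap domain: [[51, 78]]
membrane: [[11, 23], [79, 91], [101, 161]]
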