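"""Transmembrane and coiled-coil prediction on single sequences.

The TM finder slides a 19-residue Kyte-Doolittle window (mean hydropathy
>= 1.6); the coiled-coil scorer rates 28-residue windows by heptad-register
fit.  Both return merged, disjoint segments.
"""

from rdomarch import ProteinRecord, classify_tm_position, predict_cc, predict_tm

# a receptor-like protein shape: extracellular stretch, then one TM helix
# 23 residues before a short cytoplasmic tail
rlp_like = ProteinRecord("rlp_like", "M" + "DKESTNQ" * 40 + "ILFILFILFILFILFILFILFIL" + "KRKDE")
for seg in predict_tm(rlp_like):
    pos = classify_tm_position(seg, len(rlp_like))
    print(f"TM {seg.start}-{seg.end}  mean KD {seg.mean_hydropathy:.2f}  position {pos}")

# an N-terminal coiled-coil followed by a hydrophilic region, the layout of
# a CC-NBS-LRR (CNL) amino terminus
cnl_nterm = ProteinRecord("cnl_nterm", "M" + "LEALEGK" * 6 + "DKESTNQ" * 30)
for seg in predict_cc(cnl_nterm):
    print(f"CC {seg.start}-{seg.end}  heptad score {seg.score:.2f}")

# The TM segment sits within 75 residues of the C terminus, so it classifies
# C_TERMINAL (the receptor-like-protein membrane anchor); the coiled-coil
# segment near the start is what routes an NBS-LRR protein to the CNL
# subclass.
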