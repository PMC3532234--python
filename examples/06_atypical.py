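"""Atypical associations, transposon insertions and tandem R-domain repeats.

Builds a few hand-crafted annotation rows of the kinds reported for real
transcript datasets — an NBS protein with a WRKY transcription-factor
domain, an NBS protein carrying a Gag-Pol retrotransposon signature, and a
TNL with a second TIR copy at its far end — and runs the atypical screen.
"""

from rdomarch import classify_protein, collapse_hits, detect_atypical
from rdomarch.io import DomainHit


def hit(pid, sig, cat, start, end, subrole="generic", desc=""):
    return DomainHit(protein_id=pid, signature_id=sig, database="Pfam",
                     start=start, end=end, category=cat, subrole=subrole,
                     description=desc)


hits = [
    # NBS + WRKY: an atypical R/transcription-factor fusion
    hit("prot_wrky", "PF00931", "NBS", 10, 300),
    hit("prot_wrky", "PF03106", "NONR", 400, 460, "WRKY", "WRKY transcription factor"),
    # NBS + retrotransposon Gag-Pol
    hit("prot_tn", "PF00931", "NBS", 10, 300),
    hit("prot_tn", "PF03732", "NONR", 350, 700, "GAG_POL", "Gag-Pol-related Retrotransposon"),
    # TNL with a repeated TIR domain at the C terminus
    hit("prot_tnl_tir", "PF01582", "TIR", 5, 150),
    hit("prot_tnl_tir", "PF00931", "NBS", 200, 500),
    hit("prot_tnl_tir", "PF00560", "LRR", 550, 850),
    hit("prot_tnl_tir", "PF01582", "TIR", 900, 1040),
]

collapsed = collapse_hits(hits)
for pid, intervals in collapsed.items():
    categories = [c for c in intervals if c in ("TIR", "NBS", "LRR", "KIN", "OTHR")]
    call = classify_protein(pid, categories)
    aty = detect_atypical(call, hits, intervals)
    print(
        f"{pid}: class {aty.label:12s} aty_domains={aty.aty_domains} "
        f"transposon={aty.transposon} repeats={aty.repeat_domains} flags={sorted(call.flags)}"
    )

# prot_wrky reports as NBS-AtyR; prot_tn additionally carries the transposon
# flag; prot_tnl_tir keeps its TNL class but is flagged DOMAIN_REPEAT with
# two disjoint TIR copies.
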