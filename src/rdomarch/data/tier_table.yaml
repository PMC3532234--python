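# Candidate tier table: class label or subclass -> tier.
#
# Reconstruction of the colour legend of the five-set Venn filtering summary:
# strong candidates (TNL/CNL), plausible-but-undescribed resistance-capable
# classes, classes needing further validation, and ubiquitous classes excluded
# outright.  Lookup order: subclass first, then class label, then `default`.
# Editable by design — the source analysis does not enumerate every region.
tiers:
  # strongest candidates
  TNL: STRONG
  CNL: STRONG
  # resistance-capable, undescribed as functional classes
  NBS-LRR: PLAUSIBLE
  CC-NBS: PLAUSIBLE
  TIR-NBS: PLAUSIBLE
  TIR: PLAUSIBLE
  NBS: PLAUSIBLE
  # classes admitted only after a reference/signature filter
  RLP: PLAUSIBLE            # post Fritz-Laylin-style reference-clade filter
  PTO-like: PLAUSIBLE
  MLO-like: PLAUSIBLE       # post reference-clade filter
  RPW8-like: PLAUSIBLE
  RLP-candidate: NEEDS_VALIDATION
  MLO-like-candidate: NEEDS_VALIDATION
  # ubiquitous classes excluded from the candidate set
  LRR: EXCLUDED
  RLK: EXCLUDED
  KIN: EXCLUDED             # kinases not matching the PTO-like signatures
  LRR-OthR: EXCLUDED
  LRR-KIN-OthR: EXCLUDED
  KIN-OthR: EXCLUDED
default: NEEDS_VALIDATION
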