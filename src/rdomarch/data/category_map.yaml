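# Default signature -> macro-category map.
#
# This is a reconstruction: only four accessions are fixed by the study design
# (PF03094 MLO, PF05659 RPW8, PTHR24420:SF785 and PTHR23258:SF418 PTO-like);
# the rest are representative Pfam/PANTHER/SMART accessions for the five
# macro-categories (LRR, NBS, TIR, KIN, OthR) plus the named non-R signatures
# used for atypical-association calls.  Edit freely; exact ids beat prefixes.
#
# entry fields: category in {LRR, NBS, TIR, KIN, OTHR, NONR}; subrole optional.
exact:
  # Other-R families
  PF03094: {category: OTHR, subrole: MLO_LIKE}     # Mlo seven-TM family
  PF05659: {category: OTHR, subrole: RPW8}         # RPW8 powdery-mildew resistance
  PF00954: {category: OTHR, subrole: generic}      # S-locus glycoprotein
  # PTO-like kinases (PANTHER subfamilies)
  "PTHR24420:SF785": {category: KIN, subrole: PTO_LIKE}
  "PTHR23258:SF418": {category: KIN, subrole: PTO_LIKE}
  # core R-domain signatures
  PF00931: {category: NBS, subrole: generic}       # NB-ARC
  PF01582: {category: TIR, subrole: generic}       # TIR
  SM00255: {category: TIR, subrole: generic}
  PF00069: {category: KIN, subrole: generic}       # Pkinase
  PF07714: {category: KIN, subrole: generic}       # Pkinase_Tyr
  PF00560: {category: LRR, subrole: generic}       # LRR_1
  PF07723: {category: LRR, subrole: generic}       # LRR_2
  PF07725: {category: LRR, subrole: generic}       # LRR_3
  PF13855: {category: LRR, subrole: generic}       # LRR_8
  PF08263: {category: LRR, subrole: generic}       # LRRNT_2
  # named non-R signatures (atypical-association vocabulary)
  PF03106: {category: NONR, subrole: WRKY}         # WRKY DNA-binding
  PF03637: {category: NONR, subrole: generic}      # Mob1
  PF13912: {category: NONR, subrole: generic}      # zinc finger C2H2
  PF00098: {category: NONR, subrole: generic}      # zinc finger CCHC
  PF13676: {category: NONR, subrole: TIRAP}        # TIR-domain adapter-like
  PF00481: {category: NONR, subrole: generic}      # protein phosphatase 2C
  PF03732: {category: NONR, subrole: GAG_POL}      # Retrotrans_gag
  PF00078: {category: NONR, subrole: GAG_POL}      # reverse transcriptase
  PF00665: {category: NONR, subrole: GAG_POL}      # integrase core
prefix:
  # PANTHER NBS-LRR family umbrella
  PTHR23155: {category: NBS, subrole: generic}
# subroles whose presence marks a transposon-derived protein
transposon_subroles: [GAG_POL]
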