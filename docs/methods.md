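# Methods

## Problem and scope

Plant disease-resistance (R) proteins are built from a small vocabulary of
domains: the Toll/interleukin-1-receptor homology domain (TIR), the
nucleotide-binding site (NBS), leucine-rich repeats (LRR), serine/threonine
kinase domains (KIN), and a catch-all "other resistance-related" bin (OthR)
holding families such as MLO (Pfam PF03094) and RPW8 (PF05659).  `rdomarch`
takes translated protein sequences plus their InterProScan-style domain
annotations and answers four questions:

1. which domain-combination class does each protein belong to, and how does
   the observed class census compare with a neutral combinatorial model;
2. which proteins survive a structural/phylogenetic filtering decision tree
   as credible resistance candidates, and at what confidence tier;
3. how conserved is each class internally (identity, identical sites,
   per-column conservation), and is the identity estimate stable under
   subsampling;
4. which proteins carry atypical domain company — named non-R domains,
   retrotransposon signatures, or tandem copies of one R domain.

MSA construction, HMM scanning and transcript translation are upstream of
the package: alignments arrive as aligned FASTA, annotations as TSV.

## Classification and the combinatorial model

Raw signature accessions are mapped to the five macro-categories through an
editable YAML map; exact accessions beat prefix rules, and unknown
signatures become `UNMAPPED`, which can never create a class.  Only four
accessions of the original mapping are documented (PF03094, PF05659,
PTHR24420:SF785, PTHR23258:SF418); the shipped map is otherwise a
reconstruction from representative Pfam/PANTHER/SMART accessions and should
be replaced by the user's own mapping for real data.

Overlapping or bookended hits of one category are unioned into disjoint
intervals (multiple member databases routinely report the same region).  A
protein's class is its *set* of categories, labelled in the fixed order
TIR-NBS-LRR-KIN-OthR; `k` counts distinct categories, never domain copies
(tandem copies are a flag, not a class).  With `n` categories there are
`2^n − 1` possible classes, `C(n, k)` of them with `k` domains; the
theoretical fraction of k-domain classes is `C(n, k)/(2^n − 1)`, kept as an
exact rational so rounding is a presentation choice.  Report percentages use
one-decimal *truncation* (16.504 → "16.5%", 56.25 → "56.2%"), with integer
percentages printed without a decimal ("100%", "9%") — this is the format
of the summary tables the package emulates, implemented over integer
arithmetic to avoid float edge cases.

## Structure features

The package substitutes desk-scale deterministic predictors for external
membrane-topology and coiled-coil tools (whose output can be ingested
instead via a segments TSV):

* **Transmembrane segments** — Kyte–Doolittle sliding window, window 19
  residues, threshold mean hydropathy 1.6 (dimensionless; the classical
  membrane-spanning cutoff region).  Qualifying windows are merged, so every
  segment is ≥ 19 residues.  `X` is treated as hydropathy 0.
* **Coiled-coils** — for each 28-residue window (four heptads) and each of
  the 7 registers, score = (fraction of a/d core slots holding L, I, V, M, A
  or F) − 0.5 × (fraction of e/g flank slots holding those residues),
  clipped to [0, 1]; best register wins, windows ≥ 0.5 merge.  A clean
  (LEALEGK)ₙ repeat scores 1.0.
* **TM position** — C-terminal iff the segment ends within 75 residues of
  the protein end (the short cytoplasmic tail typical of receptor-like
  proteins); N-terminal iff it starts within 75 residues of the start;
  C-terminal wins for tiny proteins where both apply.  The margin is
  configurable.

These are crude by design: they recover strongly hydrophobic helices and
canonical heptads reliably (≥ 0.9 recall/precision on planted segments in
hydrophilic background) but will miss amphipathic TM helices and will score
occasional background windows above the coiled-coil cutoff.  The latter can
flip an NBS-LRR protein to CNL on real-looking random sequence; no tier
boundary in the default tier table depends on that distinction alone
(both are candidate tiers).

## Filtering decision tree

* NBS-LRR proteins split into **CNL** iff a coiled-coil segment *starts
  before the NBS interval* (the canonical CNL layout has an N-terminal CC;
  we follow the layout, and the rule is configurable), else NBS-LRR; NBS-only
  proteins split into CC-NBS vs NBS the same way.
* LRR (± KIN) proteins with TM evidence split into **RLP** (LRR only, all
  TM segments C-terminal) and **RLK** (LRR + KIN with an internal TM
  separating extracellular LRR from intracellular kinase).
* Kinases are narrowed to **PTO-like** by PANTHER subfamily signatures;
  OthR proteins to **MLO-like** (PF03094) and **RPW8-like** (PF05659)
  candidates; RPW8 in an NBS-LRR context is routed to the atypical report.
* MLO-like (and, given references, RLP) candidates pass a
  **reference-clade filter**: p-distance matrix (gap columns excluded per
  pair, `X` matches nothing) → neighbor-joining tree → midpoint rooting →
  smallest clade containing all references that contains at least one
  query; its non-reference leaves are selected.  NJ is implemented here
  because its determinism is part of the contract: ties in the Q criterion
  break toward the lowest index pair and negative branch estimates clamp to
  zero.  On additive matrices the tree reproduces the input distances to
  1e-9.  If the references span the midpoint root the whole tree is used and
  a warning emitted.  An externally computed newick tree (e.g. from a
  maximum-likelihood program) can be supplied instead.
* Every classified protein receives exactly one **tier** from an editable
  YAML table: STRONG (CNL, TNL), PLAUSIBLE (NBS-LRR, CC-NBS, TIR-NBS, TIR,
  NBS, and the filtered RLP / PTO-like / MLO-like / RPW8 sets),
  NEEDS_VALIDATION (default for everything unlisted, including unfiltered
  MLO/RLP candidates), EXCLUDED (ubiquitous classes: LRR-only, RLK,
  plain KIN, LRR-OthR, LRR-KIN-OthR, KIN-OthR).  The table is a
  reconstruction of a colour-coded candidate summary and is deliberately
  user-editable.

## Conservation statistics

"Identity" of a class alignment is the mean over all sequence pairs of
matches / compared columns, where columns with a gap in *either* member of
the pair are excluded per pair (the convention of common alignment
viewers); `X` matches nothing.  "Identical sites" are columns that are
gap-free and unanimous, as a fraction of alignment length.  Per-column
conservation is the modal-residue frequency among non-gap entries scaled by
the non-gap fraction (a half-gapped unanimous column scores 0.5); residue
ties break alphabetically, and the consensus shows `-` when gaps outnumber
every residue.  An optional column-occupancy mask (drop columns with more
than a given gap fraction) stands in for manual removal of unaligned
regions.  Because the definition of "identity" in the emulated tables is
unstated, the choice above is documented rather than assumed unique.

**Batch ANOVA.**  To check that class identity is not an artefact of how
many sequences are aligned, `n_batches` (default 10) random batches of
`batch_size` (default 10) sequences are drawn — disjoint when the class has
at least `batch_size × n_batches` members, otherwise independent
without-replacement draws — and batch identities are compared with the
full-class value.  The rejection flags at α = 0.05 / 0.01 are driven by a
one-way F across batches whose observations are identities of *disjoint*
sequence pairs within each batch: pairwise identities sharing a sequence
are correlated, and using all pairs makes the nominal F wildly
anticonservative (measured same-distribution rejection ≈ 0.99), while a
one-sample t of batch identities against the full-class value is degenerate
in the other direction (the reference value is computed from the same data;
measured rejection ≈ 0).  The disjoint-pair F is calibrated (measured
same-distribution rejection ≈ 0.03–0.06 at α = 0.05).  The one-sample t is
still reported for reference.  Degenerate all-constant inputs report
F = 0, p = 1.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
protein evolution.  Proteins start with methionine and interleave
hydrophilic linkers (10–40 residues, composition biased to D/E/K/N/Q/S/T/
G/P/R, mean hydropathy ≈ −1.6) with planted blocks:

* LRR: 4–10 repeats of a 24-residue LxxLxLxx-patterned template;
* NBS 150–300, TIR 120–180, KIN 200–280, OthR 100–250 residues of
  Dirichlet-perturbed background composition (one perturbation per category
  per dataset);
* TM: 23-mers over {I, L, F}; CC: (LEALEGK)₄.

Fifteen class blueprints cover the canonical architectures (TNL, CNL,
NBS-LRR, CC-NBS, TIR-NBS, RLK, RLP, PTO-like, MLO-like, KIN-OthR and the
single-domain classes); default class frequencies are the observed shares of
the survey the package emulates (kinases 35.2%, receptor classes ~22.9%
split between RLK and RLP, CNL+TNL 9.2%, kinase-OthR 13%, minor classes at
their census fractions).  Each planted block emits one or two
InterProScan-dialect TSV rows (two member databases where a category has
two representative accessions — redundant annotation being the norm in real
InterProScan output); annotation noise removes a row or re-maps it to an
unknown accession with equal probability.  All randomness flows from one
seed through spawned `numpy` generators, so outputs are byte-identical per
seed.

Class alignments are star phylogenies: a uniform-random ancestor mutated
independently per sequence at a per-site rate `d`, replacements drawn
uniformly from all 20 residues (so expected pairwise identity is
`(1 − d′)² + (1 − (1 − d′)²)/20` with `d′ = 19d/20`, ≈ 5% at `d = 1`);
optional independent per-site gaps.

What passing closed-loop tests show — and do not show: at zero noise the
pipeline recovers 100% of planted class labels, and ≥ 0.85 macro-averaged
recall survives 10% per-row annotation noise; this validates the plumbing
and the decision rules, not performance on real proteomes, whose domain
boundaries, compositional biases and annotation errors are far richer than
the generator's.

## Numerical choices and degenerate inputs

* Coordinates 1-based inclusive everywhere (InterProScan convention);
  intervals merge when overlapping or bookended (end + 1 = next start).
* A single terminal `*` is stripped; internal `*` is an error; `X` is
  allowed and mismatches everything in identity computations.
* Sequences shorter than a predictor window yield no segments (not an
  error).  Empty inputs produce empty reports with warnings, not failures.
* A sequence pair with zero comparable columns is an error in distance
  computation (it would have no defined distance) but only a warning, with
  exclusion, in identity statistics.
* Tie-breaks are deterministic everywhere: lowest index in NJ, alphabetical
  in consensus calls; the pipeline default seed is 42.

## Known limitations

* The signature→category map and the tier table are reconstructions; both
  ship as editable config and should be adapted for real datasets.
* The TM/CC predictors are intentionally simple; use the segments-TSV
  ingest to supply predictions from dedicated tools when fidelity matters.
* p-distance + NJ replaces maximum-likelihood tree inference; for clade
  *membership* at small scale this is usually adequate, and a newick
  override is provided for anything finer.
* The generator does not emulate domain-boundary uncertainty, compositional
  drift between species, or profile-HMM emission.
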