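"""The candidate-filtering decision tree.

Classified proteins are refined and tiered:

* NBS-LRR proteins split into CNL (coiled-coil starting before the NBS
  region) vs plain NBS-LRR; NBS-only proteins likewise into CC-NBS vs NBS.
* LRR/LRR-KIN proteins with transmembrane evidence split into receptor-like
  proteins (RLP: all TM segments C-terminal, no kinase) and receptor-like
  kinases (RLK: internal TM separating the extracellular LRR from the
  kinase).
* Other-R and kinase classes are narrowed by signature (MLO-like PF03094,
  RPW8 PF05659, PTO-like PANTHER subfamilies).
* MLO-like and RLP candidates are kept only when they fall in the same clade
  as reference resistance proteins, on a p-distance neighbor-joining tree
  (midpoint-rooted); an externally computed newick tree may be supplied
  instead.
* Every classified protein then receives exactly one candidate tier:
  STRONG, PLAUSIBLE, NEEDS_VALIDATION or EXCLUDED (UNOBSERVED marks
  theoretical classes with no members).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from skbio import DistanceMatrix, TreeNode

from .architecture import ArchitectureCall
from .features import C_TERMINAL, INTERNAL, CCSegment, TMSegment, classify_tm_position
from .io import DomainHit

STRONG = "STRONG"
PLAUSIBLE = "PLAUSIBLE"
NEEDS_VALIDATION = "NEEDS_VALIDATION"
EXCLUDED = "EXCLUDED"
UNOBSERVED = "UNOBSERVED"
TIERS = (STRONG, PLAUSIBLE, NEEDS_VALIDATION, EXCLUDED, UNOBSERVED)


class FilterError(ValueError):
    """A split applied to a protein outside its precondition."""


@dataclass
class TierTable:
    """Class/subclass -> tier lookup; subclass entries take precedence."""

    tiers: Mapping[str, str]
    default: str = NEEDS_VALIDATION

    def lookup(self, call: ArchitectureCall) -> str:
        if call.subclass and call.subclass in self.tiers:
            return self.tiers[call.subclass]
        return self.tiers.get(call.class_label, self.default)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TierTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tiers=dict(raw["tiers"]), default=raw.get("default", NEEDS_VALIDATION))

    @classmethod
    def default_table(cls) -> "TierTable":
        ref = importlib.resources.files("rdomarch.data") / "tier_table.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls(tiers=dict(raw["tiers"]), default=raw.get("default", NEEDS_VALIDATION))


# ---------------------------------------------------------------------------
# subclass splits


def _first_interval_start(intervals_by_cat: Mapping[str, Sequence[tuple[int, int]]],
                          category: str) -> int | None:
    ivs = intervals_by_cat.get(category)
    return min(s for s, _ in ivs) if ivs else None


def split_nbs_lrr(
    call: ArchitectureCall,
    cc: Sequence[CCSegment],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> str:
    """CNL iff a coiled-coil segment starts before the NBS region; else NBS-LRR.

    The coiled-coil of a canonical CNL is N-terminal, upstream of the
    nucleotide-binding site.
    """
    if call.categories != frozenset({"NBS", "LRR"}):
        raise FilterError(f"{call.protein_id}: split_nbs_lrr needs categories {{NBS, LRR}}")
    return "CNL" if _has_cc_before_nbs(cc, intervals) else "NBS-LRR"


def split_nbs(
    call: ArchitectureCall,
    cc: Sequence[CCSegment],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> str:
    """CC-NBS iff a coiled-coil segment starts before the NBS region; else NBS."""
    if call.categories != frozenset({"NBS"}):
        raise FilterError(f"{call.protein_id}: split_nbs needs categories {{NBS}}")
    return "CC-NBS" if _has_cc_before_nbs(cc, intervals) else "NBS"


def _has_cc_before_nbs(
    cc: Sequence[CCSegment], intervals: Mapping[str, Sequence[tuple[int, int]]]
) -> bool:
    nbs_start = _first_interval_start(intervals, "NBS")
    if nbs_start is None or not cc:
        return False
    return any(seg.start < nbs_start for seg in cc)


def split_receptor(
    call: ArchitectureCall, tm: Sequence[TMSegment], protein_length: int,
    cterm_margin: int = 75,
) -> str:
    """Split transmembrane receptors: RLP vs RLK vs NONE.

    LRR-only proteins whose TM segments are all C-terminal are receptor-like
    proteins (RLP); LRR+KIN proteins with an internal TM (the membrane pass
    between extracellular LRR and intracellular kinase) are receptor-like
    kinases (RLK); anything else is NONE.
    """
    if not tm:
        return "NONE"
    positions = [classify_tm_position(s, protein_length, cterm_margin) for s in tm]
    if call.categories == frozenset({"LRR"}) and all(p == C_TERMINAL for p in positions):
        return "RLP"
    if call.categories == frozenset({"LRR", "KIN"}) and any(p == INTERNAL for p in positions):
        return "RLK"
    return "NONE"


# ---------------------------------------------------------------------------
# distance, neighbor-joining, clade extraction


def p_distance(sequences: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distance matrix of aligned sequences.

    d(i, j) = mismatches / compared columns, columns with a gap in either
    sequence excluded; 'X' mismatches every residue.  A pair with zero
    comparable columns raises, naming the pair.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    ids = [sid for sid, _ in sequences]
    lengths = {len(s) for _, s in sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s) for _, s in sequences])
    gap = arr == "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            mism = int((((arr[i] != arr[j]) | (arr[i] == "X")) & ok).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(d, ids)


def nj_build(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou-Nei agglomeration with the Studier-Keppler Q criterion;
    deterministic: ties in Q are broken toward the lowest (i, j) index pair,
    and negative branch-length estimates are clamped to zero.  The result is
    unrooted (trifurcating root).
    """
    ids = list(distances.ids)
    if len(ids) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    d = distances.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of flattened array scans row-major
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = float(li), float(lj)
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # join the last three nodes at a single internal vertex
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = float(max(ln, 0.0))
    return root


def clade_select(tree: TreeNode, references: Iterable[str]) -> set[str]:
    """Leaves sharing the smallest clade with all reference taxa.

    The (unrooted) tree is midpoint-rooted, the smallest rooted clade
    containing every reference is found, and its non-reference leaves are
    returned.  If the references span the root the whole tree is the fallback
    (all queries selected) and a warning is emitted.
    """
    refs = set(references)
    if not refs:
        raise ValueError("need at least one reference taxon")
    leaves = {t.name for t in tree.tips()}
    missing = refs - leaves
    if missing:
        raise ValueError(f"references not in tree: {sorted(missing)}")
    work = tree.copy()
    total_length = sum(n.length or 0.0 for n in work.traverse())
    if total_length > 0:
        work = work.root_at_midpoint()
    if refs == leaves:
        return set()
    ref_tips = [t for t in work.tips() if t.name in refs]
    mrca = ref_tips[0] if len(ref_tips) == 1 else work.lca(ref_tips)
    # expand to the smallest clade that also contains at least one query
    while {t.name for t in mrca.tips()} <= refs:
        mrca = mrca.parent
    if mrca.is_root():
        warnings.warn(
            "reference taxa span the root; falling back to the whole tree",
            stacklevel=2,
        )
    return {t.name for t in mrca.tips() if t.name not in refs}


# ---------------------------------------------------------------------------
# signature filters and tier assignment


def signature_select(
    calls: Sequence[ArchitectureCall], hits: Sequence[DomainHit]
) -> dict[str, set[str]]:
    """Route proteins by subrole-tagged signatures.

    Returns protein-id sets: ``PTO_like`` (kinase proteins carrying a PTO-like
    PANTHER subfamily hit), ``MLO_like_candidates`` (Other-R proteins with the
    MLO signature, pending the reference-clade filter), ``RPW8_like`` (RPW8
    signature, no NBS-LRR context) and ``RPW8_NBS_LRR`` (RPW8 with an NBS-LRR
    profile, routed to the atypical-association report).
    """
    by_prot: dict[str, set[str]] = {}
    for h in hits:
        by_prot.setdefault(h.protein_id, set()).add(h.subrole)
    out: dict[str, set[str]] = {
        "PTO_like": set(), "MLO_like_candidates": set(),
        "RPW8_like": set(), "RPW8_NBS_LRR": set(),
    }
    for call in calls:
        roles = by_prot.get(call.protein_id, set())
        if "PTO_LIKE" in roles and "KIN" in call.categories:
            out["PTO_like"].add(call.protein_id)
        if "MLO_LIKE" in roles and "OTHR" in call.categories:
            out["MLO_like_candidates"].add(call.protein_id)
        if "RPW8" in roles:
            if {"NBS", "LRR"} <= call.categories:
                out["RPW8_NBS_LRR"].add(call.protein_id)
            else:
                out["RPW8_like"].add(call.protein_id)
    return out


def assign_tier(call: ArchitectureCall, table: TierTable | None = None) -> str:
    """Assign the candidate tier of one classified protein (total function)."""
    if table is None:
        table = TierTable.default_table()
    tier = table.lookup(call)
    call.tier = tier
    return tier


@dataclass
class FilterResult:
    """Outcome of the full decision tree on one dataset."""

    calls: list[ArchitectureCall]
    selected: dict[str, set[str]] = field(default_factory=dict)

    def tier_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in TIERS}
        for c in self.calls:
            if c.class_label != "NONE" and c.tier:
                counts[c.tier] += 1
        return counts


def apply_filters(
    calls: Sequence[ArchitectureCall],
    hits: Sequence[DomainHit],
    intervals_by_protein: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    tm_by_protein: Mapping[str, Sequence[TMSegment]],
    cc_by_protein: Mapping[str, Sequence[CCSegment]],
    protein_lengths: Mapping[str, int],
    tier_table: TierTable | None = None,
    mlo_selected: set[str] | None = None,
    rlp_selected: set[str] | None = None,
    cterm_margin: int = 75,
) -> FilterResult:
    """Run the whole decision tree: splits, signature filters, tiering.

    *mlo_selected* / *rlp_selected* are the outcomes of the reference-clade
    filters (:func:`clade_select`); when ``None`` the corresponding candidates
    stay at their unfiltered (candidate) subclass and tier.
    """
    if tier_table is None:
        tier_table = TierTable.default_table()
    sigs = signature_select(calls, hits)
    for call in calls:
        pid = call.protein_id
        ivs = intervals_by_protein.get(pid, {})
        cc = cc_by_protein.get(pid, ())
        tm = tm_by_protein.get(pid, ())
        cats = call.categories
        if cats == frozenset({"TIR", "NBS", "LRR"}):
            call.subclass = "TNL"
        elif cats == frozenset({"NBS", "LRR"}):
            call.subclass = split_nbs_lrr(call, cc, ivs)
        elif cats == frozenset({"NBS"}):
            call.subclass = split_nbs(call, cc, ivs)
        elif cats in (frozenset({"LRR"}), frozenset({"LRR", "KIN"})):
            sub = split_receptor(call, tm, protein_lengths[pid], cterm_margin)
            if sub == "RLP":
                if rlp_selected is None:
                    call.subclass = "RLP"
                else:
                    call.subclass = "RLP" if pid in rlp_selected else "RLP-candidate"
            elif sub == "RLK":
                call.subclass = "RLK"
        if pid in sigs["PTO_like"]:
            call.subclass = "PTO-like"
        if pid in sigs["MLO_like_candidates"]:
            if mlo_selected is None:
                call.subclass = "MLO-like"
            else:
                call.subclass = "MLO-like" if pid in mlo_selected else "MLO-like-candidate"
        if pid in sigs["RPW8_like"]:
            call.subclass = "RPW8-like"
        if pid in sigs["RPW8_NBS_LRR"]:
            call.flags.add("ATY_R")
        assign_tier(call, tier_table)
    return FilterResult(calls=list(calls), selected=sigs)
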