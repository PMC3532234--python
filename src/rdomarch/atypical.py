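"""Atypical R-domain associations, transposon insertions, tandem repeats.

An *atypical* association (Aty-R) is a resistance-domain hit co-occurring
with an explicitly named non-resistance signature (WRKY, zinc fingers, Mob1,
TIRAP, phosphatase 2C, ...).  Unannotated regions (UNMAPPED hits) never
produce an Aty-R call.  Transposon-derived candidates carry a hit whose
subrole is in the map's transposon tag list (Gag-Pol by default).  Tandem
repetition of one R category (e.g. a second TIR block at the far end of a
TNL) is detected from the merged disjoint intervals: two or more disjoint
spans of the same category count as copies.  The three flags are independent
and order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .architecture import ArchitectureCall
from .io import CategoryMap, DomainHit, R_CATEGORIES

ATY_R = "ATY_R"
TRANSPOSON = "TRANSPOSON"
DOMAIN_REPEAT = "DOMAIN_REPEAT"


@dataclass
class AtypicalCall:
    protein_id: str
    r_class_label: str
    aty_domains: list[str] = field(default_factory=list)  # non-R signature descriptions
    transposon: bool = False
    repeat_domains: list[tuple[str, int]] = field(default_factory=list)
    species: str | None = None

    @property
    def label(self) -> str:
        """Report label, e.g. ``NBS-AtyR``."""
        if self.aty_domains and self.r_class_label != "NONE":
            return f"{self.r_class_label}-AtyR"
        return self.r_class_label


def detect_transposon(
    hits: Iterable[DomainHit], transposon_subroles: Iterable[str] = ("GAG_POL",)
) -> bool:
    """True iff any hit carries a transposon subrole tag."""
    tags = set(transposon_subroles)
    return any(h.subrole in tags for h in hits)


def detect_repeats(
    intervals_by_cat: Mapping[str, Sequence[tuple[int, int]]]
) -> list[tuple[str, int]]:
    """Categories present as >=2 disjoint merged intervals, with copy counts.

    Input is the per-category merged-interval map of one protein (see
    ``collapse_hits``); touching hits have already been unioned, so each
    disjoint span is a genuine separate copy.
    """
    return [
        (cat, len(ivs))
        for cat in R_CATEGORIES
        if len(ivs := intervals_by_cat.get(cat, [])) >= 2
    ]


def detect_atypical(
    call: ArchitectureCall,
    hits: Sequence[DomainHit],
    intervals_by_cat: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    cmap: CategoryMap | None = None,
) -> AtypicalCall:
    """Full atypical screen of one classified protein; sets flags on *call*.

    ATY_R fires iff at least one R-category hit co-occurs with at least one
    named NONR hit; the description (falling back to the accession) of each
    named non-R signature is reported.
    """
    mine = [h for h in hits if h.protein_id == call.protein_id]
    has_r = any(h.category in R_CATEGORIES for h in mine)
    # dict keyed by description keeps order stable and duplicates collapsed
    named = {
        (h.description or h.signature_id): None
        for h in sorted(mine, key=lambda h: (h.start, h.signature_id))
        if h.category == "NONR"
    }
    aty = list(named) if (has_r and named) else []
    transposon_tags = cmap.transposon_subroles if cmap else ("GAG_POL",)
    transposon = detect_transposon(mine, transposon_tags)
    repeats = detect_repeats(intervals_by_cat or {})
    if aty:
        call.flags.add(ATY_R)
    if transposon:
        call.flags.add(TRANSPOSON)
    if repeats:
        call.flags.add(DOMAIN_REPEAT)
    return AtypicalCall(
        protein_id=call.protein_id,
        r_class_label=call.class_label,
        aty_domains=aty,
        transposon=transposon,
        repeat_domains=repeats,
    )


def atypical_report(atypical_calls: Sequence[AtypicalCall]) -> pd.DataFrame:
    """Tabular Aty-R report: id, resistance class, Aty-R domains, flags."""
    rows = []
    for a in atypical_calls:
        if not (a.aty_domains or a.transposon or a.repeat_domains):
            continue
        rows.append(
            {
                "protein_id": a.protein_id,
                "resistance_class": a.label,
                "aty_domains": "; ".join(a.aty_domains),
                "transposon": a.transposon,
                "repeats": "; ".join(f"{c}x{n}" for c, n in a.repeat_domains),
                "species": a.species or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "resistance_class", "aty_domains", "transposon", "repeats", "species"],
    )
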