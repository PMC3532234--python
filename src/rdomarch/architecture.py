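"""Domain-combination classes and the binomial theoretical model.

A protein carrying any subset of the five macro-categories (TIR, NBS, LRR,
KIN, OthR) belongs to exactly one of the 2^5 - 1 = 31 possible
domain-combination classes.  The theoretical model treats every non-empty
subset as equally available, so the number of k-domain classes is C(n, k) and
their fraction of all classes is C(n, k) / (2^n - 1); comparing this with the
observed class census shows whether domain combinations are random or shaped
by selection (fewer proteins in more complex arrangements).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

#: canonical component order for class labels
CATEGORY_ORDER = ("TIR", "NBS", "LRR", "KIN", "OTHR")
#: printable component names
_DISPLAY = {"TIR": "TIR", "NBS": "NBS", "LRR": "LRR", "KIN": "KIN", "OTHR": "OthR"}
#: common aliases for well-known classes
CLASS_ALIASES = {
    "TIR-NBS-LRR": "TNL",
    "NBS-LRR": "NBS-LRR",  # refined to CNL/NBS-LRR by the coiled-coil split
    "LRR-KIN": "LRR-KIN",  # refined to RLK by the transmembrane split
}


def class_label(categories: Iterable[str]) -> str:
    """Canonical class label: components ordered TIR, NBS, LRR, KIN, OthR.

    The empty set labels as ``"NONE"`` (no mapped macro-category); such
    proteins are excluded from class counts.
    """
    cats = set(categories)
    unknown = cats - set(CATEGORY_ORDER)
    if unknown:
        raise ValueError(f"not macro-categories: {sorted(unknown)}")
    if not cats:
        return "NONE"
    return "-".join(_DISPLAY[c] for c in CATEGORY_ORDER if c in cats)


def all_class_labels(n: int = 5) -> list[str]:
    """The labels of all 2^n - 1 theoretical classes, by ascending k then order."""
    cats = CATEGORY_ORDER[:n]
    labels = []
    for k in range(1, n + 1):
        for combo in combinations(cats, k):
            labels.append(class_label(combo))
    return labels


@dataclass
class ArchitectureCall:
    """A protein's classification: category set, class label, refinements.

    ``k`` counts distinct categories, not domain copies — tandem repeats of a
    category are recorded through the DOMAIN_REPEAT flag, never in the label.
    """

    protein_id: str
    categories: frozenset[str]
    class_label: str = ""
    k: int = 0
    subclass: str | None = None
    tier: str | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.categories = frozenset(self.categories)
        self.class_label = class_label(self.categories)
        self.k = len(self.categories)


def classify_protein(
    protein_id: str, categories: Iterable[str], flags: Iterable[str] = ()
) -> ArchitectureCall:
    """Assign a protein to its domain-combination class.

    Only macro-categories count; NONR/UNMAPPED hits never enter the label, so
    the call is invariant to hit order, multiplicity and coordinates.
    """
    cats = frozenset(c for c in categories if c in CATEGORY_ORDER)
    return ArchitectureCall(protein_id=protein_id, categories=cats, flags=set(flags))


def enumerate_combinations(n: int) -> tuple[int, list[int]]:
    """Total and per-k counts of non-empty category subsets.

    total = sum_{k=1..n} C(n, k) = 2^n - 1.
    """
    if not (1 <= n <= 10):
        raise ValueError("n must be between 1 and 10")
    per_k = [math.comb(n, k) for k in range(1, n + 1)]
    return 2**n - 1, per_k


def theoretical_distribution(n: int) -> dict[int, Fraction]:
    """Fraction of theoretical classes having exactly k domains.

    fraction(k) = C(n, k) / (2^n - 1); fractions sum to 1.  Returned exactly
    (as :class:`fractions.Fraction`) so that rounding is the caller's choice.
    """
    total, per_k = enumerate_combinations(n)
    return {k: Fraction(c, total) for k, c in zip(range(1, n + 1), per_k)}


@dataclass
class CombinationTable:
    """Observed vs theoretical domain-combination census for n categories."""

    n: int
    class_counts: Counter  # observed proteins per class label
    observed_classes: list[str]  # distinct labels seen, census order
    missing_classes: list[str]  # theoretical labels with zero members
    per_k_observed_classes: dict[int, int]
    per_k_observed_proteins: dict[int, int]
    per_k_theoretical_classes: dict[int, int]

    @property
    def n_classified(self) -> int:
        return sum(self.class_counts.values())

    def to_frame(self):
        """Tabular form: one row per theoretical class."""
        import pandas as pd

        rows = []
        for label in all_class_labels(self.n):
            k = label.count("-") + 1
            rows.append(
                {
                    "class_label": label,
                    "k": k,
                    "observed_count": self.class_counts.get(label, 0),
                    "observed": label in set(self.observed_classes),
                }
            )
        return pd.DataFrame(rows)


def observed_distribution(calls: Sequence[ArchitectureCall], n: int = 5) -> CombinationTable:
    """Census of observed classes against the 2^n - 1 theoretical ones.

    Proteins with an empty category set (label ``NONE``) are excluded.
    """
    counts: Counter = Counter(c.class_label for c in calls if c.class_label != "NONE")
    theory = all_class_labels(n)
    observed = [lab for lab in theory if lab in counts]
    missing = [lab for lab in theory if lab not in counts]
    _, per_k_theory = enumerate_combinations(n)
    per_k_obs_classes: dict[int, int] = {k: 0 for k in range(1, n + 1)}
    per_k_obs_prot: dict[int, int] = {k: 0 for k in range(1, n + 1)}
    for lab, cnt in counts.items():
        k = lab.count("-") + 1
        per_k_obs_classes[k] += 1
        per_k_obs_prot[k] += cnt
    return CombinationTable(
        n=n,
        class_counts=counts,
        observed_classes=observed,
        missing_classes=missing,
        per_k_observed_classes=per_k_obs_classes,
        per_k_observed_proteins=per_k_obs_prot,
        per_k_theoretical_classes={k: c for k, c in zip(range(1, n + 1), per_k_theory)},
    )


def domain_occurrence(
    calls: Sequence[ArchitectureCall],
) -> tuple[dict[str, int], dict[frozenset, int]]:
    """Per category: in how many distinct observed classes does it occur.

    Also returns pairwise co-occurrence counts (number of observed classes
    containing both categories of each pair), which reveal preferential
    associations such as LRR-NBS and LRR-KIN.
    """
    observed_sets = {c.categories for c in calls if c.categories}
    occ = {cat: sum(1 for s in observed_sets if cat in s) for cat in CATEGORY_ORDER}
    pairs: dict[frozenset, int] = {}
    for a, b in combinations(CATEGORY_ORDER, 2):
        pairs[frozenset((a, b))] = sum(1 for s in observed_sets if a in s and b in s)
    return occ, pairs


def truncate_pct(numerator: float, denominator: float) -> str:
    """Percentage formatted by one-decimal truncation.

    10.98 -> "10.9%", 56.25 -> "56.2%"; integer percentages drop the decimal
    ("100%", "9%").  Integer inputs are handled exactly (no float rounding).
    """
    if denominator == 0:
        raise ZeroDivisionError("empty class")
    if float(numerator).is_integer() and float(denominator).is_integer():
        tenths = (1000 * int(numerator)) // int(denominator)
    else:
        tenths = math.floor(1000.0 * numerator / denominator + 1e-9)
    whole, frac = divmod(tenths, 10)
    return f"{whole}%" if frac == 0 else f"{whole}.{frac}%"
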