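"""Reading sequences and domain annotations; signature -> category mapping.

Proteins arrive as amino-acid FASTA; domain annotations arrive in the
InterProScan tab-separated dialect (protein id, member database, signature
accession, start, end, description).  Raw signature accessions are mapped to
the five macro-categories used throughout the analysis — LRR, NBS, TIR, KIN
and OthR — via a :class:`CategoryMap`; signatures outside the map fall back to
``UNMAPPED`` so that unannotated regions never create a resistance class by
accident, while explicitly named non-resistance signatures (WRKY, Mob1,
retrotransposon Gag-Pol, ...) map to ``NONR`` and feed the atypical-association
detector.

Coordinates are 1-based inclusive throughout, the InterProScan convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

#: the five macro-categories that define a resistance-protein class ...
R_CATEGORIES = ("TIR", "NBS", "LRR", "KIN", "OTHR")
#: ... plus the two non-class bins
ALL_CATEGORIES = R_CATEGORIES + ("NONR", "UNMAPPED")


class AnnotationError(ValueError):
    """Malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with a unique id and optional species tag."""

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise AnnotationError("protein id must be non-empty")
        seq = self.sequence.upper().rstrip("*")
        if not seq:
            raise AnnotationError(f"{self.id}: empty sequence")
        if "*" in seq:
            raise AnnotationError(f"{self.id}: internal stop codon '*'")
        bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise AnnotationError(f"{self.id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One signature match on one protein, with its mapped macro-category.

    ``category`` is assigned only through an explicit :class:`CategoryMap`
    entry; anything else is ``UNMAPPED``.  ``subrole`` carries the finer tag
    (MLO_LIKE, RPW8, PTO_LIKE, WRKY, GAG_POL, generic, ...) used by the
    signature filters and the atypical-association detector.
    """

    protein_id: str
    signature_id: str
    database: str
    start: int
    end: int
    description: str = ""
    category: str = "UNMAPPED"
    subrole: str = "generic"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.protein_id}/{self.signature_id}: bad coordinates "
                f"({self.start}, {self.end}); need 1 <= start <= end"
            )
        if self.category not in ALL_CATEGORIES:
            raise AnnotationError(f"unknown category {self.category!r}")


class CategoryMap:
    """Deterministic signature -> (category, subrole) lookup.

    Exact-accession entries take precedence over prefix entries; unknown
    signatures resolve to ``("UNMAPPED", "generic")``.
    """

    def __init__(
        self,
        exact: Mapping[str, tuple[str, str]],
        prefix: Mapping[str, tuple[str, str]] | None = None,
        transposon_subroles: Iterable[str] = ("GAG_POL",),
    ) -> None:
        self._exact = dict(exact)
        # longest prefix wins so that finer PANTHER subfamily rules beat family rules
        self._prefix = sorted((prefix or {}).items(), key=lambda kv: -len(kv[0]))
        self.transposon_subroles = frozenset(transposon_subroles)
        for cat, _ in list(self._exact.values()) + [v for _, v in self._prefix]:
            if cat not in ALL_CATEGORIES:
                raise AnnotationError(f"category map names unknown category {cat!r}")

    def resolve(self, signature_id: str) -> tuple[str, str]:
        hit = self._exact.get(signature_id)
        if hit is not None:
            return hit
        for pfx, val in self._prefix:
            if signature_id.startswith(pfx):
                return val
        return ("UNMAPPED", "generic")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: Mapping) -> "CategoryMap":
        def block(name: str) -> dict[str, tuple[str, str]]:
            out = {}
            for sig, ent in (raw.get(name) or {}).items():
                out[str(sig)] = (ent["category"], ent.get("subrole", "generic"))
            return out

        return cls(
            exact=block("exact"),
            prefix=block("prefix"),
            transposon_subroles=raw.get("transposon_subroles", ["GAG_POL"]),
        )

    @classmethod
    def default(cls) -> "CategoryMap":
        ref = importlib.resources.files("rdomarch.data") / "category_map.yaml"
        return cls._from_dict(yaml.safe_load(ref.read_text()))


def read_fasta(path: str | Path, species: str | None = None) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and a single terminal ``'*'`` is stripped;
    duplicate ids raise :class:`AnnotationError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AnnotationError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), species=species))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def filter_met_start(proteins: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Keep only proteins whose first residue is methionine (order preserved).

    Mirrors the selection of properly initiated translations from a translated
    transcript set; idempotent.
    """
    return [p for p in proteins if p.sequence.startswith("M")]


def read_interproscan_tsv(path: str | Path, cmap: CategoryMap) -> list[DomainHit]:
    """Read domain hits from an InterProScan-style TSV.

    Accepts either the minimal 5/6-column layout ``(protein id, database,
    signature accession, start, end[, description])`` or the official 11+
    column layout, recognised by column count and indexed positionally
    (columns 1, 4, 5, 7, 8 and the description in column 6).  Row order is
    preserved; categories are resolved through *cmap*.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 9:  # official layout: md5 + length occupy cols 2-3
                pid, db, sig = cols[0], cols[3], cols[4]
                desc, s_raw, e_raw = cols[5], cols[6], cols[7]
            elif len(cols) >= 5:
                pid, db, sig, s_raw, e_raw = cols[:5]
                desc = cols[5] if len(cols) > 5 else ""
            else:
                raise AnnotationError(f"{path}:{lineno}: expected >=5 tab-separated columns")
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            category, subrole = cmap.resolve(sig)
            try:
                hits.append(
                    DomainHit(
                        protein_id=pid, signature_id=sig, database=db,
                        start=start, end=end, description=desc,
                        category=category, subrole=subrole,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return hits


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; overlapping or bookended
    (end + 1 == next start) intervals are merged."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def collapse_hits(hits: Iterable[DomainHit]) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Per protein and per category, merge hit intervals into disjoint spans.

    Multiple member databases report overlapping matches for the same region;
    downstream steps only need category presence and merged spans.  Output
    intervals within one category are pairwise disjoint and non-bookended.
    """
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in hits:
        raw.setdefault(h.protein_id, {}).setdefault(h.category, []).append((h.start, h.end))
    return {
        pid: {cat: merge_intervals(ivs) for cat, ivs in cats.items()}
        for pid, cats in raw.items()
    }
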