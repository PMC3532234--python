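"""Sequence/annotation ingestion, category mapping, interval collapsing."""

import numpy as np
import pytest

from rdomarch.io import (
    AnnotationError,
    CategoryMap,
    DomainHit,
    ProteinRecord,
    collapse_hits,
    filter_met_start,
    merge_intervals,
    read_fasta,
    read_interproscan_tsv,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">p1\nMKL\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [("p1", "MKL")]

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_fasta(_write(tmp_path, "e.fasta", "")) == []

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "d.fasta", ">p1\nMKL\n>p1\nMAA\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            read_fasta(p)

    def test_lowercase_and_terminal_stop_normalised(self, tmp_path):
        recs = read_fasta(_write(tmp_path, "n.fasta", ">p1\nmkl*\n"))
        assert recs[0].sequence == "MKL"

    def test_internal_stop_rejected(self):
        with pytest.raises(AnnotationError, match="internal stop"):
            ProteinRecord(id="p1", sequence="MK*L")


class TestFilterMetStart:
    def test_keeps_only_met_start_preserving_order(self):
        prots = [ProteinRecord("a", "MKL"), ProteinRecord("b", "AKL"),
                 ProteinRecord("c", "MAA")]
        assert [p.id for p in filter_met_start(prots)] == ["a", "c"]

    def test_identity_when_all_start_with_met(self):
        prots = [ProteinRecord("a", "MKL"), ProteinRecord("b", "MAA")]
        assert filter_met_start(prots) == prots

    def test_idempotent(self):
        prots = [ProteinRecord("a", "MKL"), ProteinRecord("b", "AKL")]
        once = filter_met_start(prots)
        assert filter_met_start(once) == once

    def test_empty(self):
        assert filter_met_start([]) == []


class TestCategoryMap:
    def test_named_accessions_resolve(self, cmap):
        assert cmap.resolve("PF03094") == ("OTHR", "MLO_LIKE")
        assert cmap.resolve("PF05659") == ("OTHR", "RPW8")
        assert cmap.resolve("PTHR24420:SF785") == ("KIN", "PTO_LIKE")
        assert cmap.resolve("PTHR23258:SF418") == ("KIN", "PTO_LIKE")

    def test_unknown_maps_to_unmapped(self, cmap):
        assert cmap.resolve("PF99999") == ("UNMAPPED", "generic")

    def test_exact_beats_prefix(self):
        cm = CategoryMap(exact={"PF1": ("NBS", "generic")}, prefix={"PF": ("LRR", "generic")})
        assert cm.resolve("PF1") == ("NBS", "generic")
        assert cm.resolve("PF2") == ("LRR", "generic")

    def test_resolution_is_pure(self, cmap, rng):
        sigs = ["PF03094", "PF99999", "PTHR23155:SF9", "PF00931"]
        for sig in sigs:
            first = cmap.resolve(sig)
            assert all(cmap.resolve(sig) == first for _ in range(5))


class TestReadInterproscanTsv:
    def test_minimal_layout_with_mapping(self, tmp_path, cmap):
        p = _write(tmp_path, "h.tsv", "p1\tPfam\tPF03094\t10\t300\tMlo family\n")
        (hit,) = read_interproscan_tsv(p, cmap)
        assert (hit.category, hit.subrole, hit.start, hit.end) == ("OTHR", "MLO_LIKE", 10, 300)

    def test_official_11_column_layout(self, tmp_path, cmap):
        row = "\t".join(
            ["p1", "md5", "321", "Pfam", "PF00931", "NB-ARC", "5", "150",
             "1e-30", "T", "01-01-2012"]
        )
        (hit,) = read_interproscan_tsv(_write(tmp_path, "o.tsv", row + "\n"), cmap)
        assert (hit.category, hit.start, hit.end, hit.description) == ("NBS", 5, 150, "NB-ARC")

    def test_unmapped_accession_defaults(self, tmp_path, cmap):
        (hit,) = read_interproscan_tsv(
            _write(tmp_path, "u.tsv", "p1\tPfam\tPF99999\t1\t10\n"), cmap
        )
        assert hit.category == "UNMAPPED"

    def test_reversed_coordinates_rejected(self, tmp_path, cmap):
        p = _write(tmp_path, "b.tsv", "p1\tPfam\tPF00001\t50\t40\n")
        with pytest.raises(AnnotationError, match="coordinates"):
            read_interproscan_tsv(p, cmap)

    def test_non_integer_coordinates_rejected(self, tmp_path, cmap):
        p = _write(tmp_path, "n.tsv", "p1\tPfam\tPF00001\tx\t40\n")
        with pytest.raises(AnnotationError, match="non-integer"):
            read_interproscan_tsv(p, cmap)

    def test_row_order_preserved(self, tmp_path, cmap):
        p = _write(
            tmp_path, "r.tsv",
            "p1\tPfam\tPF00931\t200\t300\n" "p1\tPfam\tPF01582\t1\t100\n",
        )
        hits = read_interproscan_tsv(p, cmap)
        assert [h.signature_id for h in hits] == ["PF00931", "PF01582"]


def _hit(pid, cat, start, end):
    return DomainHit(protein_id=pid, signature_id="S", database="D",
                     start=start, end=end, category=cat)


class TestCollapseHits:
    def test_overlapping_merged(self):
        out = collapse_hits([_hit("p", "NBS", 10, 100), _hit("p", "NBS", 90, 150)])
        assert out["p"]["NBS"] == [(10, 150)]

    def test_categories_kept_separate(self):
        out = collapse_hits([_hit("p", "NBS", 10, 100), _hit("p", "LRR", 200, 300)])
        assert out["p"] == {"NBS": [(10, 100)], "LRR": [(200, 300)]}

    def test_three_mutually_overlapping_span_min_to_max(self):
        hits = [_hit("p", "LRR", 10, 60), _hit("p", "LRR", 40, 120), _hit("p", "LRR", 50, 90)]
        assert collapse_hits(hits)["p"]["LRR"] == [(10, 120)]

    def test_bookended_intervals_merge(self):
        assert merge_intervals([(1, 10), (11, 20)]) == [(1, 20)]
        assert merge_intervals([(1, 10), (12, 20)]) == [(1, 10), (12, 20)]

    def test_matches_residue_bitmap_oracle_on_random_instances(self, rng):
        """Merged intervals are disjoint and cover exactly the input residues."""
        for _ in range(50):
            n = int(rng.integers(1, 12))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(1, 200))
                e = s + int(rng.integers(0, 40))
                ivs.append((s, e))
            merged = merge_intervals(ivs)
            # brute-force residue bitmap
            covered = set()
            for s, e in ivs:
                covered.update(range(s, e + 1))
            merged_residues = set()
            prev_end = None
            for s, e in merged:
                assert s <= e
                if prev_end is not None:
                    assert s > prev_end + 1  # disjoint, not even bookended
                prev_end = e
                merged_residues.update(range(s, e + 1))
            assert merged_residues == covered
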