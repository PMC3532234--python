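"""End-to-end orchestration: annotate -> classify -> features -> filter ->
atypical -> report.

Writes plain TSV/JSON artifacts: the domain-combination table, the per-class
transmembrane summary, the candidate-tier table, the five-set Venn region
counts and the atypical-association report, plus a stage log that makes the
filtration funnel (input -> methionine-start -> classified -> tiered)
auditable for any dataset.  Re-running with the same config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import atypical as atypical_mod
from . import filtering
from .architecture import (
    ArchitectureCall,
    all_class_labels,
    classify_protein,
    observed_distribution,
)
from .features import predict_cc, predict_tm, read_segments_tsv, tm_summary
from .io import CategoryMap, collapse_hits, filter_met_start, read_fasta, read_interproscan_tsv

logger = logging.getLogger("rdomarch")


class ConfigError(ValueError):
    """Invalid run configuration (missing paths, bad parameters)."""


@dataclass
class RunConfig:
    fasta: str | Path
    interproscan_tsv: str | Path
    outdir: str | Path
    category_map: str | Path | None = None  # None -> packaged default
    tier_table: str | Path | None = None  # None -> packaged default
    segments_tsv: str | Path | None = None  # external TM/CC predictions
    # reference-clade filters: a newick tree over candidate + reference taxa
    # and a text file of reference taxon ids (one per line)
    mlo_tree: str | Path | None = None
    mlo_references: str | Path | None = None
    rlp_tree: str | Path | None = None
    rlp_references: str | Path | None = None
    tm_window: int = 19
    tm_threshold: float = 1.6
    cc_window: int = 28
    cc_cutoff: float = 0.5
    cterm_margin: int = 75
    require_met_start: bool = True
    seed: int = 42

    def validate(self) -> None:
        for name in ("fasta", "interproscan_tsv", "category_map", "tier_table",
                     "segments_tsv", "mlo_tree", "mlo_references", "rlp_tree",
                     "rlp_references"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for kind in ("mlo", "rlp"):
            if (getattr(self, f"{kind}_tree") is None) != (
                getattr(self, f"{kind}_references") is None
            ):
                raise ConfigError(f"{kind} clade filter needs both a tree and references")


@dataclass
class ReportBundle:
    calls: list[ArchitectureCall]
    combination_table: pd.DataFrame
    tm_table: pd.DataFrame
    tier_table: pd.DataFrame
    venn: dict[str, int]
    atypical: pd.DataFrame
    stage_counts: dict[str, int]
    outdir: Path | None = None


def venn_counts(calls: Sequence[ArchitectureCall], n: int = 5) -> dict[str, int]:
    """Counts for all 2^n - 1 regions of the n-set diagram (zeros included)."""
    table = observed_distribution(calls, n=n)
    return {label: int(table.class_counts.get(label, 0)) for label in all_class_labels(n)}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the whole analysis; see module docstring for the stage order."""
    config.validate()
    cmap = (
        CategoryMap.from_yaml(config.category_map)
        if config.category_map
        else CategoryMap.default()
    )
    tier_table = (
        filtering.TierTable.from_yaml(config.tier_table)
        if config.tier_table
        else filtering.TierTable.default_table()
    )
    stage_counts: dict[str, int] = {}

    proteins = read_fasta(config.fasta)
    stage_counts["input_proteins"] = len(proteins)
    if config.require_met_start:
        proteins = filter_met_start(proteins)
    stage_counts["met_start"] = len(proteins)
    if not proteins:
        logger.warning("no proteins after the methionine-start filter; reports will be empty")

    hits = read_interproscan_tsv(config.interproscan_tsv, cmap)
    known = {p.id for p in proteins}
    hits = [h for h in hits if h.protein_id in known]
    stage_counts["domain_hits"] = len(hits)
    collapsed = collapse_hits(hits)

    calls = [
        classify_protein(p.id, collapsed.get(p.id, {}).keys()) for p in proteins
    ]
    stage_counts["classified"] = sum(1 for c in calls if c.class_label != "NONE")

    if config.segments_tsv:
        segs = read_segments_tsv(config.segments_tsv)
        tm_by_protein = {pid: s["TM"] for pid, s in segs.items()}
        cc_by_protein = {pid: s["CC"] for pid, s in segs.items()}
    else:
        tm_by_protein = {
            p.id: predict_tm(p, window=config.tm_window, threshold=config.tm_threshold)
            for p in proteins
        }
        cc_by_protein = {
            p.id: predict_cc(p, window=config.cc_window, cutoff=config.cc_cutoff)
            for p in proteins
        }
    lengths = {p.id: len(p) for p in proteins}

    def _clade_selection(tree_path, ref_path):
        if tree_path is None:
            return None
        import skbio

        # keep taxon ids verbatim (newick readers turn '_' into spaces by default)
        tree = skbio.TreeNode.read(str(tree_path), convert_underscores=False)
        refs = [ln.strip() for ln in Path(ref_path).read_text().splitlines() if ln.strip()]
        return filtering.clade_select(tree, refs)

    result = filtering.apply_filters(
        calls, hits, collapsed, tm_by_protein, cc_by_protein, lengths,
        tier_table=tier_table, cterm_margin=config.cterm_margin,
        mlo_selected=_clade_selection(config.mlo_tree, config.mlo_references),
        rlp_selected=_clade_selection(config.rlp_tree, config.rlp_references),
    )
    stage_counts["tiered"] = sum(1 for c in calls if c.tier)

    aty_calls = [
        atypical_mod.detect_atypical(c, hits, collapsed.get(c.protein_id, {}), cmap)
        for c in calls
    ]

    combo = observed_distribution(calls).to_frame()
    tm_table = tm_summary(calls, tm_by_protein)
    tiers = pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "class_label": c.class_label,
                "k": c.k,
                "subclass": c.subclass or "",
                "tier": c.tier or "",
                "flags": ",".join(sorted(c.flags)),
            }
            for c in calls
        ]
    )
    bundle = ReportBundle(
        calls=calls,
        combination_table=combo,
        tm_table=tm_table,
        tier_table=tiers,
        venn=venn_counts(calls),
        atypical=atypical_mod.atypical_report(aty_calls),
        stage_counts=stage_counts,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combo.to_csv(outdir / "combination_table.tsv", sep="\t", index=False)
    tm_table.to_csv(outdir / "tm_summary.tsv", sep="\t", index=False)
    tiers.to_csv(outdir / "tiers.tsv", sep="\t", index=False)
    bundle.atypical.to_csv(outdir / "atypical.tsv", sep="\t", index=False)
    with open(outdir / "venn_counts.json", "w") as fh:
        json.dump(bundle.venn, fh, indent=2, sort_keys=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(stage_counts, fh, indent=2)
    bundle.outdir = outdir
    for stage, count in stage_counts.items():
        logger.info("%s: %d", stage, count)
    return bundle
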