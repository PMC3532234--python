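"""Simplified transmembrane and coiled-coil predictors, plus the TM summary.

Desk-scale, deterministic stand-ins for HMM-based membrane-topology tools:

* transmembrane segments — Kyte-Doolittle sliding-window hydropathy (window
  19, mean >= 1.6), qualifying windows merged into maximal segments.  A
  genuine TM helix is ~19-23 strongly hydrophobic residues, which this scheme
  recovers reliably; marginal amphipathic helices it will miss.
* coiled-coils — heptad-register scoring (window 28 = four heptads): for the
  best of the 7 registers, the score is the fraction of a/d core slots holding
  a hydrophobic residue {L,I,V,M,A,F} minus half the fraction of hydrophobic
  e/g slots (a charged-face penalty), clipped to [0, 1].

Externally computed segments (Phobius/TMHMM/…) can be ingested from a TSV
instead via :func:`read_segments_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import ArchitectureCall, truncate_pct
from .io import ProteinRecord

#: Kyte-Doolittle hydropathy scale; 'X' treated as neutral (0).
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

HYDROPHOBIC_CC = frozenset("LIVMAF")

N_TERMINAL = "N_TERMINAL"
INTERNAL = "INTERNAL"
C_TERMINAL = "C_TERMINAL"


@dataclass(frozen=True)
class TMSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float


@dataclass(frozen=True)
class CCSegment:
    start: int
    end: int
    score: float  # heptad-periodicity score in [0, 1]


def _mark_to_segments(marked: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean residue mask, as 1-based intervals."""
    segs = []
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return segs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        segs.append((int(idx[s]) + 1, int(idx[e]) + 1))
    return segs


def predict_tm(
    protein: ProteinRecord, window: int = 19, threshold: float = 1.6
) -> list[TMSegment]:
    """Predict transmembrane segments by windowed mean hydropathy.

    Every window of *window* residues whose Kyte-Doolittle mean is at least
    *threshold* marks all its residues; maximal marked runs become segments
    (hence each segment is at least *window* long).  Sequences shorter than
    the window yield no segments.
    """
    seq = protein.sequence
    if len(seq) < window:
        return []
    kd = np.array([KD_SCALE[a] for a in seq])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    marked = np.zeros(len(seq), dtype=bool)
    for i in np.flatnonzero(means >= threshold):
        marked[i : i + window] = True
    return [
        TMSegment(start=s, end=e, mean_hydropathy=float(kd[s - 1 : e].mean()))
        for s, e in _mark_to_segments(marked)
    ]


def classify_tm_position(
    segment: TMSegment, protein_length: int, cterm_margin: int = 75
) -> str:
    """Locate a TM segment: N_TERMINAL, INTERNAL or C_TERMINAL.

    C-terminal iff the segment ends within *cterm_margin* residues of the
    protein end; N-terminal iff it starts within the same margin of the start;
    C-terminal wins when both apply (tiny proteins).  The margin default
    reflects the short cytoplasmic tail of receptor-like proteins.
    """
    if segment.end >= protein_length - cterm_margin + 1:
        return C_TERMINAL
    if segment.start <= cterm_margin:
        return N_TERMINAL
    return INTERNAL


def _window_cc_score(sub: str) -> float:
    """Best-register heptad score of one window."""
    best = 0.0
    n = len(sub)
    for reg in range(7):
        ad = eg = ad_hyd = eg_hyd = 0
        for i, aa in enumerate(sub):
            pos = (i + reg) % 7
            if pos in (0, 3):  # a/d core slots
                ad += 1
                ad_hyd += aa in HYDROPHOBIC_CC
            elif pos in (4, 6):  # e/g flank slots
                eg += 1
                eg_hyd += aa in HYDROPHOBIC_CC
        score = ad_hyd / ad - 0.5 * (eg_hyd / eg if eg else 0.0)
        best = max(best, min(1.0, max(0.0, score)))
    return best


def predict_cc(
    protein: ProteinRecord, window: int = 28, cutoff: float = 0.5
) -> list[CCSegment]:
    """Predict coiled-coil segments by heptad-register fit.

    Windows scoring at least *cutoff* are merged; a merged segment's score is
    the maximum of its qualifying windows.
    """
    seq = protein.sequence
    if len(seq) < window:
        return []
    scores = np.array([_window_cc_score(seq[i : i + window]) for i in range(len(seq) - window + 1)])
    marked = np.zeros(len(seq), dtype=bool)
    qualifying = np.flatnonzero(scores >= cutoff)
    for i in qualifying:
        marked[i : i + window] = True
    segments = []
    for s, e in _mark_to_segments(marked):
        in_seg = [scores[i] for i in qualifying if s - 1 <= i and i + window <= e]
        segments.append(CCSegment(start=s, end=e, score=float(max(in_seg))))
    return segments


def read_segments_tsv(path: str | Path) -> dict[str, dict[str, list]]:
    """Ingest externally predicted segments: TSV (protein_id, start, end, kind).

    kind is TM or CC; returns {protein_id: {"TM": [TMSegment...], "CC": [...]}}.
    """
    out: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, s, e, kind = line.split("\t")[:4]
            slot = out.setdefault(pid, {"TM": [], "CC": []})
            if kind == "TM":
                slot["TM"].append(TMSegment(int(s), int(e), float("nan")))
            elif kind == "CC":
                slot["CC"].append(CCSegment(int(s), int(e), 1.0))
            else:
                raise ValueError(f"unknown segment kind {kind!r}")
    return out


def tm_summary(
    calls: Sequence[ArchitectureCall],
    tm_by_protein: Mapping[str, Sequence[TMSegment]],
    label: str = "class",
) -> pd.DataFrame:
    """Per-class transmembrane summary table.

    For each class (by subclass when set, else class label): number of
    proteins with >=1 TM segment, that number as a percentage of class size
    under the one-decimal truncation rule, and the 1 / 2 / more-than-2 segment
    breakdown.  Classes with zero members are omitted by construction.
    """
    rows: dict[str, dict] = {}
    for call in calls:
        if call.class_label == "NONE":
            continue
        key = call.subclass or call.class_label
        row = rows.setdefault(
            key, {label: key, "class_size": 0, "n_tm": 0, "tm_1": 0, "tm_2": 0, "tm_more": 0}
        )
        row["class_size"] += 1
        nseg = len(tm_by_protein.get(call.protein_id, ()))
        if nseg >= 1:
            row["n_tm"] += 1
            if nseg == 1:
                row["tm_1"] += 1
            elif nseg == 2:
                row["tm_2"] += 1
            else:
                row["tm_more"] += 1
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return pd.DataFrame(
            columns=[label, "class_size", "n_tm", "pct_tm", "tm_1", "tm_2", "tm_more"]
        )
    df["pct_tm"] = [
        truncate_pct(n, d) for n, d in zip(df["n_tm"], df["class_size"])
    ]
    return df[[label, "class_size", "n_tm", "pct_tm", "tm_1", "tm_2", "tm_more"]]
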