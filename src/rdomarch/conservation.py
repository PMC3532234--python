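"""Per-class alignment statistics, conservation profiles and the batch ANOVA.

Definitions (alignment-viewer conventions; see docs/methods.md):

* identity — 100 x mean over all sequence pairs of (matches / compared
  columns), where columns with a gap in either member of the pair are
  excluded per pair, and 'X' matches nothing.
* identical sites — 100 x (columns where every sequence carries the same
  residue and none carries a gap) / alignment length.
* per-column conservation — frequency of the modal residue among non-gap
  entries, scaled by the non-gap fraction of the column (so a half-gapped
  unanimous column scores 0.5).

The batch ANOVA asks whether class identity is an artefact of how many
sequences are aligned: identities of seeded random batches are compared with
the full-class value (one-sample comparison) and with each other (one-way F
across batches on per-pair identities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats


@dataclass
class AlignmentBlock:
    """One class's multiple alignment: equal-length gapped sequences."""

    class_name: str
    sequences: list[tuple[str, str]]  # (id, aligned string over residues + '-')

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"{self.class_name}: need >=2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.class_name}: unequal aligned lengths {sorted(lengths)}")

    @property
    def aligned_length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for _, s in self.sequences])

    def mask_gappy_columns(self, max_gap_fraction: float) -> "AlignmentBlock":
        """Drop columns with more than *max_gap_fraction* gaps (a stand-in for
        manual removal of unaligned regions)."""
        arr = self.to_array()
        keep = (arr == "-").mean(axis=0) <= max_gap_fraction
        return AlignmentBlock(
            class_name=self.class_name,
            sequences=[(sid, "".join(np.array(list(s))[keep])) for sid, s in self.sequences],
        )

    @classmethod
    def from_fasta(cls, path: str | Path, class_name: str | None = None) -> "AlignmentBlock":
        seqs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls(class_name=class_name or Path(path).stem, sequences=seqs)


def _pair_identity(a: np.ndarray, b: np.ndarray) -> float | None:
    """Percent identity of one aligned pair; None if no comparable columns."""
    ok = (a != "-") & (b != "-")
    m = int(ok.sum())
    if m == 0:
        return None
    matches = int(((a == b) & (a != "X") & ok).sum())
    return 100.0 * matches / m


def pairwise_identities(block: AlignmentBlock) -> list[float]:
    """Percent identities of all sequence pairs (incomparable pairs dropped
    with a warning)."""
    arr = block.to_array()
    vals: list[float] = []
    for i, j in combinations(range(block.n_sequences), 2):
        v = _pair_identity(arr[i], arr[j])
        if v is None:
            warnings.warn(
                f"{block.class_name}: pair ({block.sequences[i][0]}, "
                f"{block.sequences[j][0]}) has no comparable columns; excluded",
                stacklevel=2,
            )
        else:
            vals.append(v)
    if not vals:
        raise ValueError(f"{block.class_name}: no comparable sequence pairs")
    return vals


def identity_stats(block: AlignmentBlock) -> tuple[float, float]:
    """(identity %, identical-sites %) of one class alignment."""
    identity = float(np.mean(pairwise_identities(block)))
    arr = block.to_array()
    gapless = ~(arr == "-").any(axis=0)
    unanimous = (arr == arr[0]).all(axis=0) & (arr[0] != "X")
    identical = 100.0 * float((gapless & unanimous).sum()) / block.aligned_length
    return identity, identical


@dataclass
class ConservationProfile:
    class_name: str
    values: np.ndarray  # per-column conservation in [0, 1]
    consensus: str  # modal residue per column, '-' where gap is modal
    identity_pct: float
    identical_sites_pct: float


def conservation_profile(block: AlignmentBlock) -> ConservationProfile:
    """Per-column conservation and consensus of a class alignment.

    conservation(col) = freq of modal residue among non-gap entries x non-gap
    fraction; residue ties break alphabetically; the consensus shows '-' when
    gaps outnumber every residue.
    """
    arr = block.to_array()
    n = block.n_sequences
    values = np.zeros(block.aligned_length)
    consensus = []
    for c in range(block.aligned_length):
        col = arr[:, c]
        residues, counts = np.unique(col[col != "-"], return_counts=True)
        n_nongap = int((col != "-").sum())
        if n_nongap == 0:
            consensus.append("-")
            continue
        order = np.lexsort((residues, -counts))  # max count, then alphabetical
        top = order[0]
        values[c] = (counts[top] / n_nongap) * (n_nongap / n)
        n_gap = n - n_nongap
        consensus.append("-" if n_gap > counts[top] else str(residues[top]))
    identity, identical = identity_stats(block)
    return ConservationProfile(
        class_name=block.class_name,
        values=values,
        consensus="".join(consensus),
        identity_pct=identity,
        identical_sites_pct=identical,
    )


def one_way_f(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Plain one-way ANOVA (F = MS_between / MS_within) over value groups.

    The degenerate all-constant input (zero variance between and within) is
    reported as F = 0, p = 1 rather than scipy's nan.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", getattr(stats, "ConstantInputWarning", UserWarning))
        res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    class_name: str
    full_identity: float
    batch_identities: list[float]
    f_statistic: float  # one-way F across batches (per-pair identities)
    f_pvalue: float
    t_statistic: float  # one-sample comparison of batch identities vs full value
    t_pvalue: float
    rejected_05: bool
    rejected_01: bool


def subsample_anova(
    blocks_by_class: Mapping[str, AlignmentBlock],
    batch_size: int = 10,
    n_batches: int = 10,
    seed: int = 0,
) -> dict[str, AnovaResult]:
    """Batch-stability test of class identity.

    For each class, *n_batches* random batches of *batch_size* sequences are
    drawn (disjoint when the class is large enough, otherwise independent
    without-replacement draws); each batch's identity is compared with the
    full-class identity.  The across-batch one-way F drives the rejection
    flags (a rejection would mean identity depends on which and how many
    sequences are aligned); its groups hold identities of disjoint sequence
    pairs only, because pairs sharing a sequence are correlated and would
    invalidate the ANOVA.  A one-sample comparison of batch identities to the
    full-class value is also reported (it is conservative: the full value is
    computed from the same data).  Classes smaller than *batch_size* are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, AnovaResult] = {}
    for name in sorted(blocks_by_class):
        block = blocks_by_class[name]
        n = block.n_sequences
        if n < batch_size:
            warnings.warn(f"{name}: fewer than {batch_size} sequences; skipped", stacklevel=2)
            continue
        if n >= batch_size * n_batches:
            perm = rng.permutation(n)
            batches = [perm[b * batch_size : (b + 1) * batch_size] for b in range(n_batches)]
        else:
            batches = [
                rng.choice(n, size=batch_size, replace=False) for _ in range(n_batches)
            ]
        full_identity, _ = identity_stats(block)
        arr = block.to_array()
        batch_ids: list[float] = []
        batch_pair_groups: list[list[float]] = []
        for idx in batches:
            sub = AlignmentBlock(
                class_name=f"{name}#batch", sequences=[block.sequences[i] for i in idx]
            )
            batch_ids.append(float(np.mean(pairwise_identities(sub))))
            # F groups use disjoint pairs only (no shared sequences) so the
            # one-way ANOVA independence assumption actually holds
            group = []
            for a, b in zip(idx[0::2], idx[1::2]):
                v = _pair_identity(arr[a], arr[b])
                if v is not None:
                    group.append(v)
            batch_pair_groups.append(group)
        f_stat, f_p = one_way_f(batch_pair_groups)
        if np.allclose(batch_ids, batch_ids[0]):
            # zero batch variance: degenerate one-sample comparison
            t_stat = 0.0
            t_p = 1.0 if np.isclose(batch_ids[0], full_identity) else 0.0
        else:
            t_res = stats.ttest_1samp(batch_ids, popmean=full_identity)
            t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        out[name] = AnovaResult(
            class_name=name,
            full_identity=full_identity,
            batch_identities=batch_ids,
            f_statistic=f_stat,
            f_pvalue=f_p,
            t_statistic=t_stat,
            t_pvalue=t_p,
            rejected_05=bool(f_p < 0.05),
            rejected_01=bool(f_p < 0.01),
        )
    return out
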