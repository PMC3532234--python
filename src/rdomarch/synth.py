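"""Ground-truthed synthetic protein datasets with planted domain architectures.

Each simulated protein starts with methionine and concatenates hydrophilic
linkers with category-specific blocks:

* LRR — leucine-patterned 24-residue repeats (an LxxLxLxx-style template);
* NBS / TIR / KIN / OthR — blocks drawn from a Dirichlet-perturbed
  hydrophilic background composition (enough contrast for the built-in
  predictors without modelling real profile HMMs);
* transmembrane stretches — 23-mers over {I, L, F};
* coiled-coils — four clean LEALEGK heptads.

Every planted domain block is reported in InterProScan-dialect TSV rows,
normally by two member databases (redundant annotation is the norm for real
InterProScan output and is what the interval-collapsing step exists for);
annotation noise removes a row or re-maps it to an unknown accession with
equal probability.  A ground-truth table records the intended class label,
subclass and flags, so pipeline recovery can be scored exactly.

Class frequencies default to the observed shares of the candidate survey this
package emulates: kinases 35.2%, transmembrane receptors ~22.9%, cytoplasmic
CNL/TNL 9.2%, kinase-OthR 13%, and the minor classes at their census
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import class_label
from .conservation import AlignmentBlock
from .io import ProteinRecord, write_fasta

AMINO_ACIDS = np.array(list("ARNDCQEGHILKMFPSTWYV"))

#: hydrophilic background composition (same order as AMINO_ACIDS)
BACKGROUND_WEIGHTS = np.array([
    0.04, 0.07, 0.06, 0.08, 0.01, 0.06, 0.11, 0.08, 0.03, 0.02,
    0.03, 0.09, 0.01, 0.02, 0.06, 0.09, 0.07, 0.01, 0.03, 0.03,
])

#: 24-residue leucine-rich repeat template; '.' = background draw
LRR_TEMPLATE = "L..L.L..N.L....IP..L...."

#: signature rows emitted per planted category block: (signature, database)
CATEGORY_SIGNATURES: dict[str, list[tuple[str, str]]] = {
    "NBS": [("PF00931", "Pfam"), ("PTHR23155:SF186", "PANTHER")],
    "TIR": [("PF01582", "Pfam"), ("SM00255", "SMART")],
    "KIN": [("PF00069", "Pfam"), ("PF07714", "Pfam")],
    "LRR": [("PF00560", "Pfam"), ("PF13855", "Pfam")],
    "OTHR": [("PF00954", "Pfam")],
}

#: blueprint elements are (kind, payload): ("domain", category), ("domain_sig",
#: (category, [(sig, db), ...])), ("tm", None), ("cc", None), ("tail", None)
CLASS_BLUEPRINTS: dict[str, dict] = {
    "KIN": {"elements": [("domain", "KIN")], "subclass": None},
    "PTO-like": {
        "elements": [("domain_sig", ("KIN", [("PF00069", "Pfam"), ("PTHR24420:SF785", "PANTHER")]))],
        "subclass": "PTO-like",
    },
    "TIR": {"elements": [("domain", "TIR")], "subclass": None},
    "NBS": {"elements": [("domain", "NBS")], "subclass": "NBS"},
    "LRR": {"elements": [("domain", "LRR")], "subclass": None},
    "OthR": {"elements": [("domain", "OTHR")], "subclass": None},
    "TNL": {"elements": [("domain", "TIR"), ("domain", "NBS"), ("domain", "LRR")], "subclass": "TNL"},
    "CNL": {"elements": [("cc", None), ("domain", "NBS"), ("domain", "LRR")], "subclass": "CNL"},
    "NBS-LRR": {"elements": [("domain", "NBS"), ("domain", "LRR")], "subclass": "NBS-LRR"},
    "CC-NBS": {"elements": [("cc", None), ("domain", "NBS")], "subclass": "CC-NBS"},
    "TIR-NBS": {"elements": [("domain", "TIR"), ("domain", "NBS")], "subclass": None},
    "RLK": {"elements": [("domain", "LRR"), ("tm", None), ("domain", "KIN")], "subclass": "RLK"},
    "RLP": {"elements": [("domain", "LRR"), ("tm", None), ("tail", None)], "subclass": "RLP"},
    "MLO-like": {
        "elements": [("tm", None), ("domain_sig", ("OTHR", [("PF03094", "Pfam")])), ("tm", None)],
        "subclass": "MLO-like",
    },
    "KIN-OthR": {"elements": [("domain", "KIN"), ("domain", "OTHR")], "subclass": None},
}

#: observed class shares of the survey this package emulates
DEFAULT_CLASS_FREQUENCIES: dict[str, float] = {
    "KIN": 0.352, "RLK": 0.120, "RLP": 0.109, "KIN-OthR": 0.130, "OthR": 0.100,
    "CNL": 0.070, "TNL": 0.022, "TIR": 0.019, "NBS": 0.015, "LRR": 0.014,
    "TIR-NBS": 0.011, "NBS-LRR": 0.010, "CC-NBS": 0.007, "MLO-like": 0.017,
    "PTO-like": 0.004,
}

DEFAULT_DOMAIN_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "NBS": (150, 300), "TIR": (120, 180), "KIN": (200, 280), "OTHR": (100, 250),
    "LRR": (4, 10),  # number of 24-residue repeats, not residues
}


@dataclass
class SimSpec:
    """Generator settings; the defaults are the emulated study conditions."""

    n_proteins: int = 500
    class_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES)
    )
    domain_length_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LENGTH_RANGES)
    )
    linker_length_range: tuple[int, int] = (10, 40)
    annotation_noise: float = 0.0  # P(drop or mis-map) per TSV row
    divergence: float = 0.05  # per-site substitution rate for alignments
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.class_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {total}, expected 1")
        if not all(0.0 <= p <= 1.0 for p in self.class_frequencies.values()):
            raise ValueError("class frequencies must lie in [0, 1]")
        unknown = set(self.class_frequencies) - set(CLASS_BLUEPRINTS)
        if unknown:
            raise ValueError(f"no blueprint for classes {sorted(unknown)}")


@dataclass
class SimDataset:
    records: list[ProteinRecord]
    tsv_rows: list[tuple]  # (protein_id, database, signature, start, end, description)
    truth: pd.DataFrame  # protein_id, sim_class, class_label, subclass

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "tsv": outdir / "domains.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        with open(paths["tsv"], "w") as fh:
            for row in self.tsv_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _draw_background(rng: np.random.Generator, length: int, weights: np.ndarray) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length, p=weights))


def _dirichlet_composition(rng: np.random.Generator, concentration: float = 300.0) -> np.ndarray:
    return rng.dirichlet(BACKGROUND_WEIGHTS * concentration)


def _lrr_block(rng: np.random.Generator, n_repeats: int, weights: np.ndarray) -> str:
    out = []
    for _ in range(n_repeats):
        for ch in LRR_TEMPLATE:
            out.append(ch if ch != "." else str(rng.choice(AMINO_ACIDS, p=weights)))
    return "".join(out)


def generate_dataset(spec: SimSpec) -> SimDataset:
    """Generate proteins, annotation rows and ground truth from *spec*.

    Deterministic for a given spec (byte-identical files on re-run).
    """
    root = np.random.SeedSequence(spec.seed)
    ss_assign, ss_seq, ss_noise, _ = root.spawn(4)
    rng_assign = np.random.default_rng(ss_assign)
    rng_seq = np.random.default_rng(ss_seq)
    rng_noise = np.random.default_rng(ss_noise)

    names = sorted(spec.class_frequencies)
    probs = np.array([spec.class_frequencies[n] for n in names])
    probs = probs / probs.sum()
    assignments = rng_assign.choice(len(names), size=spec.n_proteins, p=probs)

    # per-category composition: one Dirichlet perturbation per dataset
    comps = {cat: _dirichlet_composition(rng_seq) for cat in ("NBS", "TIR", "KIN", "OTHR")}
    linker_comp = _dirichlet_composition(rng_seq)
    lrr_comp = _dirichlet_composition(rng_seq)

    records: list[ProteinRecord] = []
    rows: list[tuple] = []
    truth_rows: list[dict] = []
    lo_link, hi_link = spec.linker_length_range

    for i, cls_idx in enumerate(assignments):
        sim_class = names[cls_idx]
        bp = CLASS_BLUEPRINTS[sim_class]
        pid = f"SIM{i:05d}"
        seq_parts = ["M"]
        pos = 2  # 1-based position of the next residue
        categories: set[str] = set()
        protein_rows: list[tuple] = []

        def _append(s: str) -> tuple[int, int]:
            nonlocal pos
            seq_parts.append(s)
            start = pos
            pos += len(s)
            return start, pos - 1

        for kind, payload in bp["elements"]:
            if kind != "tail":
                _append(_draw_background(rng_seq, int(rng_seq.integers(lo_link, hi_link + 1)),
                                         linker_comp))
            if kind in ("domain", "domain_sig"):
                if kind == "domain":
                    cat, sigs = payload, CATEGORY_SIGNATURES[payload]
                else:
                    cat, sigs = payload
                if cat == "LRR":
                    lo, hi = spec.domain_length_ranges["LRR"]
                    block = _lrr_block(rng_seq, int(rng_seq.integers(lo, hi + 1)), lrr_comp)
                else:
                    lo, hi = spec.domain_length_ranges[cat]
                    block = _draw_background(rng_seq, int(rng_seq.integers(lo, hi + 1)), comps[cat])
                start, end = _append(block)
                categories.add(cat)
                for sig, db in sigs:
                    protein_rows.append((pid, db, sig, start, end, f"simulated {cat} block"))
            elif kind == "tm":
                _append("".join(rng_seq.choice(np.array(list("ILF")), size=23)))
            elif kind == "cc":
                _append("LEALEGK" * 4)
            elif kind == "tail":
                _append(_draw_background(rng_seq, int(rng_seq.integers(5, 16)), linker_comp))

        records.append(ProteinRecord(id=pid, sequence="".join(seq_parts), species="synthetic"))
        # annotation noise: drop or mis-map whole rows
        for row in protein_rows:
            if spec.annotation_noise > 0 and rng_noise.random() < spec.annotation_noise:
                if rng_noise.random() < 0.5:
                    continue  # dropped
                row = (row[0], row[1], "PF99999", row[3], row[4], row[5])
            rows.append(row)
        truth_rows.append(
            {
                "protein_id": pid,
                "sim_class": sim_class,
                "class_label": class_label(categories),
                "subclass": bp["subclass"] or "",
            }
        )
    return SimDataset(records=records, tsv_rows=rows, truth=pd.DataFrame(truth_rows))


def generate_class_alignment(
    n_sequences: int,
    length: int,
    divergence: float,
    seed: int,
    class_name: str = "synthetic",
    gap_fraction: float = 0.0,
) -> AlignmentBlock:
    """Star-phylogeny alignment: one ancestor, independent per-site mutation.

    Each sequence substitutes each site with probability *divergence*, drawing
    the replacement uniformly from the 20 residues (so a "substitution" keeps
    the ancestral residue with probability 1/20, and expected pairwise
    identity is approximately 100 x [(1 - d')^2 + (1 - (1 - d')^2)/20] with
    d' = 19 d / 20).  *gap_fraction* > 0 plants independent per-site gaps.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(AMINO_ACIDS, size=length)
    seqs = []
    for i in range(n_sequences):
        seq = ancestor.copy()
        mask = rng.random(length) < divergence
        seq[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
        if gap_fraction > 0:
            gmask = rng.random(length) < gap_fraction
            seq = seq.astype(object)
            seq[gmask] = "-"
        seqs.append((f"{class_name}_{i:03d}", "".join(seq)))
    return AlignmentBlock(class_name=class_name, sequences=seqs)
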