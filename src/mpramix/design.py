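"""MPRA library design: core-region selection, shuffled negatives, assembly.

A designed library consists of candidate enhancer sequences (270 bp cores cut
from larger ChIP-seq-defined enhancers), positive-control sequences with prior
evidence of activity, and negative controls obtained by shuffling the
nucleotides of randomly chosen candidates.  Coordinates are 0-based half-open
(BED convention) throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("candidate", "positive_control", "negative_control")
DNA_ALPHABET = set("ACGTN")


class DesignError(ValueError):
    """Invalid library design input (duplicate ids, malformed sequence, ...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DesignError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise DesignError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise DesignError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp intersection on the same chromosome."""
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class LibraryElement:
    element_id: str
    sequence: str
    category: str
    source_interval: GenomicInterval | None = None
    linked_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DesignError(f"unknown category {self.category!r}")
        if not self.sequence or set(self.sequence) - DNA_ALPHABET:
            raise DesignError(f"invalid sequence for {self.element_id}")


@dataclass
class LibraryDesign:
    elements: list[LibraryElement]
    adapter_5p: str = "AGGACCGGATCAACT"
    adapter_3p: str = "CATTGCGTGAACCGA"

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DesignError(f"duplicate element_id: {dup!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.elements:
            counts[e.category] += 1
        return counts

    def by_category(self, category: str) -> list[LibraryElement]:
        return [e for e in self.elements if e.category == category]

    def element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements]


@dataclass
class FeatureSet:
    """A named set of genomic intervals (e.g. p300 peaks, DNase HS sites)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))


def shuffle_sequence(seq: str, seed: int) -> str:
    """Mononucleotide shuffle: a uniform random permutation of ``seq``.

    Preserves length and base composition exactly; deterministic given
    ``seed``.
    """
    if not seq:
        raise DesignError("cannot shuffle an empty sequence")
    if set(seq) - DNA_ALPHABET:
        raise DesignError("sequence contains non-ACGTN letters")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(seq.encode(), dtype="S1")
    return rng.permutation(letters).tobytes().decode()


def select_core_region(
    region: GenomicInterval,
    feature_sets: Sequence[FeatureSet] = (),
    motif_hits: Sequence[GenomicInterval] = (),
    target_len: int = 270,
) -> GenomicInterval:
    """Pick the ``target_len`` window of ``region`` best supported by evidence.

    Regions already at or below ``target_len`` are returned unchanged.
    Otherwise every possible window is scored by, in priority order:

    1. number of feature-set intervals it overlaps by ≥1 bp (a peak anywhere
       in the window flags the general region as active);
    2. number of motif hits fully contained (a truncated motif is assumed
       non-functional);
    3. centrality — window centre nearest the region centre, residual ties
       broken leftmost.
    """
    if target_len < 1:
        raise DesignError("target_len must be >= 1")
    if len(region) <= target_len:
        return region

    features = [
        iv for fs in feature_sets for iv in fs.intervals if iv.chrom == region.chrom
    ]
    motifs = [m for m in motif_hits if m.chrom == region.chrom]
    f_start = np.array([iv.start for iv in features], dtype=np.int64)
    f_end = np.array([iv.end for iv in features], dtype=np.int64)
    m_start = np.array([m.start for m in motifs], dtype=np.int64)
    m_end = np.array([m.end for m in motifs], dtype=np.int64)

    region_centre = region.start + region.end  # ×2, avoids fractions
    best = None
    best_key = None
    for start in range(region.start, region.end - target_len + 1):
        end = start + target_len
        n_feat = int(np.count_nonzero((f_start < end) & (f_end > start)))
        n_motif = int(np.count_nonzero((m_start >= start) & (m_end <= end)))
        dist = abs((start + end) - region_centre)
        key = (-n_feat, -n_motif, dist, start)
        if best_key is None or key < best_key:
            best_key = key
            best = start
    return GenomicInterval(region.chrom, best, best + target_len, region.strand)


def make_shuffled_negatives(
    candidates: Sequence[LibraryElement],
    n: int,
    seed: int,
    id_prefix: str = "neg",
) -> list[LibraryElement]:
    """Shuffle the nucleotides of ``n`` randomly chosen candidates."""
    if n > len(candidates):
        raise DesignError(f"cannot pick {n} of {len(candidates)} candidates")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(candidates), size=n, replace=False)
    negatives = []
    for k, idx in enumerate(picks):
        src = candidates[int(idx)]
        shuffled = shuffle_sequence(src.sequence, seed=int(rng.integers(2**31)))
        negatives.append(
            LibraryElement(
                element_id=f"{id_prefix}_{k:04d}",
                sequence=shuffled,
                category="negative_control",
            )
        )
    return negatives


def assemble_library(
    candidates: Iterable[LibraryElement],
    positives: Iterable[LibraryElement] = (),
    negatives: Iterable[LibraryElement] = (),
    adapter_5p: str = "AGGACCGGATCAACT",
    adapter_3p: str = "CATTGCGTGAACCGA",
) -> LibraryDesign:
    """Combine the three element groups into one design with category labels."""

    def relabel(elems, category):
        out = []
        for e in elems:
            if e.category != category:
                e = LibraryElement(
                    e.element_id, e.sequence, category, e.source_interval, e.linked_genes
                )
            out.append(e)
        return out

    elements = (
        relabel(candidates, "candidate")
        + relabel(positives, "positive_control")
        + relabel(negatives, "negative_control")
    )
    return LibraryDesign(elements, adapter_5p=adapter_5p, adapter_3p=adapter_3p)


# ---------------------------------------------------------------------------
# I/O: FASTA + manifest, BED feature sets, FIMO motif-hit tables
# ---------------------------------------------------------------------------

def _interval_label(iv: GenomicInterval | None) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}" if iv is not None else "NA"


def write_design_fasta(design: LibraryDesign, path: str | Path) -> None:
    """Write elements as FASTA with headers ``element_id|category|chrom:start-end``."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(e.sequence),
            id=f"{e.element_id}|{e.category}|{_interval_label(e.source_interval)}",
            description="",
        )
        for e in design.elements
    ]
    seqio_write(records, str(path), "fasta")


def write_design_manifest(design: LibraryDesign, path: str | Path) -> None:
    rows = []
    for e in design.elements:
        iv = e.source_interval
        rows.append(
            {
                "element_id": e.element_id,
                "category": e.category,
                "chrom": iv.chrom if iv else "NA",
                "start": iv.start if iv else -1,
                "end": iv.end if iv else -1,
                "strand": iv.strand if iv else ".",
                "linked_genes": ";".join(e.linked_genes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"element_id", "category", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"manifest missing columns: {sorted(missing)}")
    return df


def read_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """Read a BED3+ file into a FeatureSet (extra columns ignored)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DesignError(f"BED line with <3 columns: {line!r}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return FeatureSet(name or Path(path).stem, intervals)


FIMO_COLUMNS = [
    "motif_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
]


def read_fimo(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a FIMO-style TSV of motif hits.

    FIMO reports 1-based inclusive coordinates; the returned frame adds
    0-based half-open ``start0``/``end0`` columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FIMO_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"FIMO table missing columns: {sorted(missing)}")
    df = df.copy()
    df["start0"] = df["start"].astype(int) - 1
    df["end0"] = df["stop"].astype(int)
    return df


def fimo_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.sequence_name), int(r.start0), int(r.end0))
        for r in df.itertuples()
    ]
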