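"""Barcode-level count QC and aggregation to element activity.

Enhancer activity is the ratio of transcribed barcode reads (RNA-seq) to
integrated genomic barcode reads (DNA-seq).  Counts are normalised to counts
per million within each sample, summed over an element's barcodes, and the
log2 ratio taken with a pseudocount:

    activity[e, s] = log2( (CPM_rna(e, s) + p) / (CPM_dna(e, s) + p) )

The ratio-of-sums form is used rather than a mean of per-barcode ratios
because it is far more stable at low counts.  Replicates within a time point
are combined by the arithmetic mean of their log2 activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CountMatrix, TIME_POINTS

logger = logging.getLogger(__name__)


class CountFormatError(ValueError):
    """Malformed count input (missing column, no usable barcodes, ...)."""


@dataclass
class ActivityMatrix:
    """Per-element log2 activity, per sample and aggregated per time point."""

    sample_matrix: pd.DataFrame  # element_id × sample_id
    timepoint_matrix: pd.DataFrame  # element_id × time_point
    samples: pd.DataFrame
    categories: pd.Series | None = None  # element_id -> category

    @property
    def element_ids(self) -> pd.Index:
        return self.sample_matrix.index

    def with_categories(self, categories: pd.Series) -> "ActivityMatrix":
        return ActivityMatrix(
            self.sample_matrix,
            self.timepoint_matrix,
            self.samples,
            categories.reindex(self.sample_matrix.index),
        )

    def values_for(self, category: str, per_sample: bool = True) -> np.ndarray:
        """Flat activity values for one element category.

        ``per_sample=True`` pools every (element, sample) value — the default
        for background fitting; otherwise (element, time point) means.
        """
        if self.categories is None:
            raise ValueError("no category labels attached")
        mask = self.categories == category
        mat = self.sample_matrix if per_sample else self.timepoint_matrix
        return mat.loc[mask.reindex(mat.index, fill_value=False)].to_numpy().ravel()


@dataclass
class QCReport:
    surviving_barcodes: pd.DataFrame  # element_id × sample: surviving barcode count
    qc_pass: pd.Series  # element_id -> bool
    min_barcodes: int
    min_dna_per_barcode: int
    dropped_elements: list[str] = field(default_factory=list)

    @property
    def pass_fraction(self) -> float:
        return float(self.qc_pass.mean())


def read_counts(
    barcode_map_path: str | Path,
    counts_path: str | Path,
    samples_path: str | Path,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Read barcode-map, long-format count and sample-metadata TSVs.

    Barcodes in the count table absent from the barcode map are dropped; the
    number dropped is logged and recorded on ``CountMatrix.n_unknown_barcodes``.
    """
    bm = pd.read_csv(barcode_map_path, sep="\t")
    _require(bm, ["barcode", "element_id"], "barcode map")
    long = pd.read_csv(counts_path, sep="\t")
    _require(long, ["barcode", "sample_id", "dna_count", "rna_count"], "counts")
    samples = pd.read_csv(samples_path, sep="\t")
    _require(samples, ["sample_id", "time_point"], "samples")
    samples = samples.set_index("sample_id")

    known = set(bm["barcode"])
    unknown_mask = ~long["barcode"].isin(known)
    n_unknown = int(long.loc[unknown_mask, "barcode"].nunique())
    if n_unknown:
        logger.warning("dropping %d unknown barcodes from count table", n_unknown)
        long = long.loc[~unknown_mask]
    if long.empty:
        raise CountFormatError("no usable barcodes after cross-referencing")

    dna = long.pivot(index="barcode", columns="sample_id", values="dna_count")
    rna = long.pivot(index="barcode", columns="sample_id", values="rna_count")
    dna = dna.reindex(columns=samples.index).fillna(0).astype(np.int64)
    rna = rna.reindex(columns=samples.index).fillna(0).astype(np.int64)
    cm = CountMatrix(dna=dna, rna=rna, samples=samples, n_unknown_barcodes=n_unknown)
    return bm, cm


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CountFormatError(f"{what} table missing column(s): {missing}")


def qc_filter(
    bm: pd.DataFrame,
    cm: CountMatrix,
    min_barcodes: int = 10,
    min_dna_per_barcode: int = 1,
) -> tuple[CountMatrix, QCReport]:
    """Mask under-covered barcodes and flag under-represented elements.

    A barcode with DNA count below ``min_dna_per_barcode`` in a sample is
    masked (both layers zeroed) in that sample only.  An element whose
    surviving barcode count falls below ``min_barcodes`` in any sample is
    flagged ``qc_fail``; it stays in the matrix so the caller decides whether
    to drop it.
    """
    if min_barcodes < 0 or min_dna_per_barcode < 0:
        raise ValueError("thresholds must be >= 0")
    bm_idx = bm.set_index("barcode")["element_id"].reindex(cm.barcodes)
    keep = cm.dna.to_numpy() >= min_dna_per_barcode
    dna = pd.DataFrame(np.where(keep, cm.dna.to_numpy(), 0),
                       index=cm.barcodes, columns=cm.dna.columns)
    rna = pd.DataFrame(np.where(keep, cm.rna.to_numpy(), 0),
                       index=cm.barcodes, columns=cm.rna.columns)

    surviving = (
        pd.DataFrame(keep, index=cm.barcodes, columns=cm.dna.columns)
        .groupby(bm_idx)
        .sum()
    )
    qc_pass = (surviving.min(axis=1) >= min_barcodes).rename("qc_pass")
    report = QCReport(
        surviving_barcodes=surviving,
        qc_pass=qc_pass,
        min_barcodes=min_barcodes,
        min_dna_per_barcode=min_dna_per_barcode,
    )
    filtered = CountMatrix(dna=dna, rna=rna, samples=cm.samples,
                           n_unknown_barcodes=cm.n_unknown_barcodes)
    return filtered, report


def aggregate_activity(
    bm: pd.DataFrame,
    cm: CountMatrix,
    pseudocount: float = 1.0,
) -> ActivityMatrix:
    """Aggregate barcode counts to log2(RNA/DNA) activity per element.

    Elements with zero surviving barcode counts in both layers across all
    samples are excluded and logged.
    """
    elem = bm.set_index("barcode")["element_id"].reindex(cm.barcodes)
    dna_sum = cm.dna.groupby(elem).sum()
    rna_sum = cm.rna.groupby(elem).sum()

    empty = (dna_sum.sum(axis=1) == 0) & (rna_sum.sum(axis=1) == 0)
    if empty.any():
        for eid in dna_sum.index[empty]:
            logger.warning("excluding element with no surviving counts: %s", eid)
        dna_sum, rna_sum = dna_sum.loc[~empty], rna_sum.loc[~empty]

    dna_tot = cm.dna.sum(axis=0).astype(float)
    rna_tot = cm.rna.sum(axis=0).astype(float)
    dna_cpm = dna_sum / dna_tot * 1e6
    rna_cpm = rna_sum / rna_tot * 1e6
    sample_matrix = np.log2((rna_cpm + pseudocount) / (dna_cpm + pseudocount))

    tp = cm.samples["time_point"]
    timepoint_matrix = sample_matrix.T.groupby(tp).mean().T
    order = [t for t in TIME_POINTS if t in timepoint_matrix.columns]
    timepoint_matrix = timepoint_matrix[order + sorted(
        set(timepoint_matrix.columns) - set(order))]
    return ActivityMatrix(
        sample_matrix=sample_matrix,
        timepoint_matrix=timepoint_matrix,
        samples=cm.samples,
    )


def write_activity(am: ActivityMatrix, path: str | Path) -> None:
    path = Path(path)
    am.sample_matrix.to_csv(path, sep="\t")
    tp_path = path.with_name(path.stem + ".timepoints" + path.suffix)
    am.timepoint_matrix.to_csv(tp_path, sep="\t")


def read_activity(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
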