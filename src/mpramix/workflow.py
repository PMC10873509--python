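"""End-to-end helpers: build a synthetic library and run the calling pipeline.

These convenience functions wire the modules together the way the analysis is
meant to run: design → simulated counts → QC → activity aggregation →
background fit on negative controls → signal fit on tested elements →
active calls → sensitivity.  They exist so tests, examples and scripts share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import MixtureFit, fit_background, fit_mixture
from .calls import CallTable, call_active, estimate_sensitivity, SensitivityEstimate
from .counts import ActivityMatrix, QCReport, aggregate_activity, qc_filter
from .design import (
    GenomicInterval,
    LibraryDesign,
    LibraryElement,
    assemble_library,
    make_shuffled_negatives,
)
from .simulate import CountMatrix, SimTruth, simulate_counts

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_synthetic_library(
    n_candidates: int,
    n_positives: int = 0,
    n_negatives: int = 0,
    seq_len: int = 270,
    n_genes: int | None = None,
    seed: int = 0,
) -> LibraryDesign:
    """A random library with the standard three-category composition.

    Candidate and positive-control sequences are random DNA with genomic
    provenance; negatives are nucleotide shuffles of randomly chosen
    candidates.  Candidates are linked round-robin to ``n_genes`` gene ids
    (default: one gene per two candidates).
    """
    rng = np.random.default_rng(seed)
    if n_genes is None:
        n_genes = max(1, n_candidates // 2)
    genes = [f"gene{g:05d}" for g in range(n_genes)]

    def random_seq() -> str:
        return _BASES[rng.integers(0, 4, size=seq_len)].tobytes().decode()

    candidates = [
        LibraryElement(
            element_id=f"cand_{i:05d}",
            sequence=random_seq(),
            category="candidate",
            source_interval=GenomicInterval(
                f"chr{1 + i % 22}", 1000 * (i + 1), 1000 * (i + 1) + seq_len
            ),
            linked_genes=(genes[i % n_genes],),
        )
        for i in range(n_candidates)
    ]
    positives = [
        LibraryElement(
            element_id=f"pos_{i:04d}",
            sequence=random_seq(),
            category="positive_control",
            source_interval=GenomicInterval(
                f"chr{1 + i % 22}", 10_000_000 + 1000 * i,
                10_000_000 + 1000 * i + seq_len
            ),
        )
        for i in range(n_positives)
    ]
    negatives = (
        make_shuffled_negatives(candidates, n_negatives,
                                seed=int(rng.integers(2**31)))
        if n_negatives
        else []
    )
    return assemble_library(candidates, positives, negatives)


@dataclass
class ExperimentResult:
    design: LibraryDesign
    barcode_map: pd.DataFrame
    counts: CountMatrix
    truth_table: pd.DataFrame
    activity: ActivityMatrix
    qc: QCReport
    background_fit: MixtureFit
    tested_fit: MixtureFit | None
    calls: CallTable
    sensitivity: SensitivityEstimate | None

    def recall_of_true_actives(self) -> float:
        """Fraction of truly active (element, time point) pairs called."""
        truth = self.truth_table.set_index(["element_id", "time_point"])["is_active"]
        t = self.calls.table.set_index(["element_id", "time_point"])
        active_idx = t.index.intersection(truth.index[truth])
        if len(active_idx) == 0:
            return float("nan")
        return float(t.loc[active_idx, "significant"].mean())


def run_experiment(
    design: LibraryDesign,
    truth: SimTruth | None = None,
    n_samples_per_timepoint: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    min_barcodes: int = 10,
    fit_method: str = "histogram_ls",
) -> ExperimentResult:
    """Simulate an MPRA experiment and run the full calling pipeline on it.

    The background component is fitted to pooled per-(element, sample)
    negative-control activities; the signal component comes from the mixture
    fitted to the tested (candidate + positive-control) activities.  Tests are
    Bonferroni-corrected over the QC-passing tested elements.
    """
    truth = truth or SimTruth()
    bm, cm, truth_table = simulate_counts(
        design, truth, n_samples_per_timepoint=n_samples_per_timepoint, seed=seed
    )
    cm_f, qc = qc_filter(bm, cm, min_barcodes=min_barcodes)
    am = aggregate_activity(bm, cm_f)
    categories = pd.Series(
        {e.element_id: e.category for e in design.elements}, name="category"
    )
    am = am.with_categories(categories)

    neg_vals = am.values_for("negative_control", per_sample=True)
    bg_fit = fit_background(neg_vals, method=fit_method, seed=seed)

    tested_mask = categories.reindex(am.element_ids).isin(
        ["candidate", "positive_control"]
    ) & qc.qc_pass.reindex(am.element_ids, fill_value=False)
    tested = am.timepoint_matrix.loc[tested_mask]

    tested_fit = None
    sens = None
    try:
        tested_fit = fit_mixture(
            am.sample_matrix.loc[tested_mask].to_numpy().ravel(),
            method=fit_method,
            seed=seed,
        )
    except Exception:  # degenerate tested distribution: no sensitivity estimate
        pass

    calls = call_active(tested, bg_fit.background, alpha=alpha,
                        n_tests=len(tested))
    if (
        tested_fit is not None
        and tested_fit.signal.mean - tested_fit.background.mean >= 0.1
    ):
        sens = estimate_sensitivity(
            bg_fit.background, tested_fit.signal, alpha=alpha, n_tests=len(tested)
        )
    return ExperimentResult(
        design=design,
        barcode_map=bm,
        counts=cm,
        truth_table=truth_table,
        activity=am,
        qc=qc,
        background_fit=bg_fit,
        tested_fit=tested_fit,
        calls=calls,
        sensitivity=sens,
    )
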