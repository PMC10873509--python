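"""Active-enhancer calling, temporal classification and assay sensitivity.

An element is called active at a time point when its activity is
significantly above the background component: one-sided upper-tail p-value
p = 1 − Φ((a − μ_bg)/σ_bg), Bonferroni-corrected over the number of tested
elements.  Equivalently, a > c with cutoff c = μ_bg + σ_bg·Φ⁻¹(1 − α/N);
both routes are computed and checked against each other.

Assay sensitivity is the signal-component mass above the cutoff:
S = 1 − Φ((c − μ_sig)/σ_sig), i.e. the probability that a truly active
element clears the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .background import GaussianComponent

TEMPORAL_CLASSES = (
    "inactive",
    "iPSC_only",
    "TD0_only",
    "TD30_only",
    "iPSC&TD0",
    "iPSC&TD30",
    "TD0&TD30",
    "all_three",
)


@dataclass(frozen=True)
class SensitivityEstimate:
    cutoff: float
    sensitivity: float
    signal: GaussianComponent


@dataclass
class CallTable:
    """Long-format calls: one row per (element_id, time_point)."""

    table: pd.DataFrame  # element_id, time_point, activity_log2, p_value, significant
    alpha: float
    n_tests: int
    cutoff: float

    def significant_at(self, time_point: str) -> pd.Index:
        t = self.table
        return pd.Index(
            t.loc[(t.time_point == time_point) & t.significant, "element_id"]
        )

    def active_elements(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t.significant, "element_id"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def activity_pvalue(a, bg: GaussianComponent):
    """One-sided upper-tail p-value of activity ``a`` under the background."""
    if bg.sd <= 0:
        raise ValueError("background sd must be positive")
    return stats.norm.sf(a, loc=bg.mean, scale=bg.sd)


def significance_cutoff(bg: GaussianComponent, alpha: float, n_tests: int) -> float:
    """Activity cutoff equivalent to the Bonferroni-corrected p threshold."""
    return float(bg.mean + bg.sd * stats.norm.ppf(1 - alpha / n_tests))


def call_active(
    timepoint_activity: pd.DataFrame,
    bg: GaussianComponent,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> CallTable:
    """Call active elements per time point against the background component.

    ``timepoint_activity`` is the element × time-point log2-activity matrix of
    the tested (QC-passing candidate + positive-control) elements; ``n_tests``
    defaults to its number of rows.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests is None:
        n_tests = len(timepoint_activity)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")

    long = timepoint_activity.stack().rename("activity_log2").reset_index()
    long.columns = ["element_id", "time_point", "activity_log2"]
    long["p_value"] = activity_pvalue(long["activity_log2"].to_numpy(), bg)
    long["significant"] = long["p_value"] < alpha / n_tests

    cutoff = significance_cutoff(bg, alpha, n_tests)
    by_cutoff = long["activity_log2"].to_numpy() > cutoff
    if not np.array_equal(by_cutoff, long["significant"].to_numpy()):
        raise AssertionError("p-value and cutoff call routes disagree")
    return CallTable(table=long, alpha=alpha, n_tests=n_tests, cutoff=cutoff)


def classify_temporal(ct: CallTable) -> tuple[pd.Series, dict[str, int]]:
    """Assign each element to one of the 8 temporal classes.

    Returns ``(labels, counts)``: a per-element class label and the counts per
    class.  "Specific" activity means active at exactly one time point.
    """
    tps = set(ct.table["time_point"])
    if not {"iPSC", "TD0", "TD30"} <= tps:
        raise ValueError("need all three time points (iPSC, TD0, TD30)")

    sig = (
        ct.table.pivot(index="element_id", columns="time_point", values="significant")
        .fillna(False)
        .astype(bool)
    )
    def label(row) -> str:
        active = [tp for tp in ("iPSC", "TD0", "TD30") if row[tp]]
        if not active:
            return "inactive"
        if len(active) == 3:
            return "all_three"
        if len(active) == 1:
            return f"{active[0]}_only"
        return "&".join(active)

    labels = sig.apply(label, axis=1).rename("temporal_class")
    counts = {c: int((labels == c).sum()) for c in TEMPORAL_CLASSES}
    return labels, counts


def temporal_summary(counts: dict[str, int]) -> dict[str, float]:
    """Active totals and specific/shared fractions from temporal-class counts."""
    specific = sum(counts[c] for c in ("iPSC_only", "TD0_only", "TD30_only"))
    shared = sum(counts[c] for c in ("iPSC&TD0", "iPSC&TD30", "TD0&TD30", "all_three"))
    total_active = specific + shared
    return {
        "total_active": total_active,
        "specific": specific,
        "shared": shared,
        "specific_fraction": specific / total_active if total_active else float("nan"),
        "shared_fraction": shared / total_active if total_active else float("nan"),
    }


def estimate_sensitivity(
    bg: GaussianComponent,
    sig: GaussianComponent,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> SensitivityEstimate:
    """Signal-component mass above the significance cutoff.

    The area under the signal (positive-control) Gaussian above the cutoff,
    as a fraction of its total area: the probability that a truly active
    element is called.
    """
    if sig.sd <= 0:
        raise ValueError("signal sd must be positive")
    c = significance_cutoff(bg, alpha, n_tests)
    s = float(stats.norm.sf(c, loc=sig.mean, scale=sig.sd))
    return SensitivityEstimate(cutoff=c, sensitivity=s, signal=sig)
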