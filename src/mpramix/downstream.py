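"""Post-calling analyses.

* Ward hierarchical clustering of activity profiles (linear RNA/DNA scale,
  display values capped — the cap affects the heat-map matrix only, never the
  distances);
* activity vs linked-gene expression log2 fold-change pairing and the
  concordance-fraction curve over a cutoff grid;
* overlap enrichment of active vs inactive elements against external interval
  sets (Fisher's exact test) with UpSet-style intersection counts;
* two-sample Kolmogorov–Smirnov comparisons (TFBS counts, linked-gene RPKM);
* per-element TFBS counting from FIMO-style motif-hit tables.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .calls import CallTable
from .counts import ActivityMatrix
from .design import FeatureSet, GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series  # element_id -> cluster id in {1, 2}
    display_matrix: pd.DataFrame  # leaf-ordered, linear scale, capped
    leaf_order: list[str]


def cluster_activity(
    am: ActivityMatrix, cap_for_display: float = 4.0
) -> ClusterResult:
    """Ward clustering of per-sample linear activity profiles.

    Distances are Euclidean over uncapped linear (RNA/DNA) activities;
    ``cap_for_display`` truncates only the returned heat-map matrix, mirroring
    a colour-scale cap.
    """
    linear = np.exp2(am.sample_matrix)
    if len(linear) < 2:
        raise ValueError("need >= 2 elements to cluster")
    if not np.isfinite(linear.to_numpy()).all():
        raise ValueError("activity matrix contains non-finite values")
    X = linear.to_numpy()
    if np.allclose(X, X[0]):
        warnings.warn("constant activity matrix; returning a single cluster")
        labels = pd.Series(1, index=linear.index, name="cluster")
        disp = linear.clip(upper=cap_for_display)
        return ClusterResult(np.empty((0, 4)), labels, disp, list(linear.index))
    Z = hierarchy.ward(X)
    lab = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    leaf_order = [linear.index[i] for i in order]
    disp = linear.iloc[order].clip(upper=cap_for_display)
    return ClusterResult(
        linkage=Z,
        labels=pd.Series(lab, index=linear.index, name="cluster"),
        display_matrix=disp,
        leaf_order=leaf_order,
    )


# ---------------------------------------------------------------------------
# Activity / expression log2 fold-change pairing and concordance
# ---------------------------------------------------------------------------

def pair_log2fc(
    am: ActivityMatrix,
    expr: pd.DataFrame,
    links: pd.DataFrame,
    contrast: tuple[str, str],
    calls: CallTable | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per enhancer–gene pair, Δ activity and Δ expression between time points.

    ``expr`` is a gene × sample RPKM frame with a sample-metadata frame in
    ``expr.attrs['samples']`` (column ``time_point``).  ``links`` needs
    columns element_id, gene_id.  ``contrast=(tp_a, tp_b)`` gives
    d = mean(tp_a) − mean(tp_b) for both quantities; expression is averaged as
    log2(RPKM + pseudocount).  Pairs whose gene is missing from ``expr`` or
    whose element is missing from the activity matrix are dropped and logged.
    """
    tp_a, tp_b = contrast
    tpm = am.timepoint_matrix
    for tp in contrast:
        if tp not in tpm.columns:
            raise ValueError(f"time point {tp!r} absent from activity matrix")
    expr_samples = expr.attrs.get("samples")
    if expr_samples is None:
        raise ValueError("expression frame lacks attrs['samples'] metadata")
    for tp in contrast:
        if tp not in set(expr_samples["time_point"]):
            raise ValueError(
                f"expression data has no samples at {tp!r}; supply measured "
                "expression for both contrast conditions (no imputation)"
            )

    log_expr = np.log2(expr + pseudocount)
    expr_by_tp = log_expr.T.groupby(expr_samples["time_point"]).mean().T

    rows = []
    n_dropped = 0
    sig_by_tp = None
    if calls is not None:
        sig_by_tp = (
            calls.table.pivot(index="element_id", columns="time_point",
                              values="significant")
            .fillna(False).astype(bool)
        )
    for link in links.itertuples():
        e, g = link.element_id, link.gene_id
        if e not in tpm.index or g not in expr_by_tp.index:
            n_dropped += 1
            continue
        d_act = float(tpm.loc[e, tp_a] - tpm.loc[e, tp_b])
        d_expr = float(expr_by_tp.loc[g, tp_a] - expr_by_tp.loc[g, tp_b])
        active = (
            bool(sig_by_tp.loc[e, [tp_a, tp_b]].any())
            if sig_by_tp is not None and e in sig_by_tp.index
            else None
        )
        rows.append(
            {
                "element_id": e,
                "gene_id": g,
                "contrast": f"{tp_a}_vs_{tp_b}",
                "d_activity": d_act,
                "d_expression": d_expr,
                "active": active,
            }
        )
    if n_dropped:
        logger.warning("dropped %d link pairs lacking activity or expression",
                       n_dropped)
    return pd.DataFrame(
        rows,
        columns=["element_id", "gene_id", "contrast", "d_activity",
                 "d_expression", "active"],
    )


def concordance_curve(
    pairs: pd.DataFrame, cutoffs=None
) -> pd.DataFrame:
    """Fraction of pairs with |Δ activity| ≥ t and |Δ expression| ≥ t.

    Computed per group (active / inactive element status), relative to each
    group's own pair count; curves are monotone non-increasing in t.  Empty
    groups yield NaN fractions.
    """
    if cutoffs is None:
        cutoffs = np.arange(0.0, 2.01, 0.1)
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    if cutoffs.size == 0 or (cutoffs < 0).any():
        raise ValueError("cutoff grid must be non-empty and non-negative")

    rows = []
    for group, sub in (("active", pairs[pairs.active == True]),   # noqa: E712
                       ("inactive", pairs[pairs.active == False])):  # noqa: E712
        da = sub["d_activity"].abs().to_numpy()
        de = sub["d_expression"].abs().to_numpy()
        for t in cutoffs:
            frac = (
                float(((da >= t) & (de >= t)).mean()) if len(sub) else float("nan")
            )
            rows.append({"group": group, "cutoff": float(t), "fraction": frac,
                         "n_pairs": len(sub)})
    return pd.DataFrame(rows)


def concordance_at(curve: pd.DataFrame, t: float = 0.8) -> dict[str, float]:
    out = {}
    for group in ("active", "inactive"):
        sub = curve[(curve.group == group)]
        idx = (sub.cutoff - t).abs().idxmin()
        out[group] = float(sub.loc[idx, "fraction"])
    return out


def sign_concordance(pairs: pd.DataFrame, min_abs: float = 0.0) -> float:
    """Fraction of pairs whose Δ activity and Δ expression share a sign."""
    sub = pairs[pairs["d_activity"].abs() > min_abs]
    if sub.empty:
        return float("nan")
    return float(
        (np.sign(sub["d_activity"]) == np.sign(sub["d_expression"])).mean()
    )


# ---------------------------------------------------------------------------
# Overlap enrichment against external interval sets
# ---------------------------------------------------------------------------

def _overlaps_any(iv: GenomicInterval, fs: FeatureSet) -> bool:
    for other in fs.intervals:
        if iv.overlaps(other):
            return True
    return False


def overlap_enrichment(
    calls: CallTable,
    external: list[FeatureSet],
    element_intervals: dict[str, GenomicInterval],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fisher-exact enrichment of active elements in external interval sets.

    An element overlaps a set iff it shares ≥1 bp with any of its intervals.
    Elements lacking an interval (e.g. shuffled negatives) are excluded.
    Returns ``(enrichment, upset)``: per-set 2×2 counts (a = active∩overlap,
    b = active∖overlap, c = inactive∩overlap, d = inactive∖overlap), odds
    ratio, two-sided Fisher p with a Bonferroni column; and UpSet-style
    intersection counts over all subset patterns, split by call status.
    """
    active_ids = set(calls.active_elements())
    elements = [e for e in calls.table["element_id"].unique()
                if e in element_intervals]

    membership = pd.DataFrame(
        {
            fs.name: [_overlaps_any(element_intervals[e], fs) for e in elements]
            for fs in external
        },
        index=pd.Index(elements, name="element_id"),
    )
    is_active = pd.Series([e in active_ids for e in elements], index=elements)

    rows = []
    for fs in external:
        ov = membership[fs.name]
        a = int((is_active & ov).sum())
        b = int((is_active & ~ov).sum())
        c = int((~is_active & ov).sum())
        d = int((~is_active & ~ov).sum())
        if not fs.intervals or (a + c) == 0:
            warnings.warn(f"external set {fs.name!r} overlaps no elements")
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"set": fs.name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(odds), "p_value": float(p)})
    enrich = pd.DataFrame(rows)
    enrich["p_bonferroni"] = np.minimum(enrich["p_value"] * len(enrich), 1.0)

    upset_rows = []
    names = [fs.name for fs in external]
    patterns = membership.apply(tuple, axis=1)
    for combo, sub in membership.groupby(patterns.values):
        in_sets = [n for n, flag in zip(names, combo) if flag]
        mask = patterns == combo
        upset_rows.append(
            {
                "sets": "&".join(in_sets) if in_sets else "(none)",
                "n_active": int(is_active[mask].sum()),
                "n_inactive": int((~is_active[mask]).sum()),
            }
        )
    upset = pd.DataFrame(upset_rows).sort_values(
        ["n_active", "n_inactive"], ascending=False, ignore_index=True
    )
    return enrich, upset


# ---------------------------------------------------------------------------
# Distribution comparisons
# ---------------------------------------------------------------------------

def ks_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sample KS tests between labelled value groups.

    Exact p-values at small n, asymptotic otherwise (scipy's ``auto`` rule).
    Every group needs at least 5 values.
    """
    for name, vals in groups.items():
        if len(vals) < 5:
            raise ValueError(f"group {name!r} has fewer than 5 values")
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
        res = stats.ks_2samp(va, vb, method="auto")
        rows.append({"group_a": na, "group_b": nb,
                     "ks_stat": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)


def ecdf_summary(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pooled-grid empirical CDFs for cumulative-distribution plots."""
    grid = np.unique(np.concatenate([np.asarray(v, float) for v in groups.values()]))
    rows = {"value": grid}
    for name, vals in groups.items():
        v = np.sort(np.asarray(vals, float))
        rows[name] = np.searchsorted(v, grid, side="right") / len(v)
    return pd.DataFrame(rows)


def count_tfbs(
    motif_hits: pd.DataFrame,
    element_ids,
    fdr_max: float = 0.05,
) -> pd.Series:
    """Per-element count of motif hits passing the q-value threshold.

    ``motif_hits`` is a FIMO-style frame (columns sequence_name, q-value).
    Hits whose sequence name is not a known element are tallied into an
    ``(unassigned)`` bucket and logged.
    """
    ids = pd.Index(element_ids, name="element_id")
    passing = motif_hits[motif_hits["q-value"] <= fdr_max]
    counts = passing.groupby("sequence_name").size()
    known = counts.reindex(ids, fill_value=0).astype(int)
    unassigned = int(counts.loc[~counts.index.isin(ids)].sum())
    if unassigned:
        logger.warning("%d motif hits on unknown sequence names", unassigned)
        known.attrs["unassigned"] = unassigned
    return known.rename("tfbs_count")
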