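"""Synthetic MPRA experiments with known ground truth.

The generator emulates the statistical structure of a lentiviral MPRA carried
out over three developmental stages (iPSC, TD0, TD30) with replicate samples:

* each library element carries a Poisson number of unique 15 bp barcodes;
* per barcode and sample, DNA counts are negative-binomial (integration depth
  varies between barcodes and samples);
* RNA counts are Poisson with rate ``dna × 2^(activity + barcode effect)`` —
  activity acts multiplicatively on the linear scale;
* element activity per time point is drawn from a two-component Gaussian
  mixture on the log2 scale: an inactive (background) component and an active
  (signal) component.  Negative controls always draw from the background;
  positive controls are active with high probability; candidates follow a
  per-time-point active fraction;
* genes linked to enhancers get log2 expression tracking the true activity of
  their linked ever-active enhancers, with Gaussian noise, so that activity
  changes and expression changes between time points are correlated with a
  chosen effect size ``beta``.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import LibraryDesign

TIME_POINTS = ("iPSC", "TD0", "TD30")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated experiment.

    Activity is on the log2(RNA/DNA) scale.  The defaults describe a
    background component at 0 and a signal component 0.65 log2 units above it
    (≈57% stronger on the linear scale), both with sd 0.35, barcodes per
    element averaging 39.9 and a mean DNA depth of 50 reads per barcode.
    """

    mu_bg: float = 0.0
    sd_bg: float = 0.35
    mu_sig: float = 0.65
    sd_sig: float = 0.35
    active_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "candidate": 0.15,
            "positive_control": 0.9,
            "negative_control": 0.0,
        }
    )
    mean_barcodes: float = 39.9
    barcode_length: int = 15
    mean_dna_per_barcode: float = 50.0
    dna_dispersion: float = 0.3
    barcode_log2_sd: float = 0.25
    beta: float = 1.0
    expr_noise_sd: float = 0.2
    expr_baseline_mean: float = 3.0
    expr_baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.sd_bg <= 0 or self.sd_sig <= 0:
            raise ValueError("component standard deviations must be positive")
        if self.mu_sig <= self.mu_bg:
            raise ValueError("mu_sig must exceed mu_bg")
        for cat, frac in self.active_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"active_fraction[{cat}] outside [0, 1]")
        if self.mean_barcodes <= 0 or self.mean_dna_per_barcode <= 0:
            raise ValueError("barcode and depth means must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimTruth":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "seed" not in cfg:
            raise ValueError("config must set an explicit seed")
        truth = cls(**cfg)
        truth.validate()
        return truth

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class CountMatrix:
    """Barcode × sample DNA and RNA count layers plus sample metadata."""

    dna: pd.DataFrame  # barcodes × samples, int
    rna: pd.DataFrame  # barcodes × samples, int
    samples: pd.DataFrame  # index sample_id; columns line, replicate, time_point
    n_unknown_barcodes: int = 0

    def __post_init__(self) -> None:
        if not self.dna.index.equals(self.rna.index) or not self.dna.columns.equals(
            self.rna.columns
        ):
            raise ValueError("dna and rna layers must share axes")

    @property
    def barcodes(self) -> pd.Index:
        return self.dna.index

    def subset_barcodes(self, barcodes) -> "CountMatrix":
        return CountMatrix(
            self.dna.loc[barcodes], self.rna.loc[barcodes], self.samples
        )


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """n distinct random DNA strings of the given length."""
    out: set[str] = set()
    while len(out) < n:
        draws = rng.integers(0, 4, size=(n - len(out), length))
        for row in draws:
            out.add(_BASES[row].tobytes().decode())
    return sorted(out)[:n] if len(out) > n else list(out)


def _sample_table(n_per_tp: int) -> pd.DataFrame:
    rows = []
    for tp in TIME_POINTS:
        for r in range(1, n_per_tp + 1):
            rows.append(
                {
                    "sample_id": f"{tp}_rep{r}",
                    "line": f"line{r}",
                    "replicate": r,
                    "time_point": tp,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def draw_truth_table(
    design: LibraryDesign, truth: SimTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Per (element, time point) activity draws from the mixture.

    Returns a long frame with columns element_id, category, time_point,
    is_active, true_log_activity.
    """
    rows = []
    for e in design.elements:
        frac = truth.active_fraction.get(e.category, 0.0)
        for tp in TIME_POINTS:
            active = bool(rng.random() < frac)
            mu, sd = (
                (truth.mu_sig, truth.sd_sig) if active else (truth.mu_bg, truth.sd_bg)
            )
            rows.append(
                {
                    "element_id": e.element_id,
                    "category": e.category,
                    "time_point": tp,
                    "is_active": active,
                    "true_log_activity": float(rng.normal(mu, sd)),
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    design: LibraryDesign,
    truth: SimTruth,
    n_samples_per_timepoint: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, CountMatrix, pd.DataFrame]:
    """Simulate barcode-level DNA/RNA counts for a designed library.

    Returns ``(barcode_map, counts, truth_table)`` where ``barcode_map`` has
    columns (barcode, element_id), ``counts`` is a :class:`CountMatrix` and
    ``truth_table`` is the realised per-(element, time point) ground truth.
    """
    if n_samples_per_timepoint < 1:
        raise ValueError("n_samples_per_timepoint must be >= 1")
    if len(design) == 0:
        raise ValueError("design is empty")
    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    truth_table = draw_truth_table(design, truth, rng)
    activity = truth_table.pivot(
        index="element_id", columns="time_point", values="true_log_activity"
    )

    element_ids = design.element_ids()
    n_elem = len(element_ids)
    n_bc_per_elem = np.maximum(1, rng.poisson(truth.mean_barcodes, size=n_elem))
    n_bc_total = int(n_bc_per_elem.sum())
    barcodes = _random_barcodes(n_bc_total, truth.barcode_length, rng)
    elem_idx = np.repeat(np.arange(n_elem), n_bc_per_elem)
    barcode_map = pd.DataFrame(
        {"barcode": barcodes, "element_id": np.array(element_ids)[elem_idx]}
    )

    samples = _sample_table(n_samples_per_timepoint)
    n_samp = len(samples)
    tp_of_sample = samples["time_point"].to_numpy()

    # barcode effects: lognormal on the linear scale, normalised to unit mean
    log2_eff = rng.normal(0.0, truth.barcode_log2_sd, size=n_bc_total)
    lin_eff = np.exp2(log2_eff)
    lin_eff /= np.exp((truth.barcode_log2_sd * np.log(2)) ** 2 / 2)

    # DNA: gamma-Poisson with mean depth and var = m + dispersion * m^2
    shape = 1.0 / truth.dna_dispersion
    lam = rng.gamma(
        shape, truth.mean_dna_per_barcode / shape, size=(n_bc_total, n_samp)
    )
    dna = rng.poisson(lam)

    # RNA rate per cell: dna × 2^activity × barcode effect
    act = activity.loc[np.array(element_ids)].to_numpy()  # elements × 3 tps
    tp_index = {tp: i for i, tp in enumerate(activity.columns)}
    act_per_cell = act[elem_idx][:, [tp_index[tp] for tp in tp_of_sample]]
    rate = dna * np.exp2(act_per_cell) * lin_eff[:, None]
    rna = rng.poisson(rate)

    cm = CountMatrix(
        dna=pd.DataFrame(dna, index=pd.Index(barcodes, name="barcode"),
                         columns=samples.index),
        rna=pd.DataFrame(rna, index=pd.Index(barcodes, name="barcode"),
                         columns=samples.index),
        samples=samples,
    )
    return barcode_map, cm, truth_table


def sample_offset_oracle(
    barcode_map: pd.DataFrame, cm: CountMatrix, truth_table: pd.DataFrame
) -> pd.Series:
    """Per-sample additive offset of CPM-normalised log2 activity.

    CPM scaling divides each sample by its total, so estimated activities are
    shifted by −log2 of the DNA-weighted mean linear activity of the whole
    library.  This returns that shift, computed from the realised DNA counts
    and true activities, for use in recovery checks.
    """
    activity = truth_table.pivot(
        index="element_id", columns="time_point", values="true_log_activity"
    )
    elem_of_bc = barcode_map.set_index("barcode")["element_id"]
    offsets = {}
    for s in cm.samples.index:
        tp = cm.samples.loc[s, "time_point"]
        a = activity[tp].loc[elem_of_bc.loc[cm.barcodes]].to_numpy()
        d = cm.dna[s].to_numpy().astype(float)
        offsets[s] = -float(np.log2((d * np.exp2(a)).sum() / d.sum()))
    return pd.Series(offsets, name="offset")


def simulate_expression(
    design: LibraryDesign,
    truth: SimTruth,
    truth_table: pd.DataFrame,
    n_expr_samples: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate linked-gene expression (RPKM) tracking true enhancer activity.

    Per gene and time point, mean log2 RPKM = baseline + beta × (mean true
    log-activity, relative to background, of linked ever-active enhancers);
    genes linked only to never-active enhancers get baseline + noise.
    Returns a gene × sample RPKM frame whose columns follow the
    ``{tp}_rep{r}`` naming convention with time-point metadata in
    ``df.attrs['samples']``.
    """
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 10_007)
    activity = truth_table.pivot(
        index="element_id", columns="time_point", values="true_log_activity"
    )
    ever_active = truth_table.groupby("element_id")["is_active"].any()

    gene_links: dict[str, list[str]] = {}
    for e in design.elements:
        for g in e.linked_genes:
            gene_links.setdefault(g, []).append(e.element_id)
    genes = sorted(gene_links)
    if not genes:
        raise ValueError("design has no linked genes")

    samples = _sample_table(n_expr_samples)
    baseline = rng.normal(truth.expr_baseline_mean, truth.expr_baseline_sd,
                          size=len(genes))
    values = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        linked = gene_links[g]
        active_linked = [e for e in linked if ever_active.loc[e]]
        for si, s in enumerate(samples.index):
            tp = samples.loc[s, "time_point"]
            if active_linked:
                drive = float(
                    activity.loc[active_linked, tp].mean() - truth.mu_bg
                )
            else:
                drive = 0.0
            log2_rpkm = (
                baseline[gi]
                + truth.beta * drive
                + rng.normal(0.0, truth.expr_noise_sd)
            )
            values[gi, si] = np.exp2(log2_rpkm)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples.index)
    expr.attrs["samples"] = samples
    return expr


# ---------------------------------------------------------------------------
# TSV round-trip used by the counts module and the CLI
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | Path,
    barcode_map: pd.DataFrame,
    cm: CountMatrix,
    truth_table: pd.DataFrame | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    barcode_map.to_csv(outdir / "barcode_map.tsv", sep="\t", index=False)
    long = (
        cm.dna.stack().rename("dna_count").to_frame()
        .join(cm.rna.stack().rename("rna_count"))
        .reset_index()
    )
    long.columns = ["barcode", "sample_id", "dna_count", "rna_count"]
    long.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    cm.samples.reset_index().to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if truth_table is not None:
        truth_table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
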