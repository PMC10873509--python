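"""Two-component Gaussian background model for MPRA activity.

Even nucleotide-shuffled negative controls can show residual activity — TF
binding is probabilistic and shuffled sequence occasionally recreates
functional motifs — so the distribution of negative-control activities is
modelled as a sum of two Gaussians on the log2 scale: a background component
(lower mean) and a signal component (higher mean).  The background component
is the null distribution for activity calling; the gap between the two means,
mapped back to the linear scale, quantifies how much stronger "accidentally
active" sequences are than true background.

Two fit routes are provided:

* ``histogram_ls`` (primary): nonlinear least squares of the 5-parameter
  mixture density against the binned empirical density (scipy curve_fit with
  multi-start initialisation);
* ``em`` (cross-check): standard 2-component EM via scikit-learn, best of
  ``n_starts`` initialisations by log-likelihood.

Because the mixture parameters are estimated from the data, goodness-of-fit
p-values for the Kolmogorov–Smirnov and Anderson–Darling statistics are
obtained by parametric bootstrap (refit on each simulated sample) rather than
from the asymptotic null distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

_SIGMA_FLOOR = 1e-4


class FitError(RuntimeError):
    """Mixture fit failed to converge in every start."""


class DegenerateFitError(FitError):
    """A component's sd collapsed; the data look single-component."""


@dataclass(frozen=True)
class GaussianComponent:
    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside [0, 1]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def pdf(self, x):
        return self.weight * stats.norm.pdf(x, self.mean, self.sd)

    def cdf(self, x):
        return self.weight * stats.norm.cdf(x, self.mean, self.sd)


@dataclass(frozen=True)
class MixtureFit:
    """Background (lower-mean) + signal (higher-mean) Gaussian components."""

    background: GaussianComponent
    signal: GaussianComponent
    fit_method: str
    n_points: int
    gof: tuple[float, float, float, float] | None = None  # ks, ks_p, ad, ad_p

    def __post_init__(self) -> None:
        if abs(self.background.weight + self.signal.weight - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.background.mean > self.signal.mean:
            raise ValueError("background must be the lower-mean component")

    def pdf(self, x):
        return self.background.pdf(x) + self.signal.pdf(x)

    def cdf(self, x):
        return self.background.cdf(x) + self.signal.cdf(x)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        n_sig = rng.binomial(size, self.signal.weight)
        draws = np.concatenate([
            rng.normal(self.background.mean, self.background.sd, size - n_sig),
            rng.normal(self.signal.mean, self.signal.sd, n_sig),
        ])
        rng.shuffle(draws)
        return draws

    @property
    def signal_excess(self) -> float:
        return signal_excess(self)

    def is_degenerate(self, min_weight: float = 0.1, min_sep: float = 0.1) -> bool:
        """Heuristic: does the fit reduce to a single component?"""
        return (
            self.signal.weight < min_weight
            or self.background.weight < min_weight
            or (self.signal.mean - self.background.mean) < min_sep
        )

    def to_dict(self) -> dict[str, float]:
        d = {
            "w_bg": self.background.weight,
            "mu_bg": self.background.mean,
            "sd_bg": self.background.sd,
            "w_sig": self.signal.weight,
            "mu_sig": self.signal.mean,
            "sd_sig": self.signal.sd,
            "signal_excess": self.signal_excess,
            "n_points": self.n_points,
        }
        if self.gof is not None:
            d.update(zip(("ks_stat", "ks_p", "ad_stat", "ad_p"), self.gof))
        return d


_INV_SQRT_2PI = 0.3989422804014327


def _mixture_density(x, w, mu1, sd1, mu2, sd2):
    # inlined Gaussian pdf: curve_fit calls this thousands of times
    s1, s2 = abs(sd1), abs(sd2)
    g1 = _INV_SQRT_2PI / s1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
    g2 = _INV_SQRT_2PI / s2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    return w * g1 + (1 - w) * g2


def _mixture_jac(x, w, mu1, sd1, mu2, sd2):
    # analytic Jacobian of the mixture density wrt (w, mu1, sd1, mu2, sd2)
    s1, s2 = abs(sd1), abs(sd2)
    z1, z2 = (x - mu1) / s1, (x - mu2) / s2
    g1 = _INV_SQRT_2PI / s1 * np.exp(-0.5 * z1**2)
    g2 = _INV_SQRT_2PI / s2 * np.exp(-0.5 * z2**2)
    dmu1 = w * g1 * z1 / s1
    dmu2 = (1 - w) * g2 * z2 / s2
    dsd1 = np.sign(sd1) * w * g1 * (z1**2 - 1) / s1
    dsd2 = np.sign(sd2) * (1 - w) * g2 * (z2**2 - 1) / s2
    return np.column_stack([g1 - g2, dmu1, dsd1, dmu2, dsd2])


def _order_components(w, mu1, sd1, mu2, sd2, method, n) -> MixtureFit:
    comps = sorted(
        [(mu1, sd1, w), (mu2, sd2, 1.0 - w)], key=lambda c: c[0]
    )
    (mb, sb, wb), (ms, ss, ws) = comps
    if min(sb, ss) < _SIGMA_FLOOR:
        raise DegenerateFitError(
            f"component sd collapsed below {_SIGMA_FLOOR}; "
            "data may be single-component"
        )
    return MixtureFit(
        background=GaussianComponent(wb, mb, sb),
        signal=GaussianComponent(ws, ms, ss),
        fit_method=method,
        n_points=n,
    )


def _starts(values: np.ndarray, n_starts: int, rng: np.random.Generator):
    """Initial (w, mu1, sd1, mu2, sd2) vectors: one moment-based, rest random."""
    med = np.median(values)
    lo, hi = values[values <= med], values[values > med]
    sd_all = max(values.std(), 10 * _SIGMA_FLOOR)
    yield (0.5, lo.mean(), max(lo.std(), 0.25 * sd_all),
           hi.mean(), max(hi.std(), 0.25 * sd_all))
    q5, q95 = np.quantile(values, [0.05, 0.95])
    for _ in range(max(0, n_starts - 1)):
        m1, m2 = np.sort(rng.uniform(q5, q95, size=2))
        yield (
            rng.uniform(0.2, 0.8),
            m1, sd_all * rng.uniform(0.3, 1.2),
            m2, sd_all * rng.uniform(0.3, 1.2),
        )


def fit_mixture(
    values,
    method: str = "histogram_ls",
    n_bins: int | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> MixtureFit:
    """Fit the 2-component Gaussian mixture to activity values.

    ``histogram_ls`` bins the data (Freedman–Diaconis by default) and fits the
    mixture density to the bin densities by nonlinear least squares with
    ``n_starts`` initialisations, keeping the best sum of squares.  ``em``
    runs standard EM with ``n_starts`` initialisations, keeping the best
    log-likelihood.  Components are then ordered by mean: background = lower.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError(f"need >= 30 values, got {values.size}")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")

    if method == "em":
        return _fit_em(values, n_starts, seed)
    if method != "histogram_ls":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    if n_bins is None:
        edges = np.histogram_bin_edges(values, bins="fd")
        if len(edges) < 8:  # FD can under-bin small n; keep the fit determined
            edges = np.histogram_bin_edges(values, bins=8)
    else:
        edges = np.histogram_bin_edges(values, bins=n_bins)
    dens, edges = np.histogram(values, bins=edges, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])

    span = values.max() - values.min()
    bounds = (
        [0.0, values.min() - span, _SIGMA_FLOOR, values.min() - span, _SIGMA_FLOOR],
        [1.0, values.max() + span, 4 * span + 1, values.max() + span, 4 * span + 1],
    )
    best, best_sse, failures = None, np.inf, []
    for p0 in _starts(values, n_starts, rng):
        popt = None
        try:  # fast unbounded Levenberg–Marquardt first
            with warnings.catch_warnings():
                # the parameter covariance is never used
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                cand, _ = optimize.curve_fit(
                    _mixture_density, centres, dens, p0=p0, method="lm",
                    jac=_mixture_jac, maxfev=500,
                )
            # a weight slightly past [0, 1] is clipped; SSE re-scored below
            if (
                -0.05 <= cand[0] <= 1.05
                and min(abs(cand[2]), abs(cand[4])) > 2 * _SIGMA_FLOOR
            ):
                popt = np.array(cand)
                popt[0] = min(max(popt[0], 0.0), 1.0)
        except (RuntimeError, ValueError):
            pass
        if popt is None:  # lm failed or left the valid region: bounded refit
            x0 = np.clip(p0, np.array(bounds[0]) + 1e-9,
                         np.array(bounds[1]) - 1e-9)
            res = optimize.least_squares(
                lambda p: _mixture_density(centres, *p) - dens,
                jac=lambda p: _mixture_jac(centres, *p),
                x0=x0, bounds=bounds, max_nfev=100,
            )
            if not np.isfinite(res.x).all():
                failures.append("bounded fit diverged")
                continue
            popt = res.x  # best point found; SSE comparison filters bad starts
        popt = np.array([popt[0], popt[1], abs(popt[2]), popt[3], abs(popt[4])])
        if min(popt[2], popt[4]) <= 2 * _SIGMA_FLOOR:
            failures.append("component sd collapsed to the boundary")
            continue
        sse = float(np.sum((_mixture_density(centres, *popt) - dens) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        if failures and all("collapsed" in f for f in failures):
            raise DegenerateFitError(
                "component sd collapsed in every start; "
                "data may be single-component"
            )
        raise FitError(
            f"curve_fit failed in all {n_starts} starts; last errors: "
            + "; ".join(failures[-3:])
        )
    return _order_components(*best, method="histogram_ls", n=values.size)


def _fit_em(values: np.ndarray, n_starts: int, seed: int) -> MixtureFit:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_starts,
        random_state=seed,
        reg_covar=1e-10,
    ).fit(values.reshape(-1, 1))
    w = float(gm.weights_[0])
    mu1, mu2 = (float(m) for m in gm.means_.ravel())
    sd1, sd2 = (float(np.sqrt(c)) for c in gm.covariances_.ravel())
    return _order_components(w, mu1, sd1, mu2, sd2, method="em", n=values.size)


def fit_background(
    values,
    method: str = "histogram_ls",
    n_starts: int = 20,
    seed: int = 0,
) -> MixtureFit:
    """Background fit robust to effectively single-component data.

    Tries the 2-component mixture; if the fit is degenerate (tiny signal
    weight or near-coincident means) or collapses, falls back to a
    single-Gaussian background (sample mean/sd) with a token zero-weight
    signal component, so downstream calling always has a usable null.
    """
    values = np.asarray(values, dtype=float)
    try:
        fit = fit_mixture(values, method=method, n_starts=n_starts, seed=seed)
        if not fit.is_degenerate():
            return fit
    except FitError:
        pass
    mu, sd = float(values.mean()), float(values.std(ddof=1))
    bg = GaussianComponent(1.0, mu, sd)
    sig = GaussianComponent(0.0, mu + _SIGMA_FLOOR, sd)
    return MixtureFit(background=bg, signal=sig,
                      fit_method=f"{method}+single_gaussian_fallback",
                      n_points=values.size)


def signal_excess(fit: MixtureFit) -> float:
    """Fractional excess of the signal over the background on the linear scale.

    Activities live on log2 scale, so the components' geometric means on the
    linear RNA/DNA scale are 2^μ; the excess is 2^(μ_sig − μ_bg) − 1.
    """
    return float(2.0 ** (fit.signal.mean - fit.background.mean) - 1.0)


def ks_statistic(values, cdf) -> float:
    """One-sample Kolmogorov–Smirnov statistic against an arbitrary CDF."""
    return float(stats.kstest(values, cdf).statistic)


def ad_statistic(values, cdf) -> float:
    """Anderson–Darling A² statistic against a fully specified CDF."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    u = np.clip(cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def goodness_of_fit(
    values,
    fit: MixtureFit,
    n_boot: int = 999,
    seed: int = 0,
    refit_starts: int = 5,
) -> tuple[float, float, float, float]:
    """KS and Anderson–Darling GOF of ``values`` against the fitted mixture.

    p-values come from a parametric bootstrap: simulate ``n_boot`` samples of
    the same size from the fitted mixture, refit each with the same method,
    and compare the resulting statistics with the observed ones
    (p = (1 + #{boot ≥ obs}) / (n_boot + 1)).
    """
    import logging

    values = np.asarray(values, dtype=float)
    if n_boot < 99:
        logging.getLogger(__name__).warning(
            "n_boot=%d is small; bootstrap p-values will be coarse", n_boot
        )
    ks_obs = ks_statistic(values, fit.cdf)
    ad_obs = ad_statistic(values, fit.cdf)

    method = "em" if fit.fit_method.startswith("em") else "histogram_ls"
    rng = np.random.default_rng(seed)
    ks_ge = ad_ge = 0
    for _ in range(n_boot):
        sample = fit.rvs(values.size, rng)
        try:
            refit = fit_mixture(
                sample, method=method, n_starts=refit_starts,
                seed=int(rng.integers(2**31)),
            )
        except FitError:
            refit = fit  # rare; score against the original fit
        if ks_statistic(sample, refit.cdf) >= ks_obs:
            ks_ge += 1
        if ad_statistic(sample, refit.cdf) >= ad_obs:
            ad_ge += 1
    ks_p = (1 + ks_ge) / (n_boot + 1)
    ad_p = (1 + ad_ge) / (n_boot + 1)
    return ks_obs, ks_p, ad_obs, ad_p


def with_gof(values, fit: MixtureFit, n_boot: int = 999, seed: int = 0) -> MixtureFit:
    return replace(fit, gof=goodness_of_fit(values, fit, n_boot=n_boot, seed=seed))


def write_fit(fit: MixtureFit, path) -> None:
    """Serialise a fit as flat key/value text, 6-decimal fixed precision."""
    with open(path, "w") as fh:
        fh.write(f"fit_method\t{fit.fit_method}\n")
        for k, v in fit.to_dict().items():
            if isinstance(v, float):
                fh.write(f"{k}\t{v:.6f}\n")
            else:
                fh.write(f"{k}\t{v}\n")


def read_fit(path) -> MixtureFit:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            kv[k] = v
    bg = GaussianComponent(float(kv["w_bg"]), float(kv["mu_bg"]), float(kv["sd_bg"]))
    sig = GaussianComponent(float(kv["w_sig"]), float(kv["mu_sig"]),
                            float(kv["sd_sig"]))
    gof = None
    if "ks_stat" in kv:
        gof = tuple(float(kv[k]) for k in ("ks_stat", "ks_p", "ad_stat", "ad_p"))
    return MixtureFit(bg, sig, kv["fit_method"], int(float(kv["n_points"])), gof)
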