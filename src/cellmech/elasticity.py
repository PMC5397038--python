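"""Group-level aggregation of Young's moduli and group comparisons.

The aggregation follows the histogram-based protocol used for AFM elasticity
maps: build a density-normalized histogram of the accepted per-curve moduli,
fit a Gaussian density to the bin centres/heights, discard values outside
mean +/- 2 SD of that fit (the 95% band), then rebuild the histogram and
refit once.  Both pre- and post-trim parameters are reported; the post-trim
fitted mean/SD are the group summary.

Comparisons are a pooled-variance two-sample Student's t-test for two groups
(Welch available by flag) and one-way fixed-effects ANOVA for three or more.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GroupResult",
    "TestResult",
    "gaussian_trim_fit",
    "compare_two_groups",
    "compare_multi_groups",
]

log = logging.getLogger(__name__)


@dataclass
class GroupResult:
    """Trimmed-Gaussian summary of one group's per-curve moduli (kPa)."""

    group_label: str
    n_curves_initial: int
    n_curves_after_trim: int
    mean_E: float
    sd_E: float
    pre_trim_mean: float
    pre_trim_sd: float
    bin_edges: np.ndarray
    heights: np.ndarray
    trimmed_values: np.ndarray
    fit_fallback: bool = False

    def __post_init__(self) -> None:
        if self.n_curves_after_trim > self.n_curves_initial:
            raise ValueError("n_after_trim cannot exceed n_initial")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    significant: bool


def _gauss_density(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def _hist(values: np.ndarray, bin_rule):
    edges = np.histogram_bin_edges(values, bins=bin_rule)
    heights, edges = np.histogram(values, bins=edges, density=True)
    return edges, heights


def _fit_gaussian(values: np.ndarray, bin_rule) -> tuple[float, float, np.ndarray, np.ndarray, bool]:
    """Least-squares Gaussian-density fit to the normalized histogram.

    Initialized at the sample mean/SD; falls back to the sample statistics
    (with a warning) if the optimizer fails to converge.
    """
    m0, s0 = float(np.mean(values)), float(np.std(values, ddof=1))
    edges, heights = _hist(values, bin_rule)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = optimize.curve_fit(
            _gauss_density, centers, heights, p0=[m0, s0],
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
        mu, sigma = float(popt[0]), float(abs(popt[1]))
        return mu, sigma, edges, heights, False
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        log.warning("Gaussian histogram fit failed; using sample mean/SD")
        return m0, s0, edges, heights, True


def gaussian_trim_fit(
    E_values: Iterable[float],
    bin_rule: Union[str, int] = "fd",
    trim_sigmas: float = 2.0,
    group_label: str = "",
) -> GroupResult:
    """Histogram -> Gaussian fit -> +/- ``trim_sigmas``*SD trim -> single refit.

    Parameters
    ----------
    E_values : accepted per-curve Young's moduli in kPa (>= 20 values).
    bin_rule : any rule accepted by :func:`numpy.histogram_bin_edges`
        ("fd" default) or an explicit bin count for reproducibility.
    trim_sigmas : half-width of the retained band in fitted-SD units
        (2 keeps the central ~95%).
    """
    values = np.asarray(list(E_values), dtype=float)
    if values.size < 20:
        raise ValueError(f"need >= 20 values for a histogram fit, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite modulus values")

    if np.ptp(values) == 0:
        # all identical: SD = 0, nothing to trim or fit
        log.warning("all modulus values identical; trimming skipped")
        v = float(values[0])
        edges = np.array([v - 0.5, v + 0.5])
        return GroupResult(
            group_label=group_label, n_curves_initial=values.size,
            n_curves_after_trim=values.size, mean_E=v, sd_E=0.0,
            pre_trim_mean=v, pre_trim_sd=0.0,
            bin_edges=edges, heights=np.array([1.0]),
            trimmed_values=values, fit_fallback=True,
        )

    mu0, sd0, _, _, fb0 = _fit_gaussian(values, bin_rule)
    keep = np.abs(values - mu0) <= trim_sigmas * sd0
    trimmed = values[keep] if keep.sum() >= 20 else values
    mu1, sd1, edges, heights, fb1 = _fit_gaussian(trimmed, bin_rule)
    return GroupResult(
        group_label=group_label,
        n_curves_initial=int(values.size),
        n_curves_after_trim=int(trimmed.size),
        mean_E=mu1, sd_E=sd1,
        pre_trim_mean=mu0, pre_trim_sd=sd0,
        bin_edges=edges, heights=heights,
        trimmed_values=trimmed,
        fit_fallback=fb0 or fb1,
    )


def _as_values(group) -> np.ndarray:
    if isinstance(group, GroupResult):
        return np.asarray(group.trimmed_values, dtype=float)
    return np.asarray(group, dtype=float)


def compare_two_groups(a, b, equal_var: bool = True, alpha: float = 0.05) -> TestResult:
    """Two-sample two-tailed t-test on (trimmed) per-curve moduli.

    Accepts arrays or :class:`GroupResult` objects (uses their trimmed
    values).  Pooled-variance Student's test by default; ``equal_var=False``
    selects Welch.  Degenerate zero-variance inputs are resolved by the
    definition of the test rather than propagated as NaN.
    """
    av, bv = _as_values(a), _as_values(b)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(av) == 0 and np.var(bv) == 0:
        if float(np.mean(av)) == float(np.mean(bv)):
            return TestResult(0.0, av.size + bv.size - 2, 1.0, False)
        return TestResult(float("inf"), av.size + bv.size - 2, 0.0, True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(av, bv, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else av.size + bv.size - 2
    p = float(res.pvalue)
    return TestResult(float(res.statistic), df, p, p < alpha)


def compare_multi_groups(groups: Sequence, alpha: float = 0.05) -> TestResult:
    """One-way fixed-effects ANOVA across >= 3 groups of moduli."""
    arrays = [_as_values(g) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need >= 3 groups for one-way ANOVA")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has < 2 values")
    if all(np.var(g) == 0 for g in arrays):
        means = {float(np.mean(g)) for g in arrays}
        if len(means) == 1:
            return TestResult(0.0, len(arrays) - 1, 1.0, False)
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    p = float(res.pvalue)
    return TestResult(float(res.statistic), float(k - 1), p, p < alpha)
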