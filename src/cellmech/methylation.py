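"""Methylation-array region analysis.

Operates on probe x sample beta-value matrices (methylation fractions in
[0, 1]) with matching detection p-values and probe coordinates.  The
pipeline mirrors common 450K-style region workflows:

* probe QC — mask entries whose detection p-value exceeds 0.01 and drop
  probes failing in more than 30% of samples;
* quantile normalization across samples (rank-preserving, tie- and
  missing-value aware);
* hierarchical clustering of samples on the probes of a genomic region;
* per-sample binary promoter-methylation calls from a beta threshold;
* Fisher's exact two-tailed association between calls and clinical risk
  (low vs intermediate+high).

Coordinates are 1-based inclusive; promoter windows can be expressed as
offsets around a TSS on the annotated strand.  The genome build tag of the
probe annotation is checked against the region's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "BetaMatrix",
    "RegionSpec",
    "ClinicalTable",
    "ClusterResult",
    "FisherResult",
    "filter_probes",
    "quantile_normalize",
    "cluster_samples",
    "region_methylation_call",
    "fisher_association",
]

log = logging.getLogger(__name__)

RISK_LEVELS = ("low", "intermediate", "high")


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions with QC and coordinates.

    ``beta`` and ``detection_p`` share index (probe ids) and columns (sample
    ids); ``probe_info`` is indexed by probe id with columns ``chrom``,
    ``pos`` (1-based) and ``build``.
    """

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    probe_info: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(b, initial=0.0) < 0 or np.nanmax(b, initial=1.0) > 1:
                raise ValueError("beta values must lie in [0, 1] (or be missing)")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValueError("detection_p must share beta's index and columns")
        if self.probe_info is not None:
            missing = self.beta.index.difference(self.probe_info.index)
            if len(missing):
                raise ValueError(f"probe_info missing probes: {list(missing)[:5]}")
            if "pos" in self.probe_info and (self.probe_info["pos"] <= 0).any():
                raise ValueError("probe positions must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)


@dataclass(frozen=True)
class RegionSpec:
    """A genomic region, 1-based inclusive coordinates."""

    name: str
    chromosome: str
    start: int
    end: int
    build: str = "hg19"
    tss: Optional[int] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @classmethod
    def promoter_window(
        cls,
        name: str,
        chromosome: str,
        tss: int,
        strand: str = "+",
        upstream: int = -37,
        downstream: int = 333,
        build: str = "hg19",
    ) -> "RegionSpec":
        """Window expressed as offsets to the TSS on the annotated strand.

        ``upstream``/``downstream`` follow transcription direction (negative
        = before the TSS), so on the minus strand the genomic interval is
        mirrored.
        """
        if strand == "+":
            start, end = tss + upstream, tss + downstream
        else:
            start, end = tss - downstream, tss - upstream
        return cls(name=name, chromosome=chromosome, start=start, end=end,
                   build=build, tss=tss, strand=strand)


@dataclass
class ClinicalTable:
    """Sample id -> risk group (low / intermediate / high) and INSS stage."""

    table: pd.DataFrame  # index sample id; columns risk, inss_stage

    def __post_init__(self) -> None:
        if "risk" not in self.table.columns:
            raise ValueError("clinical table needs a 'risk' column")
        bad = self.table.loc[~self.table["risk"].isin(RISK_LEVELS)]
        if len(bad):
            raise ValueError(
                f"unknown risk label(s) for sample(s) {list(bad.index)[:5]}: "
                f"{sorted(set(bad['risk']))}"
            )

    def risk(self) -> pd.Series:
        return self.table["risk"]


def probes_in_region(m: BetaMatrix, region: RegionSpec) -> list[str]:
    if m.probe_info is None:
        raise ValueError("beta matrix carries no probe coordinates")
    info = m.probe_info.loc[m.beta.index]
    if "build" in info.columns:
        builds = set(info["build"].dropna().unique())
        if builds and builds != {region.build}:
            raise ValueError(
                f"genome build mismatch: probes {sorted(builds)} vs region {region.build}"
            )
    sel = (
        (info["chrom"].astype(str) == str(region.chromosome))
        & (info["pos"] >= region.start)
        & (info["pos"] <= region.end)
    )
    return list(info.index[sel])


def filter_probes(
    m: BetaMatrix, p_max: float = 0.01, max_fail_frac: float = 0.30
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Mask unreliable entries and drop frequently failing probes.

    An entry with detection p-value > ``p_max`` is set missing; a probe
    missing (for any reason) in more than ``max_fail_frac`` of samples is
    dropped.  Returns the filtered matrix and a per-probe report with the
    failure fraction and drop flag.
    """
    beta = m.beta.copy()
    if m.detection_p is not None:
        beta = beta.mask(m.detection_p > p_max)
    fail_frac = beta.isna().mean(axis=1)
    dropped = fail_frac > max_fail_frac
    report = pd.DataFrame({"fail_fraction": fail_frac, "dropped": dropped})
    keep = beta.index[~dropped]
    if len(keep) == 0:
        raise ValueError("all probes dropped by detection-p filtering")
    out = BetaMatrix(
        beta=beta.loc[keep],
        detection_p=None if m.detection_p is None else m.detection_p.loc[keep],
        probe_info=m.probe_info,  # annotation covers a superset; unchanged
    )
    return out, report


def quantile_normalize(m: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the cohort-average value distribution.

    Each sample's non-missing values are replaced by the mean quantile
    function of all samples evaluated at the value's (average, tie-aware)
    rank quantile; within-sample rank order is preserved and missing entries
    stay missing.  With no missing data and no ties this is the classic
    sorted-row-means construction.
    """
    beta = m.beta
    if beta.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    grids = []
    for s in beta.columns:
        v = beta[s].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            raise ValueError(f"sample {s!r} has no usable values")
        srt = np.sort(obs)
        p = (np.arange(obs.size) + 0.5) / obs.size
        grids.append((p, srt))

    # cohort-average quantile function on a fine common grid
    n_grid = max(len(srt) for _, srt in grids)
    pg = (np.arange(n_grid) + 0.5) / n_grid
    ref = np.mean([np.interp(pg, p, srt) for p, srt in grids], axis=0)

    out = beta.copy()
    for s in beta.columns:
        v = beta[s].to_numpy(dtype=float)
        mask = ~np.isnan(v)
        obs = v[mask]
        # average ranks for ties -> tied values map to identical quantiles
        ranks = stats.rankdata(obs, method="average")
        q = (ranks - 0.5) / obs.size
        out.loc[mask, s] = np.interp(q, pg, ref)
    return BetaMatrix(beta=out, detection_p=m.detection_p, probe_info=m.probe_info)


@dataclass
class ClusterResult:
    sample_order: list[str]
    linkage: np.ndarray
    samples: list[str]

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")


def cluster_samples(
    m: BetaMatrix,
    region: RegionSpec,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of samples on region-restricted beta vectors.

    Missing entries are imputed with the probe mean for distance computation
    only.  Samples are processed in sorted-label order so ties in merge
    heights resolve deterministically.
    """
    probes = probes_in_region(m, region)
    if not probes:
        raise ValueError(f"region {region.name} contains no probes")
    samples = sorted(m.beta.columns)
    X = m.beta.loc[probes, samples].T.to_numpy(dtype=float)
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    Z = hierarchy.linkage(X, method=method, metric=metric)
    order = [samples[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(sample_order=order, linkage=Z, samples=samples)


def region_methylation_call(
    m: BetaMatrix,
    region: RegionSpec,
    beta_threshold: float = 0.3,
    min_probes: int = 1,
) -> pd.Series:
    """Binary per-sample methylation call for a region.

    A sample is called methylated when at least ``min_probes`` probes inside
    the region show beta >= ``beta_threshold``.  Missing entries never count
    toward the threshold.
    """
    probes = probes_in_region(m, region)
    if not probes:
        raise ValueError(f"region {region.name} contains no probes")
    sub = m.beta.loc[probes]
    n_meth = (sub >= beta_threshold).sum(axis=0)
    calls = n_meth >= min_probes
    calls.name = f"methylated_{region.name}"
    return calls


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]
    significant: bool


def fisher_association(
    calls: pd.Series,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> FisherResult:
    """Fisher's exact two-tailed test of methylation call vs clinical risk.

    Risk is dichotomized low vs intermediate+high.  The two-tailed p-value
    sums hypergeometric probabilities of all tables no more likely than the
    observed one (the minimum-likelihood convention); the odds ratio is the
    conditional maximum-likelihood estimate.
    """
    risk = clinical.risk()
    common = calls.index.intersection(risk.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between calls and clinical table")
    c = calls.loc[common].astype(bool)
    elevated = risk.loc[common].isin(("intermediate", "high"))
    a = int((c & elevated).sum())
    b = int((c & ~elevated).sum())
    cc = int((~c & elevated).sum())
    d = int((~c & ~elevated).sum())
    table = [[a, b], [cc, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    try:
        orr = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    except ValueError:  # degenerate margins
        orr = float("nan")
    p = float(p)
    return FisherResult(odds_ratio=orr, pvalue=p,
                        table=((a, b), (cc, d)), significant=p < alpha)
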