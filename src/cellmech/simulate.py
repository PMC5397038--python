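"""Synthetic data generators for every pipeline stage.

The generators encode the statistical structure the analyses assume, so the
whole package is testable without instrument files or array downloads:

* force curves follow the pyramidal contact law within the parabolic regime
  and switch to an additional linear (substrate-stiffening) response beyond
  a depth threshold; cantilever deflection carries additive Gaussian noise;
* an AFM experiment is a cell -> point -> curve hierarchy whose modulus
  varies at all three levels; the three variance components sum to the
  group's nominal histogram SD;
* the methylation cohort reproduces a 105-sample structure: a small subset
  of promoter-methylated samples, a bimodal gene-body CpG pair splitting the
  cohort in two, risk labels with a configurable association to gene-body
  status, and sporadic detection failures;
* bisulphite clones are converted reads with a configurable conversion
  efficiency at non-CpG cytosines.

All generators are pure functions of (spec, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .bisulfite import CloneSet, find_cpg_positions
from .mechanics import CurveMeta, ForceCurve, Probe, hertz_force
from .methylation import BetaMatrix, ClinicalTable, RegionSpec
from .presets import LMNA_REGION

__all__ = [
    "AfmGroupSpec",
    "CohortSpec",
    "CohortResult",
    "simulate_force_curve",
    "simulate_afm_experiment",
    "simulate_beta_cohort",
    "simulate_bisulphite_clones",
]

#: fractions of the nominal group SD assigned to the cell / point levels;
#: the remainder (in variance) varies curve-to-curve.  See docs/methods.md.
SD_FRACTION_CELL = 0.15
SD_FRACTION_POINT = 0.30

_E_FLOOR = 0.01  # kPa; truncation floor keeping moduli physical


@dataclass(frozen=True)
class AfmGroupSpec:
    """Generating conditions for one experimental group of force curves.

    The per-curve modulus is ``E = E_cell + dE_point + dE_curve`` with the
    three centred Gaussian components' SDs given below, truncated at a small
    positive floor.  ``deflection_noise_sd`` is the effective (post
    instrument-averaging) noise of the recorded deflection in nm.
    Curves indent to ``max_depth`` nm; beyond ``substrate_onset`` the curve
    leaves the parabolic regime and continues linearly with
    ``substrate_stiffening`` times the contact-law slope at the onset depth,
    emulating the stiff support felt under a thin cell region.  The
    stiffening is relative to the cell's own stiffness (bottom-effect
    corrections scale with the modulus), so soft and stiff groups are
    contaminated comparably; 0 disables the substrate regime entirely (the
    contact law holds at all depths) and the default 3 triples the local
    slope beyond the onset.
    """

    label: str
    e_mean: float
    e_sd_between_cells: float
    e_sd_between_points: float = 0.0
    e_sd_between_curves: float = 0.0
    n_cells: int = 10
    points_per_cell: int = 20
    curves_per_point: int = 10
    deflection_noise_sd: float = 0.003
    substrate_onset: float = 300.0
    substrate_stiffening: float = 3.0
    contact_z0_range: tuple[float, float] = (400.0, 600.0)
    z_step: float = 3.0
    max_depth: float = 600.0
    region: str = "lamellar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.e_mean <= 0:
            raise ValueError("e_mean must be > 0")
        for name in ("e_sd_between_cells", "e_sd_between_points",
                     "e_sd_between_curves", "deflection_noise_sd",
                     "substrate_stiffening"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_cells", "points_per_cell", "curves_per_point"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.z_step > 0 and self.max_depth > 0):
            raise ValueError("z_step and max_depth must be > 0")
        if not (0 <= self.contact_z0_range[0] <= self.contact_z0_range[1]):
            raise ValueError("contact_z0_range must be ordered and non-negative")

    @classmethod
    def from_reported(
        cls, label: str, mean: float, sd: float, region: str = "lamellar",
        seed: int = 0, **overrides,
    ) -> "AfmGroupSpec":
        """Build a spec whose pooled per-curve SD equals a reported histogram SD.

        The reported spread is split into cell-, point- and curve-level
        components (SD fractions 0.15 / 0.30 / remainder-in-variance).
        """
        f_cell, f_point = SD_FRACTION_CELL, SD_FRACTION_POINT
        f_curve = math.sqrt(max(1.0 - f_cell**2 - f_point**2, 0.0))
        return cls(
            label=label, e_mean=mean,
            e_sd_between_cells=f_cell * sd,
            e_sd_between_points=f_point * sd,
            e_sd_between_curves=f_curve * sd,
            region=region, seed=seed, **overrides,
        )


def _curve_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_force_curve(
    E_true: float,
    probe: Probe,
    spec: AfmGroupSpec,
    seed,
    meta: Optional[CurveMeta] = None,
) -> ForceCurve:
    """Forward-model one approach curve for a known modulus.

    A uniform indentation grid h in [0, max_depth] produces the true force
    F(h) (contact law, plus the linear substrate term beyond the onset
    depth), the true deflection d = F/k and the piezo position
    z = z0 + h + d; a pre-contact baseline precedes contact at z0 (drawn
    uniformly from ``contact_z0_range``).  Gaussian noise is added to the
    recorded deflection only.
    """
    rng = _curve_rng(seed)
    z0 = float(rng.uniform(*spec.contact_z0_range))

    z_base = np.arange(0.0, z0, spec.z_step)
    d_base = np.zeros_like(z_base)

    h = np.arange(0.0, spec.max_depth + spec.z_step / 2, spec.z_step)
    force = hertz_force(E_true, h, probe)
    over = h > spec.substrate_onset
    if np.any(over) and spec.substrate_stiffening > 0:
        # replace the Hertzian continuation with a linear regime whose slope
        # is `substrate_stiffening` x the contact-law slope at onset
        f_onset = float(hertz_force(E_true, spec.substrate_onset, probe))
        slope_onset = 2.0 * f_onset / spec.substrate_onset
        force[over] = f_onset + spec.substrate_stiffening * slope_onset * (
            h[over] - spec.substrate_onset
        )
    d_true = force / probe.spring_constant  # nN / (N/m) = nm
    z_ind = z0 + h + d_true

    z = np.concatenate([z_base, z_ind])
    d = np.concatenate([d_base, d_true])
    if spec.deflection_noise_sd > 0:
        d = d + rng.normal(0.0, spec.deflection_noise_sd, size=d.size)
    return ForceCurve(z=z, deflection=d, meta=meta or CurveMeta(group=spec.label, region=spec.region))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float = _E_FLOOR, max_tries: int = 1000) -> float:
    if sd == 0:
        if mean <= floor:
            raise ValueError("mean below truncation floor with zero SD")
        return mean
    for _ in range(max_tries):
        x = float(rng.normal(mean, sd))
        if x > floor:
            return x
    raise ValueError("non-positive truncation exhaustion")


def simulate_afm_experiment(
    groups: Sequence[AfmGroupSpec], probe: Probe
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Generate the full cell -> point -> curve hierarchy for each group.

    Returns the labelled curves and a truth table with the generating
    modulus of every curve (group, cell, point, curve, E_true).
    """
    if not groups:
        raise ValueError("need >= 1 group spec")
    curves: list[ForceCurve] = []
    truth_rows = []
    for spec in groups:
        ss = np.random.SeedSequence(spec.seed)
        rng = np.random.default_rng(ss)
        n_curves = spec.n_cells * spec.points_per_cell * spec.curves_per_point
        curve_seeds = ss.spawn(n_curves)
        i = 0
        for ci in range(spec.n_cells):
            e_cell = _truncated_normal(rng, spec.e_mean, spec.e_sd_between_cells)
            for pi in range(spec.points_per_cell):
                e_point = _truncated_normal(rng, e_cell, spec.e_sd_between_points)
                for ki in range(spec.curves_per_point):
                    e_curve = _truncated_normal(rng, e_point, spec.e_sd_between_curves)
                    meta = CurveMeta(group=spec.label, cell=ci, point=pi,
                                     curve=ki, region=spec.region)
                    curves.append(
                        simulate_force_curve(e_curve, probe, spec,
                                             curve_seeds[i], meta=meta)
                    )
                    truth_rows.append(
                        {"group": spec.label, "cell": ci, "point": pi,
                         "curve": ki, "E_true": e_curve}
                    )
                    i += 1
    return curves, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# methylation cohort
# ---------------------------------------------------------------------------

#: synthetic hg19 placements for the named probes: the three promoter probes
#: sit inside the -37..+333 window around the LMNA TSS used by the package;
#: the gene-body pair sits downstream within the locus.  Positions are
#: invented (the probe ids are real, their coordinates here are not).
DEFAULT_REGION_PROBES: dict[str, int] = {
    "cg23922289": 156_084_520,
    "cg20018234": 156_084_640,
    "cg04317543": 156_084_780,
    "cg08881019": 156_090_000,
    "cg03946955": 156_090_100,
}

PROMOTER_PROBES = ("cg23922289", "cg20018234", "cg04317543")
GENE_BODY_PROBES = ("cg08881019", "cg03946955")


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for the synthetic methylation-array cohort.

    Defaults emulate a 105-patient cohort in which exactly three samples are
    methylated at the promoter probes, the gene-body CpG pair is bimodal and
    splits the cohort into two clusters, and gene-body methylation is
    associated with intermediate/high clinical risk with odds
    ``risk_association_odds`` (1 = no association).  ``n_background_probes``
    additional probes with per-probe mean levels spread over
    ``background_level_range`` fill the rest of the locus so the full region
    carries 25 probes by default.
    """

    n_samples: int = 105
    n_promoter_methylated: int = 3
    n_background_probes: int = 20
    unmeth_level: float = 0.05
    meth_level: float = 0.80
    background_level_range: tuple[float, float] = (0.15, 0.90)
    gene_body_low: float = 0.10
    gene_body_high: float = 0.85
    gene_body_high_fraction: float = 0.5
    concentration: float = 50.0
    detection_fail_rate: float = 0.01
    risk_association_odds: float = 6.0
    p_elevated_risk_unmeth: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoter_methylated > self.n_samples:
            raise ValueError("n_promoter_methylated cannot exceed n_samples")
        if not (0 <= self.detection_fail_rate < 1):
            raise ValueError("detection_fail_rate must be in [0, 1)")
        if self.concentration <= 0 or self.risk_association_odds <= 0:
            raise ValueError("concentration and odds must be > 0")


@dataclass
class CohortResult:
    """Synthetic cohort plus its generating truth."""

    beta: BetaMatrix
    clinical: ClinicalTable
    promoter_methylated: list[str]
    gene_body_high: list[str]


def _beta_draw_vec(rng: np.random.Generator, means: np.ndarray, conc: float) -> np.ndarray:
    return rng.beta(means * conc, (1.0 - means) * conc)


def simulate_beta_cohort(spec: CohortSpec) -> CohortResult:
    """Draw the probe x sample beta matrix, detection p-values and clinic."""
    rng = np.random.default_rng(spec.seed)
    samples = [f"NB{i+1:03d}" for i in range(spec.n_samples)]

    probes = dict(DEFAULT_REGION_PROBES)
    span = LMNA_REGION.end - 156_085_500
    background_means: dict[str, float] = {}
    # probe-specific background levels span low to high methylation so each
    # sample's value distribution is a continuum (as on a real locus) and
    # quantile normalization cannot shunt low promoter values onto a
    # high-methylation reference rank
    levels = np.linspace(*spec.background_level_range, max(spec.n_background_probes, 1))
    for j in range(spec.n_background_probes):
        pos = 156_085_500 + int(round(j * span / max(spec.n_background_probes - 1, 1)))
        pid = f"cg9{j:07d}"
        probes[pid] = pos
        background_means[pid] = float(levels[j])
    probe_ids = list(probes)

    meth_samples = sorted(
        rng.choice(spec.n_samples, size=spec.n_promoter_methylated, replace=False)
    )
    meth_set = {samples[i] for i in meth_samples}
    n_high = int(round(spec.gene_body_high_fraction * spec.n_samples))
    high_idx = sorted(rng.choice(spec.n_samples, size=n_high, replace=False))
    high_set = {samples[i] for i in high_idx}

    probe_index = pd.Index(probe_ids, name="probe_id")
    beta = pd.DataFrame(index=probe_index, columns=samples, dtype=float)
    for pid in probe_ids:
        if pid in PROMOTER_PROBES:
            means = np.array([
                spec.meth_level if s in meth_set else spec.unmeth_level
                for s in samples
            ])
        elif pid in GENE_BODY_PROBES:
            means = np.array([
                spec.gene_body_high if s in high_set else spec.gene_body_low
                for s in samples
            ])
        else:
            means = np.full(spec.n_samples, background_means[pid])
        beta.loc[pid] = _beta_draw_vec(rng, means, spec.concentration)

    fail = rng.random((len(probe_ids), spec.n_samples)) < spec.detection_fail_rate
    detp = np.where(fail,
                    rng.uniform(0.02, 1.0, size=fail.shape),
                    rng.uniform(0.0, 0.005, size=fail.shape))
    detection_p = pd.DataFrame(detp, index=probe_index, columns=samples)

    probe_info = pd.DataFrame(
        {"chrom": "chr1", "pos": [probes[p] for p in probe_ids], "build": "hg19"},
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # risk: P(elevated | gene-body high) from the odds parameter
    p0 = spec.p_elevated_risk_unmeth
    odds1 = spec.risk_association_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    risks = []
    stages = []
    for s in samples:
        p_elev = p1 if s in high_set else p0
        if rng.random() < p_elev:
            risk = "intermediate" if rng.random() < 0.5 else "high"
            stage = rng.choice(["3", "4"])
        else:
            risk = "low"
            stage = rng.choice(["1", "2", "4S"])
        risks.append(risk)
        stages.append(stage)
    clinical = ClinicalTable(pd.DataFrame(
        {"risk": risks, "inss_stage": stages},
        index=pd.Index(samples, name="sample"),
    ))

    return CohortResult(
        beta=BetaMatrix(beta=beta, detection_p=detection_p, probe_info=probe_info),
        clinical=clinical,
        promoter_methylated=sorted(meth_set),
        gene_body_high=sorted(high_set),
    )


# ---------------------------------------------------------------------------
# bisulphite clones
# ---------------------------------------------------------------------------

def simulate_bisulphite_clones(
    reference: str,
    pattern,
    conversion_efficiency: float = 1.0,
    seed: int = 0,
) -> CloneSet:
    """Generate converted clone reads from a clone x CpG methylation pattern.

    Non-CpG cytosines convert to T with probability
    ``conversion_efficiency`` (independently per site and clone); CpG
    cytosines stay C exactly when the pattern marks them methylated and read
    T otherwise.  ``pattern`` is a 2-D boolean array or DataFrame whose
    columns match the reference's CpG sites in order.
    """
    ref = reference.upper()
    if set(ref) - set("ACGT"):
        raise ValueError("reference contains non-ACGT characters")
    cpg_positions = find_cpg_positions(ref)
    if not cpg_positions:
        raise ValueError("reference contains no CpG site")
    pat = np.asarray(pattern, dtype=bool)
    if pat.ndim != 2 or pat.shape[1] != len(cpg_positions):
        raise ValueError(
            f"pattern must be n_clones x {len(cpg_positions)} (CpG count), got {pat.shape}"
        )
    if not (0 <= conversion_efficiency <= 1):
        raise ValueError("conversion_efficiency must be in [0, 1]")

    rng = np.random.default_rng(seed)
    cpg = set(cpg_positions)
    names = (
        list(pattern.index) if isinstance(pattern, pd.DataFrame)
        else [f"clone_{i+1:02d}" for i in range(pat.shape[0])]
    )
    clones: dict[str, str] = {}
    for row, name in zip(pat, names):
        seq = list(ref)
        meth_at = {p: m for p, m in zip(cpg_positions, row)}
        for i, base in enumerate(ref, start=1):
            if base != "C":
                continue
            if i in cpg:
                if not meth_at[i]:
                    seq[i - 1] = "T"
            elif rng.random() < conversion_efficiency:
                seq[i - 1] = "T"
        clones[name] = "".join(seq)
    return CloneSet(reference=ref, clones=clones, cpg_positions=cpg_positions)
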