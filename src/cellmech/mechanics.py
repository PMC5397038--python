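"""Contact mechanics for pyramidal AFM nanoindentation.

Converts instrument signals (piezo extension ``z``, cantilever deflection
``d``) into force and indentation depth, and implements the Hertz/Sneddon
contact relation for a blunted four-sided pyramid,

    F(h) = [4 tan(alpha) / (pi^{3/2} (1 - nu^2))] * E * h**2,

where ``alpha`` is the effective half-angle of the pyramid, ``nu`` the sample
Poisson ratio and ``E`` the Young's modulus.  Units are fixed internally:
nanometres for lengths, nanonewtons for forces, kilopascals for moduli;
conversions happen only at I/O boundaries.

The quadratic force-depth law means an unconstrained second-order polynomial
fit of a force-indentation segment estimates ``E`` through its quadratic
coefficient alone; contact-point misplacement moves only the linear and
constant terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Probe",
    "CurveMeta",
    "ForceCurve",
    "IndentationSegment",
    "ModulusEstimate",
    "deflection_to_force",
    "indentation_depth",
    "hertz_force",
    "modulus_from_curvature",
]

#: kPa * nm^2 -> nN  (1 kPa = 1e3 N/m^2; 1 nm^2 = 1e-18 m^2; 1 nN = 1e-9 N)
KPA_NM2_TO_NN = 1e-6

REGION_LABELS = ("perinuclear", "lamellar", "other")


@dataclass(frozen=True)
class Probe:
    """Cantilever/tip physical parameters.

    Parameters
    ----------
    spring_constant : float
        Cantilever spring constant ``k`` in N/m (thermal-tune calibrated on
        the instrument; an input here).
    half_angle : float
        Effective pyramid half-angle ``alpha`` in degrees, ``0 < alpha < 90``.
        There is no universal default — it is a property of the tip; 35 deg
        is a typical manufacturer value for soft-cell probes.
    poisson : float
        Sample Poisson ratio ``nu`` in [0, 0.5]; 0.5 models an incompressible
        cytoplasm.
    geometry_constant_override : float, optional
        Replaces the default dimensionless tip-geometry factor
        ``4 tan(alpha) / pi^{3/2}`` so alternative pyramidal conventions
        (e.g. Bilodeau ``0.7453 tan(alpha)``, cone ``2/pi tan(alpha)``) can
        be selected; the ``1/(1 - nu^2)`` material factor is always applied.
    """

    spring_constant: float
    half_angle: float
    poisson: float = 0.5
    geometry_constant_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.spring_constant > 0):
            raise ValueError(f"spring_constant must be > 0, got {self.spring_constant}")
        if not (0 < self.half_angle < 90):
            raise ValueError(f"half_angle must be in (0, 90) degrees, got {self.half_angle}")
        if not (0 <= self.poisson <= 0.5):
            raise ValueError(f"poisson must be in [0, 0.5], got {self.poisson}")

    def geometry_constant(self) -> float:
        """Full prefactor ``C`` such that F[nN] = C * E[kPa] * h[nm]^2 * 1e-6."""
        if self.geometry_constant_override is not None:
            tip = self.geometry_constant_override
        else:
            tip = 4.0 * math.tan(math.radians(self.half_angle)) / math.pi**1.5
        return tip / (1.0 - self.poisson**2)


@dataclass(frozen=True)
class CurveMeta:
    """Identity of one force curve within an experiment."""

    group: str = ""
    cell: int = 0
    point: int = 0
    curve: int = 0
    region: str = "other"

    def __post_init__(self) -> None:
        if self.region not in REGION_LABELS:
            raise ValueError(
                f"region must be one of {REGION_LABELS}, got {self.region!r}"
            )

    @property
    def curve_id(self) -> str:
        return f"{self.group}/c{self.cell}/p{self.point}/k{self.curve}"


@dataclass
class ForceCurve:
    """Raw approach curve: piezo extension vs cantilever deflection, in nm."""

    z: np.ndarray
    deflection: np.ndarray
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.ndim != 1 or self.deflection.ndim != 1:
            raise ValueError("z and deflection must be 1-D")
        if self.z.size != self.deflection.size:
            raise ValueError(
                f"curve {self.meta.curve_id}: z and deflection lengths differ "
                f"({self.z.size} vs {self.deflection.size})"
            )
        if self.z.size < 16:
            raise ValueError(f"curve {self.meta.curve_id}: needs >= 16 samples")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.deflection))):
            raise ValueError(f"curve {self.meta.curve_id}: non-finite values")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError(f"curve {self.meta.curve_id}: z not strictly increasing")

    def __len__(self) -> int:
        return self.z.size


@dataclass
class IndentationSegment:
    """Contact-referenced indentation/force series (h in nm, force in nN)."""

    h: np.ndarray
    force: np.ndarray
    contact_z: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.h.size != self.force.size:
            raise ValueError("h and force lengths differ")
        if self.h.size and (self.h[0] != 0.0 or np.any(self.h < 0) or np.any(np.diff(self.h) < 0)):
            raise ValueError("h must start at 0 and be non-negative, non-decreasing")


@dataclass
class ModulusEstimate:
    """Per-curve Young's modulus with fit quality.

    ``coefficients`` are the fitted polynomial terms (quadratic a2 in nN/nm^2,
    linear a1 in nN/nm, constant a0 in nN).  ``accepted`` reflects both a
    physical curvature (a2 > 0) and the r^2 quality gate; ``reason`` explains
    a rejection.
    """

    young_modulus: float
    r2: float
    coefficients: tuple[float, float, float]
    accepted: bool
    curve_ref: CurveMeta
    reason: str = ""


def deflection_to_force(deflection, probe: Probe):
    """Hooke's law F = k d, elementwise; nm deflection -> nN force.

    N/m times nm is nN, so no numeric conversion factor is needed.
    """
    d = np.asarray(deflection, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite deflection values")
    return probe.spring_constant * d


def indentation_depth(z, deflection, contact_z: float, contact_deflection: float):
    """Indentation depth h = (z - contact_z) - (deflection - contact_deflection).

    The tip penetrates by whatever part of the piezo travel past contact is
    not taken up by cantilever bending.  Values for samples before contact
    come out negative; callers exclude them when building segments.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(deflection, dtype=float)
    lo, hi = np.min(z), np.max(z)
    if not (lo <= contact_z <= hi):
        raise ValueError(
            f"contact_z={contact_z} outside curve z range [{lo}, {hi}]"
        )
    return (z - contact_z) - (d - contact_deflection)


def hertz_force(young_modulus: float, h, probe: Probe):
    """Pyramidal-indenter contact force F = C(alpha, nu) * E * h^2, in nN.

    ``young_modulus`` in kPa, ``h`` in nm (scalar or array, >= 0).
    """
    if not (young_modulus > 0):
        raise ValueError(f"young_modulus must be > 0, got {young_modulus}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth h must be >= 0")
    C = probe.geometry_constant()
    return C * young_modulus * h**2 * KPA_NM2_TO_NN


def modulus_from_curvature(quadratic_coefficient: float, probe: Probe) -> float:
    """Invert the contact law: E[kPa] from the fitted a2 [nN/nm^2].

    Exact inverse of :func:`hertz_force`'s curvature.  A non-positive
    curvature has no physical modulus and raises; the fitting layer converts
    that condition into a rejected estimate instead of propagating the error.
    """
    if not (quadratic_coefficient > 0):
        raise ValueError(
            f"quadratic coefficient must be > 0 for a physical modulus, "
            f"got {quadratic_coefficient}"
        )
    return quadratic_coefficient / (probe.geometry_constant() * KPA_NM2_TO_NN)
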