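"""Batch force-curve processing: contact detection, windowing, fitting, QC.

Each approach curve passes through four stages:

1. contact-point detection — a straight baseline is fitted to the earliest
   part of the approach; contact is the first sustained excursion of the
   deflection above the baseline noise band, refined by intersecting the
   baseline with a local polynomial fit of the rising flank;
2. segment extraction — samples with indentation depth 0 <= h <= 300 nm
   (default) are kept, restricting the fit to the parabolic contact regime
   and away from the substrate-dominated linear regime at depth;
3. a second-order polynomial fit F = a2 h^2 + a1 h + a0 whose curvature a2
   yields the Young's modulus;
4. quality control — curves with r^2 below 0.99 (default) or non-physical
   curvature are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mechanics import (
    CurveMeta,
    ForceCurve,
    IndentationSegment,
    ModulusEstimate,
    Probe,
    deflection_to_force,
    indentation_depth,
    modulus_from_curvature,
)

_EMPTY_META = CurveMeta()

__all__ = [
    "FitConfig",
    "ContactDetectionError",
    "SegmentError",
    "QCError",
    "detect_contact_point",
    "extract_segment",
    "fit_modulus",
    "qc_filter",
    "process_curve",
    "process_curves",
]

log = logging.getLogger(__name__)

# rejection reasons used across the pipeline; qc_filter partitions on these
REASON_NO_CONTACT = "no contact detected"
REASON_SHORT = "insufficient indentation"
REASON_CURVATURE = "non-physical curvature"
REASON_DEGENERATE = "degenerate segment"
REASON_LOW_R2 = "low r2"


class ContactDetectionError(RuntimeError):
    pass


class SegmentError(RuntimeError):
    pass


class QCError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the per-curve pipeline.

    max_indentation : nm, depth of the fitting window (300 by default — the
        parabolic part of the curve, chosen to avoid the substrate effect).
    r2_min : acceptance threshold on the squared Pearson correlation between
        observed and fitted force (0.99 by default).
    baseline_fraction : fraction of the earliest approach samples used to fit
        the pre-contact baseline line.
    contact_threshold_sigmas : multiples of the baseline residual SD the
        deflection must exceed to count as contact.
    min_segment_samples : minimum samples inside the window for a fittable
        segment.
    min_modulus : kPa; fits whose curvature implies a modulus below this are
        treated as non-physical (a vanishing quadratic term means the force
        is not parabolic, i.e. the contact model does not apply).
    """

    max_indentation: float = 300.0
    r2_min: float = 0.99
    baseline_fraction: float = 0.3
    contact_threshold_sigmas: float = 3.0
    min_segment_samples: int = 8
    min_modulus: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.max_indentation > 0):
            raise ValueError("max_indentation must be > 0")
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        if not (0 < self.baseline_fraction < 1):
            raise ValueError("baseline_fraction must be in (0, 1)")
        if not (self.contact_threshold_sigmas > 0):
            raise ValueError("contact_threshold_sigmas must be > 0")


def _baseline_fit(curve: ForceCurve, config: FitConfig):
    """Fit the pre-contact baseline line; returns (slope, intercept, resid_sd)."""
    n_base = max(8, int(round(config.baseline_fraction * len(curve))))
    if len(curve) < n_base or n_base < 8:
        raise ContactDetectionError(
            f"curve {curve.meta.curve_id}: too short for baseline estimation"
        )
    zb = curve.z[:n_base]
    db = curve.deflection[:n_base]
    slope, intercept = np.polyfit(zb, db, 1)
    resid = db - (slope * zb + intercept)
    # ddof=2: two parameters estimated
    resid_sd = float(np.sqrt(np.sum(resid**2) / max(len(resid) - 2, 1)))
    return float(slope), float(intercept), resid_sd


def detect_contact_point(curve: ForceCurve, config: FitConfig) -> tuple[float, float]:
    """Locate the piezo position where the tip first touches the surface.

    Returns ``(contact_z, contact_deflection)``, the latter being the
    baseline prediction at contact.  Raises :class:`ContactDetectionError`
    when the deflection never rises convincingly above the baseline band.
    """
    slope, intercept, resid_sd = _baseline_fit(curve, config)
    # noise floor: avoid a zero threshold on noise-free synthetic curves
    sigma = max(resid_sd, 1e-12)
    excess = curve.deflection - (slope * curve.z + intercept)
    above = excess > config.contact_threshold_sigmas * sigma

    # first index that starts a sustained run (3 consecutive samples above,
    # or above through the end of the curve) — guards against single spikes
    run = 3
    idx = None
    for i in np.flatnonzero(above):
        j = min(i + run, len(above))
        if above[i:j].all():
            idx = int(i)
            break
    if idx is None:
        raise ContactDetectionError(
            f"no contact detected in curve {curve.meta.curve_id}"
        )

    # refine: the contact-law rise is parabolic with apex at the contact
    # point, so sqrt(excess) is linear in z on the flank; the zero crossing
    # of a straight-line fit locates contact.  This linearization is far
    # better conditioned under noise than intersecting the parabola itself.
    contact_z = curve.z[idx]
    w = slice(idx, min(idx + 25, len(curve)))
    zw, ew = curve.z[w], excess[w]
    if zw.size >= 5:
        try:
            s1, s0 = np.polyfit(zw, np.sqrt(np.clip(ew, 0.0, None)), 1)
            if s1 > 0:
                crossing = -s0 / s1
                if curve.z[0] <= crossing <= curve.z[idx]:
                    contact_z = float(crossing)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            pass
    contact_deflection = float(slope * contact_z + intercept)
    return float(contact_z), contact_deflection


def extract_segment(
    curve: ForceCurve,
    contact: tuple[float, float],
    probe: Probe,
    config: FitConfig,
) -> IndentationSegment:
    """Cut the 0 <= h <= max_indentation window and convert to force.

    Deflection is referenced to the fitted baseline (removing offset and
    tilt) before Hooke's law is applied.  Depths are then referenced to the
    first retained sample, so h starts exactly at 0; this constant shift is
    at most one sample spacing and leaves the fitted curvature (hence the
    modulus) unchanged.
    """
    contact_z, _ = contact
    if not (curve.z[0] <= contact_z <= curve.z[-1]):
        raise SegmentError(
            f"curve {curve.meta.curve_id}: contact_z {contact_z} outside curve"
        )
    slope, intercept, _ = _baseline_fit(curve, config)
    d_rel = curve.deflection - (slope * curve.z + intercept)
    h = indentation_depth(curve.z, d_rel, contact_z, 0.0)
    mask = (h >= 0) & (h <= config.max_indentation) & (curve.z >= contact_z)
    if int(mask.sum()) < config.min_segment_samples:
        raise SegmentError(
            f"curve {curve.meta.curve_id}: {REASON_SHORT} "
            f"({int(mask.sum())} samples within {config.max_indentation} nm)"
        )
    hs = h[mask]
    fs = deflection_to_force(d_rel[mask], probe)
    order = np.argsort(hs, kind="stable")
    hs, fs = hs[order], fs[order]
    hs = hs - hs[0]
    return IndentationSegment(h=hs, force=fs, contact_z=contact_z)


def _pearson_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    so = float(np.std(observed))
    sf = float(np.std(fitted))
    if so == 0 or sf == 0:
        return 0.0
    r = float(np.corrcoef(observed, fitted)[0, 1])
    return r * r


def fit_modulus(
    segment: IndentationSegment, probe: Probe, config: FitConfig
) -> ModulusEstimate:
    """Second-order polynomial fit of the segment; modulus from curvature.

    The polynomial is unconstrained (not forced through the origin): the
    linear and constant terms absorb residual baseline offset and
    contact-point error without biasing the curvature.  ``r2`` is the squared
    Pearson correlation between observed and fitted force.
    """
    h, f = segment.h, segment.force
    if np.ptp(h) == 0 or h.size < 3:
        return ModulusEstimate(
            young_modulus=float("nan"), r2=0.0, coefficients=(0.0, 0.0, 0.0),
            accepted=False, curve_ref=_EMPTY_META, reason=REASON_DEGENERATE,
        )
    a2, a1, a0 = np.polyfit(h, f, 2)
    fitted = np.polyval([a2, a1, a0], h)
    r2 = _pearson_r2(f, fitted)
    if a2 <= 0 or modulus_from_curvature(max(float(a2), 1e-300), probe) < config.min_modulus:
        return ModulusEstimate(
            young_modulus=float("nan"), r2=r2,
            coefficients=(float(a2), float(a1), float(a0)),
            accepted=False, curve_ref=_EMPTY_META, reason=REASON_CURVATURE,
        )
    E = modulus_from_curvature(float(a2), probe)
    ok = r2 >= config.r2_min
    return ModulusEstimate(
        young_modulus=E, r2=r2,
        coefficients=(float(a2), float(a1), float(a0)),
        accepted=ok, curve_ref=_EMPTY_META,
        reason="" if ok else REASON_LOW_R2,
    )


def process_curve(curve: ForceCurve, probe: Probe, config: FitConfig) -> ModulusEstimate:
    """Run detect -> extract -> fit for one curve, mapping stage failures to
    rejected estimates (never exceptions) tagged with the curve identity."""
    try:
        contact = detect_contact_point(curve, config)
        segment = extract_segment(curve, contact, probe, config)
    except ContactDetectionError:
        return ModulusEstimate(
            young_modulus=float("nan"), r2=0.0, coefficients=(0.0, 0.0, 0.0),
            accepted=False, curve_ref=curve.meta, reason=REASON_NO_CONTACT,
        )
    except SegmentError:
        return ModulusEstimate(
            young_modulus=float("nan"), r2=0.0, coefficients=(0.0, 0.0, 0.0),
            accepted=False, curve_ref=curve.meta, reason=REASON_SHORT,
        )
    est = fit_modulus(segment, probe, config)
    est.curve_ref = curve.meta
    return est


def process_curves(
    curves: Iterable[ForceCurve], probe: Probe, config: FitConfig
) -> list[ModulusEstimate]:
    return [process_curve(c, probe, config) for c in curves]


def qc_filter(
    estimates: Sequence[ModulusEstimate], config: FitConfig
) -> tuple[list[ModulusEstimate], dict[str, int]]:
    """Keep estimates passing QC; report rejection counts by reason.

    Acceptance is re-evaluated against ``config.r2_min`` so a collection
    fitted once can be re-screened at a different threshold.
    """
    accepted: list[ModulusEstimate] = []
    rejected: dict[str, int] = {}
    for e in estimates:
        if e.coefficients[0] > 0 and np.isfinite(e.young_modulus) and e.r2 >= config.r2_min:
            accepted.append(e)
        else:
            reason = e.reason or (REASON_LOW_R2 if e.coefficients[0] > 0 else REASON_CURVATURE)
            rejected[reason] = rejected.get(reason, 0) + 1
    if not accepted:
        raise QCError("no curves passed QC")
    for reason, n in sorted(rejected.items()):
        log.info("QC rejected %d curves: %s", n, reason)
    return accepted, rejected
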