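"""Reference experimental conditions the simulators reproduce by default.

``REPORTED_GROUPS`` holds the published group-level elasticity summaries
(Gaussian mean +/- SD of the per-curve Young's modulus histogram, in kPa)
for the six neuroblastoma AFM conditions the package's synthetic experiments
emulate: SK-N-SH cells with scrambled vs Lamin A/C-silencing shRNA, probed
in the perinuclear and lamellar regions, and SK-N-DZ cells carrying an empty
vector vs a Progerin construct (lamellar).

``DEFAULT_PROBE`` matches the instrument configuration of those
measurements: a soft cantilever with thermally calibrated spring constant
0.034 N/m, a pyramidal tip with an effective half-angle of 35 degrees (a
typical manufacturer value; the half-angle must always be supplied — there
is no physically meaningful universal default) and an incompressible-sample
Poisson ratio of 0.5.

``LMNA_REGION`` / ``LMNA_PROMOTER`` describe the Lamin A/C (LMNA) locus
analysed on the methylation arrays: chr1:156,083,251-156,109,330 (hg19) and
the promoter window -37..+333 bp around the TSS.
"""

from __future__ import annotations

from .mechanics import Probe
from .methylation import RegionSpec

#: group label -> (mean E in kPa, SD in kPa, region label)
REPORTED_GROUPS: dict[str, tuple[float, float, str]] = {
    "lamellar_control": (1.28, 0.37, "lamellar"),
    "lamellar_silenced": (0.73, 0.30, "lamellar"),
    "perinuclear_control": (1.49, 0.34, "perinuclear"),
    "perinuclear_silenced": (1.48, 0.39, "perinuclear"),
    "dz_vector": (1.67, 0.68, "lamellar"),
    "dz_progerin": (2.49, 0.78, "lamellar"),
}

DEFAULT_PROBE = Probe(spring_constant=0.034, half_angle=35.0, poisson=0.5)

#: LMNA TSS used for the promoter window (hg19, plus strand).
LMNA_TSS = 156_084_499

LMNA_REGION = RegionSpec(
    name="LMNA", chromosome="chr1", start=156_083_251, end=156_109_330,
    build="hg19", tss=LMNA_TSS, strand="+",
)

LMNA_PROMOTER = RegionSpec.promoter_window(
    name="LMNA_promoter", chromosome="chr1", tss=LMNA_TSS, strand="+",
    upstream=-37, downstream=333, build="hg19",
)

#: tight window holding exactly the two gene-body CpGs (cg08881019,
#: cg03946955) whose bimodal methylation splits the cohort; the risk
#: association is tested against this pair alone.
LMNA_GENE_BODY = RegionSpec(
    name="LMNA_gene_body", chromosome="chr1",
    start=156_089_990, end=156_090_110, build="hg19",
)
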