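"""Bisulphite-sequencing clone methylation calling.

Bisulphite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine at CpG sites is protected and stays C.
Given a reference sequence and clone reads pre-aligned to it (equal length),
each CpG cytosine is called methylated (C), unmethylated (T) or ambiguous
(anything else).  Non-CpG cytosines should all read T in a fully converted
clone, so the fraction converted measures per-clone conversion efficiency;
clones below a configurable floor are flagged as unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CloneSet", "find_cpg_positions", "call_clone_methylation"]

log = logging.getLogger(__name__)

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"


def find_cpg_positions(reference: str) -> list[int]:
    """1-based positions of the C of every CG dinucleotide."""
    ref = reference.upper()
    return [i + 1 for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"]


@dataclass
class CloneSet:
    """Reference, CpG map and aligned clone reads (+ calls once made).

    ``calls`` is a clone x CpG-position DataFrame with values in
    {methylated, unmethylated, ambiguous}; ``conversion_efficiency`` a
    per-clone Series; both are filled by :func:`call_clone_methylation`.
    """

    reference: str
    clones: dict[str, str]
    cpg_positions: Optional[list[int]] = None
    calls: Optional[pd.DataFrame] = None
    conversion_efficiency: Optional[pd.Series] = None
    low_conversion: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if set(self.reference) - set("ACGT"):
            raise ValueError("reference contains non-ACGT characters")
        self.clones = {k: v.upper() for k, v in self.clones.items()}
        for name, seq in self.clones.items():
            if len(seq) != len(self.reference):
                raise ValueError(
                    f"clone {name!r} length {len(seq)} != reference {len(self.reference)}"
                )
        if self.cpg_positions is None:
            self.cpg_positions = find_cpg_positions(self.reference)
        else:
            for p in self.cpg_positions:
                if not (1 <= p < len(self.reference)) or (
                    self.reference[p - 1] != "C" or self.reference[p] != "G"
                ):
                    raise ValueError(f"position {p} is not the C of a CpG")


def call_clone_methylation(c: CloneSet, min_conversion: float = 0.95) -> CloneSet:
    """Call per-clone, per-CpG methylation and score conversion efficiency.

    Efficiency is the fraction of non-CpG reference cytosines read as T
    (positions reading neither C nor T are excluded from the denominator).
    Clones with efficiency below ``min_conversion`` are flagged, not dropped:
    their calls may be inflated by conversion failures.
    """
    if not c.cpg_positions:
        raise ValueError("reference contains no CpG site")
    cpg = set(c.cpg_positions)
    non_cpg_c = [i for i, base in enumerate(c.reference, start=1)
                 if base == "C" and i not in cpg]

    rows = {}
    eff = {}
    for name, seq in c.clones.items():
        calls_row = []
        for p in c.cpg_positions:
            base = seq[p - 1]
            calls_row.append(
                METHYLATED if base == "C" else UNMETHYLATED if base == "T" else AMBIGUOUS
            )
        rows[name] = calls_row
        n_t = sum(1 for p in non_cpg_c if seq[p - 1] == "T")
        n_c = sum(1 for p in non_cpg_c if seq[p - 1] == "C")
        eff[name] = n_t / (n_t + n_c) if (n_t + n_c) else float("nan")

    calls = pd.DataFrame.from_dict(rows, orient="index", columns=c.cpg_positions)
    efficiency = pd.Series(eff, name="conversion_efficiency")
    flagged = efficiency < min_conversion
    for name in efficiency.index[flagged.fillna(False)]:
        log.warning("clone %s conversion efficiency %.3f below %.2f",
                    name, efficiency[name], min_conversion)
    return replace(
        c, calls=calls, conversion_efficiency=efficiency,
        low_conversion=flagged.rename("low_conversion"),
    )
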