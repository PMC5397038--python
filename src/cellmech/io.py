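"""Readers and writers for the package's tabular and sequence formats.

Force curves travel as long-format CSV/TSV (one row per sample point) or as
a directory of two-column per-curve files with a manifest; beta matrices,
detection p-values, probe annotation and clinical tables as CSV/TSV with
probes in rows and samples in columns; clone and reference sequences as
FASTA.  Writers and readers round-trip exactly on their own output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import CloneSet
from .elasticity import GroupResult, TestResult
from .mechanics import CurveMeta, ForceCurve, ModulusEstimate
from .methylation import BetaMatrix, ClinicalTable

__all__ = [
    "read_force_curves",
    "write_force_curves",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_clinical",
    "write_clinical",
    "read_clone_set",
    "write_clone_set",
    "estimates_to_frame",
    "write_estimates",
    "group_results_to_frame",
    "write_group_results",
    "write_json_report",
]

CURVE_COLUMNS = ["curve_id", "group", "cell", "point", "region", "z_nm", "deflection_nm"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_force_curves(path) -> list[ForceCurve]:
    """Read a curve collection from a long-format table or a manifest directory.

    The long format requires columns ``curve_id, group, cell, point, region,
    z_nm, deflection_nm`` (units are part of the header and are validated).
    A directory must contain ``manifest.tsv`` with per-curve metadata and a
    ``file`` column pointing at two-column (z_nm, deflection_nm) files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_curve_dir(path)

    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; units must be "
                         f"declared in the header as z_nm / deflection_nm")
    curves = []
    for cid, sub in df.groupby("curve_id", sort=False):
        meta_row = sub.iloc[0]
        meta = CurveMeta(
            group=str(meta_row["group"]), cell=int(meta_row["cell"]),
            point=int(meta_row["point"]), curve=_curve_index(cid),
            region=str(meta_row["region"]),
        )
        z = sub["z_nm"].to_numpy(dtype=float)
        d = sub["deflection_nm"].to_numpy(dtype=float)
        if np.any(np.diff(z) <= 0):
            row = int(sub.index[np.argmin(np.diff(z) > 0)])
            raise ValueError(f"{path}: non-monotone z in curve {cid!r} near row {row}")
        curves.append(ForceCurve(z=z, deflection=d, meta=meta))
    if not curves:
        raise ValueError(f"{path}: no curves found")
    return curves


def _curve_index(curve_id) -> int:
    s = str(curve_id)
    tail = s.rsplit("k", 1)[-1]
    try:
        return int(tail)
    except ValueError:
        return 0


def _read_curve_dir(path: Path) -> list[ForceCurve]:
    manifest = path / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"{path}: manifest.tsv not found")
    mf = pd.read_csv(manifest, sep="\t")
    required = ["curve_id", "group", "cell", "point", "region", "file"]
    missing = [c for c in required if c not in mf.columns]
    if missing:
        raise ValueError(f"{manifest}: missing column(s) {missing}")
    curves = []
    for _, row in mf.iterrows():
        fp = path / str(row["file"])
        if not fp.exists():
            raise FileNotFoundError(f"{manifest}: referenced file {row['file']!r} not found")
        tab = pd.read_csv(fp, sep="\t")
        if not {"z_nm", "deflection_nm"} <= set(tab.columns):
            raise ValueError(f"{fp}: needs columns z_nm, deflection_nm")
        meta = CurveMeta(group=str(row["group"]), cell=int(row["cell"]),
                         point=int(row["point"]), curve=_curve_index(row["curve_id"]),
                         region=str(row["region"]))
        curves.append(ForceCurve(z=tab["z_nm"].to_numpy(float),
                                 deflection=tab["deflection_nm"].to_numpy(float),
                                 meta=meta))
    return curves


def write_force_curves(curves: Iterable[ForceCurve], path) -> Path:
    path = Path(path)
    rows = []
    for c in curves:
        m = c.meta
        for z, d in zip(c.z, c.deflection):
            rows.append((m.curve_id, m.group, m.cell, m.point, m.region, z, d))
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def read_beta_matrix(beta_path, detection_path=None, probe_info_path=None) -> BetaMatrix:
    """Load beta values (probes x samples, first column probe id) plus
    optional detection p-values and probe annotation."""
    beta_path = Path(beta_path)
    beta = pd.read_csv(beta_path, sep=_sep_for(beta_path), index_col=0)
    detection = None
    if detection_path is not None:
        detection_path = Path(detection_path)
        detection = pd.read_csv(detection_path, sep=_sep_for(detection_path), index_col=0)
    info = None
    if probe_info_path is not None:
        probe_info_path = Path(probe_info_path)
        info = pd.read_csv(probe_info_path, sep=_sep_for(probe_info_path), index_col=0)
    return BetaMatrix(beta=beta, detection_p=detection, probe_info=info)


def write_beta_matrix(m: BetaMatrix, beta_path, detection_path=None,
                      probe_info_path=None) -> None:
    beta_path = Path(beta_path)
    m.beta.to_csv(beta_path, sep=_sep_for(beta_path), index_label="probe_id")
    if detection_path is not None and m.detection_p is not None:
        detection_path = Path(detection_path)
        m.detection_p.to_csv(detection_path, sep=_sep_for(detection_path),
                             index_label="probe_id")
    if probe_info_path is not None and m.probe_info is not None:
        probe_info_path = Path(probe_info_path)
        m.probe_info.to_csv(probe_info_path, sep=_sep_for(probe_info_path),
                            index_label="probe_id")


def read_clinical(path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if "risk" not in df.columns:
        raise ValueError(f"{path}: needs a 'risk' column")
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path) -> None:
    path = Path(path)
    t.table.to_csv(path, sep=_sep_for(path), index_label="sample")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_clone_set(reference_fasta, clones_fasta) -> CloneSet:
    """Reference FASTA (single record) + clone FASTA (one record per clone)."""
    refs = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if len(refs) != 1:
        raise ValueError(f"{reference_fasta}: expected exactly one reference record")
    clones = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(clones_fasta), "fasta")}
    if not clones:
        raise ValueError(f"{clones_fasta}: no clone records")
    return CloneSet(reference=str(refs[0].seq), clones=clones)


def write_clone_set(c: CloneSet, reference_fasta, clones_fasta,
                    reference_id: str = "reference") -> None:
    SeqIO.write([SeqRecord(Seq(c.reference), id=reference_id, description="")],
                str(reference_fasta), "fasta")
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in c.clones.items()],
        str(clones_fasta), "fasta",
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _sig6(x):
    """Locale-independent 6-significant-digit float for serialized reports."""
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return None
        return float(f"{float(x):.6g}")
    return x


def estimates_to_frame(estimates: Sequence[ModulusEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        m = e.curve_ref
        rows.append({
            "curve_id": m.curve_id, "group": m.group, "cell": m.cell,
            "point": m.point, "region": m.region,
            "E_kPa": e.young_modulus, "r2": e.r2,
            "a2": e.coefficients[0], "a1": e.coefficients[1], "a0": e.coefficients[2],
            "accepted": e.accepted, "reason": e.reason,
        })
    return pd.DataFrame(rows)


def write_estimates(estimates: Sequence[ModulusEstimate], path) -> Path:
    path = Path(path)
    estimates_to_frame(estimates).to_csv(path, sep=_sep_for(path), index=False)
    return path


def group_results_to_frame(results: Sequence[GroupResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": g.group_label,
            "n_curves": g.n_curves_initial,
            "n_after_trim": g.n_curves_after_trim,
            "mean_E_kPa": g.mean_E, "sd_E_kPa": g.sd_E,
            "pre_trim_mean_kPa": g.pre_trim_mean, "pre_trim_sd_kPa": g.pre_trim_sd,
        }
        for g in results
    ])


def write_group_results(results: Sequence[GroupResult], path) -> Path:
    path = Path(path)
    group_results_to_frame(results).to_csv(path, sep=_sep_for(path), index=False)
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, TestResult):
        return _jsonify(obj.__dict__)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return [_jsonify(v) for v in np.asarray(obj).tolist()]
    return _sig6(obj)


def write_json_report(report: dict, path) -> Path:
    """Serialize a report dict with 6-significant-digit floats."""
    path = Path(path)
    path.write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")
    return path
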