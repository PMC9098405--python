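"""Readers/writers for the package's on-disk formats.

Masks travel as NIfTI label volumes (integer labels, RAS affine honoured);
landmarks, head frames and phantom truth as JSON; pipeline reports as JSON
plus CSV tables shaped like the clinical outcome tables.  Rounding to two
decimals happens only here, at the report layer.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .alignment import HeadFrame, LandmarkSet
from .exceptions import ValidationError


def save_labels(img: nib.Nifti1Image, path) -> None:
    nib.save(img, str(path))


def load_labels(path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    return img


def mask_from_labels(img: nib.Nifti1Image, label: int) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(img.dataobj)
    return (data == label), np.asarray(img.affine, float)


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=2) + "\n")


def load_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


def save_frame(frame: HeadFrame, path) -> None:
    Path(path).write_text(json.dumps(frame.to_dict(), indent=2) + "\n")


def load_frame(path) -> HeadFrame:
    return HeadFrame.from_dict(json.loads(Path(path).read_text()))


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CaseBundle:
    """File-based case: label volumes + landmarks per timepoint."""

    case_id: str
    labels_path: dict[str, str]      # timepoint -> NIfTI path
    landmarks_path: dict[str, str]   # timepoint -> JSON path
    affected_side: str
    timing: str = "early"

    def __post_init__(self):
        if self.affected_side not in ("left", "right"):
            raise ValidationError("affected side must be 'left' or 'right'")
        if self.timing not in ("early", "late", "secondary"):
            raise ValidationError("timing must be early, late or secondary")
        for p in list(self.labels_path.values()) + list(self.landmarks_path.values()):
            if not Path(p).exists():
                raise ValidationError(f"case {self.case_id}: missing file {p}")


def _round2(x):
    if isinstance(x, float):
        return round(x, 2)
    if isinstance(x, dict):
        return {k: _round2(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round2(v) for v in x]
    return x


def write_report_json(report: dict, path) -> None:
    """Report JSON with the table-layer 2-decimal rounding applied."""
    body = dict(report)
    body["cases"] = _round2(report.get("cases", {}))
    body["stats"] = _round2(report.get("stats", {}))
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")


ZYGOMA_COLUMNS = [
    "case_id", "timepoint", "ZM", "ZF", "IO", "ZS", "ZT", "Sum",
    "Z1P1", "Z2P2", "Z3P3", "Z4P4", "Z5P5", "DI", "ZO_sum", "PO_sum",
]
ORBIT_COLUMNS = [
    "case_id", "timepoint", "volume_affected", "volume_unaffected",
    "volume_diff", "angle_anterior_affected", "angle_middle_affected",
    "angle_posterior_affected", "angle_anterior_unaffected",
    "angle_middle_unaffected", "angle_posterior_unaffected",
    "angle_diff_anterior", "angle_diff_middle", "angle_diff_posterior",
]


def write_report_csv(report: dict, out_dir) -> list[Path]:
    """CSV tables mirroring the zygoma / orbit outcome-table layouts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    zrows, orows = [], []
    for cid, case in sorted(report.get("cases", {}).items()):
        for tp, res in sorted(case.get("timepoints", {}).items()):
            z = res.get("zygoma")
            if z:
                zrows.append(
                    [cid, tp] + [round(z["suture_gaps_mm"][s], 2)
                                 for s in ("ZM", "ZF", "IO", "ZS", "ZT")]
                    + [round(z["suture_sum_mm"], 2)]
                    + [round(d, 2) for d in z["distances_mm"]]
                    + [round(z["DI"], 2), round(z["ZO_sum_mm"], 2),
                       round(z["PO_sum_mm"], 2)]
                )
            o = res.get("orbit")
            if o:
                orows.append(
                    [cid, tp,
                     round(o["volume_affected"], 2), round(o["volume_unaffected"], 2),
                     round(o["volume_diff"], 2)]
                    + [round(a, 2) for a in o["angles_affected_deg"]]
                    + [round(a, 2) for a in o["angles_unaffected_deg"]]
                    + [round(a, 2) for a in o["angle_diff_deg"]]
                )
    written = []
    if zrows:
        p = out_dir / "zygoma_table.csv"
        pd.DataFrame(zrows, columns=ZYGOMA_COLUMNS).to_csv(p, index=False)
        written.append(p)
    if orows:
        p = out_dir / "orbit_table.csv"
        pd.DataFrame(orows, columns=ORBIT_COLUMNS).to_csv(p, index=False)
        written.append(p)
    return written


def read_pairs_csv(path) -> dict[str, tuple[list, np.ndarray, np.ndarray]]:
    """Read a long-format pairs CSV (case_id, metric, pre, post) into
    per-metric (case_ids, pre, post) triples."""
    df = pd.read_csv(path)
    need = {"case_id", "metric", "pre", "post"}
    if not need.issubset(df.columns):
        raise ValidationError(f"pairs CSV must have columns {sorted(need)}")
    out = {}
    for metric, sub in df.groupby("metric"):
        out[str(metric)] = (
            list(sub["case_id"]),
            sub["pre"].to_numpy(float),
            sub["post"].to_numpy(float),
        )
    return out
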