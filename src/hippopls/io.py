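"""Reading and writing of the package's on-disk formats.

BOLD runs and label volumes are NIfTI-1 (via nibabel, RAS affine from the
voxel size), trial schedules are BIDS-style events TSV, and ground truth /
code tables are JSON sidecars.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldRun, LabelVolume, SimulationTruth, TrialSchedule


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_nifti(data: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    nib.save(img, str(path))


def save_bold(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data, _affine(run.voxel_size_mm))
    img.header["pixdim"][4] = run.tr_s
    nib.save(img, str(path))


def load_bold(path: str | Path, tr_s: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    tr = float(img.header["pixdim"][4]) if tr_s is None else tr_s
    return BoldRun(data=np.asarray(img.dataobj, float), voxel_size_mm=vox, tr_s=tr)


def save_labels(labels: LabelVolume, nii_path: str | Path, json_path: str | Path) -> None:
    save_nifti(labels.labels.astype(np.int16), labels.voxel_size_mm, nii_path)
    table = {str(code): list(pair) for code, pair in labels.code_table.items()}
    Path(json_path).write_text(
        json.dumps({"code_table": table, "long_axis": labels.long_axis}, indent=2)
    )


def load_labels(nii_path: str | Path, json_path: str | Path) -> LabelVolume:
    img = nib.load(str(nii_path))
    meta = json.loads(Path(json_path).read_text())
    return LabelVolume(
        labels=np.asarray(img.dataobj).astype(np.int16),
        code_table={int(k): tuple(v) for k, v in meta["code_table"].items()},
        long_axis=int(meta["long_axis"]),
        voxel_size_mm=tuple(float(v) for v in img.header.get_zooms()[:3]),
    )


def save_events_tsv(schedule: TrialSchedule, path: str | Path) -> None:
    """BIDS-style events table: onset/duration describe the stimulus block."""
    t = schedule.trials
    events = pd.DataFrame(
        {
            "onset": t["stimulus_onset_s"],
            "duration": t["elaboration_end_s"] - t["stimulus_onset_s"],
            "trial_type": t["condition"],
            "response_time": t["selection_press_s"] - t["stimulus_onset_s"],
            "rating": t["rating_value"],
        }
    )
    events.to_csv(path, sep="\t", index=False, float_format="%.3f")


def save_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    d = asdict(truth)
    d["effect_map"] = {f"{sf}|{portion}": v for (sf, portion), v in truth.effect_map.items()}
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def load_truth_json(path: str | Path) -> SimulationTruth:
    d = json.loads(Path(path).read_text())
    d["effect_map"] = {
        tuple(k.split("|")): float(v) for k, v in d["effect_map"].items()
    }
    for key in ("grid_shape", "voxel_size_mm", "isi_range_s", "spike_volumes"):
        d[key] = tuple(d[key])
    return SimulationTruth(**d)
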