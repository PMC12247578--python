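"""Subfield-mask manipulation: long-axis partition, signal extraction,
laterality collapse, and the DICE overlap metric.

The long-axis rule divides each hippocampus into four portions: the
*anterior* runs from the first hippocampus-bearing slice up to the slice
preceding the first DG/CA4 slice; the remaining slices are split into three
contiguous, near-equal parts (anterior body, posterior body, tail), any
remainder going to the rostral-most parts first.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import HEMISPHERES, PORTIONS, SUBFIELDS, LabelVolume

log = logging.getLogger(__name__)


@dataclass
class AxisPartition:
    """Per-hemisphere slice-index ranges for the four long-axis portions."""

    portions: dict[str, dict[str, np.ndarray]]  # hemisphere -> portion -> slice indices
    long_axis: int = 2

    def slices(self, hemisphere: str, portion: str) -> np.ndarray:
        if portion == "whole":
            return np.concatenate([self.portions[hemisphere][p] for p in PORTIONS])
        return self.portions[hemisphere][portion]

    def counts(self, hemisphere: str) -> dict[str, int]:
        return {p: len(v) for p, v in self.portions[hemisphere].items()}


@dataclass
class LateralityTest:
    t: float
    df: int
    p: float
    collapsed: bool


def partition_long_axis(labels: LabelVolume) -> AxisPartition:
    """Partition each hippocampus along its long axis into four portions.

    Raises if a hemisphere has no hippocampal voxels or no DG/CA4 label.
    """
    axis = labels.long_axis
    other = tuple(a for a in range(3) if a != axis)
    result: dict[str, dict[str, np.ndarray]] = {}
    for hemi in HEMISPHERES:
        hip = labels.hippocampus_mask(hemisphere=hemi).any(axis=other)
        dg = labels.mask(subfield="DG/CA4", hemisphere=hemi).any(axis=other)
        hip_slices = np.flatnonzero(hip)
        if hip_slices.size == 0:
            raise ValueError(f"no hippocampal voxels in hemisphere {hemi}")
        if not dg.any():
            raise ValueError(f"no DG/CA4 label in hemisphere {hemi}")
        first_dg = int(np.flatnonzero(dg).min())
        if first_dg <= hip_slices.min():
            raise ValueError(
                f"hemisphere {hemi}: DG/CA4 begins on the first hippocampal slice"
            )
        anterior = hip_slices[hip_slices < first_dg]
        rest = hip_slices[hip_slices >= first_dg]
        if rest.size < 3:
            raise ValueError(f"hemisphere {hemi}: too few post-DG slices to split in three")
        # np.array_split assigns the remainder to the leading (rostral) parts
        body_a, body_p, tail = np.array_split(rest, 3)
        result[hemi] = {
            "anterior": anterior,
            "anterior_body": body_a,
            "posterior_body": body_p,
            "tail": tail,
        }
    return AxisPartition(portions=result, long_axis=axis)


def _portion_mask(
    labels: LabelVolume, partition: AxisPartition, hemisphere: str, portion: str
) -> np.ndarray:
    sel = np.zeros(labels.labels.shape[labels.long_axis], dtype=bool)
    sel[partition.slices(hemisphere, portion)] = True
    shape = [1, 1, 1]
    shape[labels.long_axis] = -1
    return sel.reshape(shape)


def extract_roi_signal(
    maps: dict[str, np.ndarray],
    labels: LabelVolume,
    partition: AxisPartition,
    subject: int = 0,
) -> pd.DataFrame:
    """Mean contrast intensity per (subfield, portion, hemisphere, condition).

    ``maps`` holds one 3D contrast map per condition (typically ``AM`` and
    ``MA`` beta-contrast maps); an ``AM_minus_MA`` differential row is added
    whenever both conditions are present.  Portions cover ``whole`` plus the
    four long-axis portions; empty voxel sets (e.g. DG/CA4 in the anterior)
    yield NaN with a logged warning.
    """
    arrays = {c: np.asarray(getattr(m, "values", m), float) for c, m in maps.items()}
    grid = labels.labels.shape
    for c, a in arrays.items():
        if a.shape != grid:
            raise ValueError(f"map for condition {c!r} does not match the label grid")

    rows = []
    for sf in SUBFIELDS:
        for hemi in HEMISPHERES:
            sf_mask = labels.mask(subfield=sf, hemisphere=hemi)
            for portion in ("whole",) + PORTIONS:
                m = sf_mask & _portion_mask(labels, partition, hemi, portion)
                n_vox = int(m.sum())
                if n_vox == 0:
                    log.warning(
                        "no voxels for subject %s %s %s %s", subject, sf, portion, hemi
                    )
                vals = {}
                for cond, arr in arrays.items():
                    vals[cond] = float(arr[m].mean()) if n_vox else np.nan
                if "AM" in vals and "MA" in vals:
                    vals["AM_minus_MA"] = vals["AM"] - vals["MA"]
                for cond, v in vals.items():
                    rows.append(
                        {
                            "subject": subject,
                            "subfield": sf,
                            "portion": portion,
                            "hemisphere": hemi,
                            "condition": cond,
                            "value": v,
                            "n_voxels": n_vox,
                        }
                    )
    return pd.DataFrame(rows)


def collapse_laterality(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, LateralityTest]:
    """Collapse hemispheres if a paired left-vs-right test is non-significant.

    The test compares, across subjects, each hemisphere's mean
    whole-hippocampus AM-minus-MA differential (averaged over subfields).
    If ``p >= alpha`` the returned table carries voxel-count-weighted
    ``bilateral`` rows; otherwise the hemispheric table is returned
    unchanged with a warning.
    """
    for hemi in HEMISPHERES:
        if not (table["hemisphere"] == hemi).any():
            raise ValueError(f"hemisphere {hemi} missing from the signal table")

    whole = table[(table["portion"] == "whole") & (table["condition"] == "AM_minus_MA")]
    per = whole.groupby(["subject", "hemisphere"])["value"].mean().unstack("hemisphere")
    diffs = (per["L"] - per["R"]).dropna().to_numpy()
    if diffs.size < 2 or np.isclose(diffs.std(ddof=1), 0.0):
        # degenerate (identical hemispheres or a single subject): no evidence
        t, p = 0.0 if np.allclose(diffs, 0.0) else np.nan, 1.0
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
    test = LateralityTest(t=float(t), df=len(diffs) - 1, p=float(p), collapsed=bool(p >= alpha))
    if not test.collapsed:
        warnings.warn(
            f"lateralized effect detected (p={p:.4g} < {alpha}); keeping hemispheres separate"
        )
        return table, test
    return bilateral_collapse(table), test


def bilateral_collapse(table: pd.DataFrame) -> pd.DataFrame:
    """Voxel-count-weighted bilateral rows (equals the pooled-voxel mean)."""

    def _collapse(g: pd.DataFrame) -> pd.Series:
        w = g["n_voxels"].to_numpy(float)
        v = g["value"].to_numpy(float)
        ok = np.isfinite(v) & (w > 0)
        value = float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan
        return pd.Series({"value": value, "n_voxels": int(w.sum())})

    collapsed = (
        table.groupby(["subject", "subfield", "portion", "condition"])
        .apply(_collapse, include_groups=False)
        .reset_index()
    )
    collapsed["hemisphere"] = "bilateral"
    return collapsed


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """DICE overlap ``2|A∩B| / (|A|+|B|)`` between two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; DICE defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
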