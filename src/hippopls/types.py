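"""Core domain containers shared by the simulation and analysis stages.

The package analyzes a two-condition block-design experiment in which
participants alternate between autobiographical-memory retrieval trials
(``AM``) and mental-arithmetic control trials (``MA``).  The hippocampus is
represented by integer label volumes covering five analyzed subfields per
hemisphere (DG/CA4, CA3/2, CA1, subiculum, pre/parasubiculum; the uncus is
labelled but excluded from analysis) and is partitioned along its long axis
into four portions (anterior, anterior body, posterior body, tail).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

SUBFIELDS: tuple[str, ...] = ("DG/CA4", "CA3/2", "CA1", "subiculum", "pre/parasubiculum")
UNCUS = "uncus"
HEMISPHERES: tuple[str, ...] = ("L", "R")
PORTIONS: tuple[str, ...] = ("anterior", "anterior_body", "posterior_body", "tail")
BODY_PORTIONS: tuple[str, ...] = ("anterior_body", "posterior_body", "tail")
CONDITIONS: tuple[str, ...] = ("AM", "MA")

#: label codes: left hemisphere 1..6, right hemisphere 11..16, in SUBFIELDS + uncus order
DEFAULT_CODE_TABLE: dict[int, tuple[str, str]] = {}
for _h, _off in (("L", 0), ("R", 10)):
    for _i, _sf in enumerate(SUBFIELDS + (UNCUS,), start=1):
        DEFAULT_CODE_TABLE[_off + _i] = (_sf, _h)


def default_effect_map(
    base_pct: float = 0.2,
    planted_pct: float = 0.6,
    planted_cell: tuple[str, str] = ("pre/parasubiculum", "anterior_body"),
) -> dict[tuple[str, str], float]:
    """AM-minus-MA percent-signal-change per (subfield, portion) cell.

    Every cell carries a common positive engagement (all subfields respond
    more to AM than MA) and a single elevated cell — by default the
    anterior-body pre/parasubiculum — carries the differential effect the
    group statistics are meant to localize.
    """
    m = {(sf, p): base_pct for sf in SUBFIELDS for p in PORTIONS}
    m[planted_cell] = planted_pct
    return m


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth description of one synthetic cohort.

    Parameters mirror the study design being emulated: 24 subjects, 40
    trials per run split evenly between AM and MA, trials lasting at most
    17 s with the final 8 s treated as the elaboration window, a jittered
    1-4 s inter-stimulus interval, a 17 s pre-task wait covered by the five
    discarded leading volumes, and a volume TR of 3.4 s.  Spatial scale is
    a reduced desk-size lattice rather than an acquisition matrix.
    """

    n_subjects: int = 24
    grid_shape: tuple[int, int, int] = (40, 40, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr_s: float = 3.4
    n_trials: int = 40
    trial_max_s: float = 17.0
    elaboration_s: float = 8.0
    isi_range_s: tuple[float, float] = (1.0, 4.0)
    wait_s: float = 17.0
    n_discard: int = 5
    max_volumes: int = 264
    # planted activation, in percent signal change (AM minus MA)
    effect_map: Mapping[tuple[str, str], float] = field(default_factory=default_effect_map)
    # between-subject SD of a ROI differential, percent signal change
    subject_sd_pct: float = 0.35
    # seed-network connectivity plant
    seed_subfield: str = "pre/parasubiculum"
    seed_portion: str = "anterior_body"
    n_network_voxels: int = 150
    seed_network_r_am: float = 0.5
    seed_network_r_ma: float = 0.0
    latent_amp_pct: float = 1.0
    # noise model
    baseline: float = 1000.0
    noise_sd: float = 5.0
    # scanner-level intensity fluctuation shared by all brain voxels; keeps
    # the global-mean series at a realistic noise floor for the QC screen
    global_noise_sd: float = 1.0
    drift_amplitude: float = 10.0
    ar1_coef: float = 0.3
    # label-volume geometry (slice counts along the long axis)
    n_slices_mean: float = 40.0
    n_slices_sd: float = 2.57
    n_anterior_mean: float = 8.0
    n_anterior_sd: float = 2.01
    # optional global-intensity spikes for QC exercises
    spike_volumes: tuple[int, ...] = ()
    spike_factor: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not (abs(self.seed_network_r_am) < 1 and abs(self.seed_network_r_ma) < 1):
            raise ValueError("seed-network correlations must lie in (-1, 1)")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        expected = {(sf, p) for sf in SUBFIELDS for p in PORTIONS}
        if set(self.effect_map) != expected:
            raise ValueError("effect_map must cover exactly 5 subfields x 4 portions")

    def with_(self, **kwargs) -> "SimulationTruth":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class TrialSchedule:
    """Per-trial timing for one run, in scanner time (t=0 at first volume).

    Attributes
    ----------
    trials : pandas.DataFrame
        One row per trial with columns ``condition`` (AM/MA),
        ``stimulus_onset_s``, ``selection_press_s``, ``elaboration_onset_s``,
        ``elaboration_end_s``, ``rating_onset_s``, ``rating_value``
        and ``isi_s``.
    """

    trials: "pandas.DataFrame"  # noqa: F821 - imported lazily by callers
    subject_id: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def elaboration_onsets(self) -> np.ndarray:
        return self.trials["elaboration_onset_s"].to_numpy(float)

    @property
    def conditions(self) -> np.ndarray:
        return self.trials["condition"].to_numpy(str)

    @property
    def end_s(self) -> float:
        last = self.trials.iloc[-1]
        return float(last["elaboration_end_s"] + last["isi_s"])


@dataclass
class BoldRun:
    """A 4D BOLD-like lattice (x, y, z, t) with voxel geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    n_discarded_leading_volumes: int = 0
    run_id: str = "run-01"

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError("BoldRun.data must be 4D with at least one volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data must be finite")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabelVolume:
    """Integer subfield/hemisphere labels on a BOLD grid.

    ``long_axis`` designates the lattice axis whose index orders slices
    rostral (anterior) to caudal (posterior).
    """

    labels: np.ndarray
    code_table: Mapping[int, tuple[str, str]]
    long_axis: int = 2
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.code_table)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from code_table")

    def mask(self, subfield: str | None = None, hemisphere: str | None = None) -> np.ndarray:
        """Boolean mask of voxels matching the given subfield/hemisphere."""
        codes = [
            c
            for c, (sf, h) in self.code_table.items()
            if (subfield is None or sf == subfield) and (hemisphere is None or h == hemisphere)
        ]
        return np.isin(self.labels, codes)

    def hippocampus_mask(self, hemisphere: str | None = None, include_uncus: bool = True) -> np.ndarray:
        """All hippocampal voxels (analyzed subfields, optionally the uncus)."""
        codes = [
            c
            for c, (sf, h) in self.code_table.items()
            if (include_uncus or sf != UNCUS) and (hemisphere is None or h == hemisphere)
        ]
        return np.isin(self.labels, codes)


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("MotionTrace.params must be (n_volumes, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    def __len__(self) -> int:
        return self.params.shape[0]

    def drop_leading(self, n: int) -> "MotionTrace":
        if n >= len(self):
            raise ValueError("cannot drop all volumes from a motion trace")
        return MotionTrace(self.params[n:])
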