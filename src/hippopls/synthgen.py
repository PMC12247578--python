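"""Synthetic-cohort generator with known ground truth.

Everything downstream (GLM, ROI extraction, group statistics, PLS) is
validated against data produced here.  Two levels of simulation are
provided:

* **voxel level** — :func:`synthesize_bold` builds full 4D BOLD-like runs:
  per-voxel baseline modulated by HRF-convolved condition boxcars over the
  8 s elaboration windows, a per-trial latent "AM network" fluctuation
  shared between the seed subfield and a fixed set of neocortical voxels,
  AR(1) noise, low-frequency drift, and optional global-intensity spike
  volumes for QC exercises.

* **group level** — :func:`simulate_roi_differentials` and
  :func:`simulate_group_connectivity` draw subject-by-ROI (or
  subject-by-voxel) summary values directly from the same ground truth,
  which keeps replicate-heavy statistical validation affordable.

All draws are governed by ``SimulationTruth.rng_seed`` (plus a per-stream
offset and the subject id), so identical truth objects yield bit-identical
outputs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .hrf import condition_regressor, dct_drift_basis
from .pls import StackedBrainMatrix
from .roi import partition_long_axis
from .types import (
    BODY_PORTIONS,
    CONDITIONS,
    DEFAULT_CODE_TABLE,
    PORTIONS,
    SUBFIELDS,
    UNCUS,
    BoldRun,
    LabelVolume,
    MotionTrace,
    SimulationTruth,
    TrialSchedule,
)

# per-stream offsets so each generator op draws from an independent stream
_STREAM_SCHEDULE = 101
_STREAM_LABELS = 202
_STREAM_NETWORK = 303
_STREAM_BOLD = 404
_STREAM_TABLE = 505
_STREAM_GROUP = 606

# mean selection response times (s) emulated per condition
_RT_MEAN = {"AM": 3.53, "MA": 3.66}
_RT_SD = 0.98
# fraction of trials rated vivid (AM) / easy (MA)
_RATING_P = {"AM": 35.67 / 40.0, "MA": 28.13 / 40.0}
_RATING_LABELS = {"AM": ("vivid", "faint"), "MA": ("easy", "difficult")}


def _rng(truth: SimulationTruth, stream: int, subject_id: int | None = None):
    key = [int(truth.rng_seed), int(stream)]
    if subject_id is not None:
        key.append(int(subject_id))
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------

def make_schedule(truth: SimulationTruth, subject_id: int) -> TrialSchedule:
    """Draw one randomized run of interleaved AM and MA trials.

    Trials last exactly ``trial_max_s`` (17 s) with the elaboration window
    occupying the final ``elaboration_s`` (8 s), followed by a jittered ISI
    drawn uniformly from ``isi_range_s``.  The first trial starts after the
    ``wait_s`` pre-task waiting period.  Equal numbers of AM and MA trials
    are shuffled into a random order.
    """
    if truth.n_trials % 2 != 0:
        raise ValueError("n_trials must be even (equal AM and MA counts)")
    rng = _rng(truth, _STREAM_SCHEDULE, subject_id)
    half = truth.n_trials // 2
    conditions = np.array(["AM"] * half + ["MA"] * half)
    rng.shuffle(conditions)

    rows = []
    onset = float(truth.wait_s)
    pre_elab = truth.trial_max_s - truth.elaboration_s
    for cond in conditions:
        rt = float(np.clip(rng.normal(_RT_MEAN[cond], _RT_SD), 1.0, pre_elab - 0.5))
        isi = float(rng.uniform(*truth.isi_range_s))
        good, bad = _RATING_LABELS[cond]
        rating = good if rng.random() < _RATING_P[cond] else bad
        rows.append(
            {
                "condition": cond,
                "stimulus_onset_s": onset,
                "selection_press_s": onset + rt,
                "elaboration_onset_s": onset + pre_elab,
                "elaboration_end_s": onset + truth.trial_max_s,
                "rating_onset_s": onset + truth.trial_max_s,
                "rating_value": rating,
                "isi_s": isi,
            }
        )
        onset += truth.trial_max_s + isi
    return TrialSchedule(trials=pd.DataFrame(rows), subject_id=subject_id)


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

def make_label_volume(truth: SimulationTruth, subject_id: int) -> LabelVolume:
    """Emulate a manual hippocampal-subfield segmentation for one subject.

    Two hippocampi (left/right) extend along the designated long axis for a
    number of slices drawn near ``n_slices_mean`` (default 40), the first
    ``~n_anterior_mean`` (default 8) of which precede the first DG/CA4
    slice and therefore form the anterior portion.  Every slice carries all
    subfields applicable at that level: body/tail slices hold all five
    analyzed subfields, anterior slices hold four plus the uncus in place
    of DG/CA4.
    """
    gx, gy, gz_all = truth.grid_shape
    axis_len = truth.grid_shape[2]
    rng = _rng(truth, _STREAM_LABELS, subject_id)

    n_total = int(np.clip(np.round(rng.normal(truth.n_slices_mean, truth.n_slices_sd)), 12, axis_len))
    n_anterior = int(np.clip(np.round(rng.normal(truth.n_anterior_mean, truth.n_anterior_sd)), 2, n_total - 6))
    if axis_len < n_total:
        raise ValueError(
            f"grid axis of length {axis_len} cannot hold {n_total} hippocampal slices"
        )
    if gx < 16 or gy < 10:
        raise ValueError("in-plane grid too small for two hippocampi")

    labels = np.zeros(truth.grid_shape, dtype=np.int16)
    z0 = (axis_len - n_total) // 2
    cy = gy // 2
    # one subfield band per in-plane row, superior to inferior
    band_order = ["pre/parasubiculum", "subiculum", "CA1", "CA3/2", "DG/CA4"]
    code_of = {(sf, h): c for c, (sf, h) in DEFAULT_CODE_TABLE.items()}
    for hemi, cx in (("L", gx // 4), ("R", (3 * gx) // 4)):
        xs = slice(cx - 2, cx + 2)
        for k in range(n_total):
            z = z0 + k
            anterior = k < n_anterior
            for row, sf in enumerate(band_order):
                if anterior and sf == "DG/CA4":
                    sf = UNCUS
                labels[xs, cy - 2 + row, z] = code_of[(sf, hemi)]
    return LabelVolume(
        labels=labels,
        code_table=dict(DEFAULT_CODE_TABLE),
        long_axis=2,
        voxel_size_mm=truth.voxel_size_mm,
    )


def neocortex_mask(truth: SimulationTruth) -> np.ndarray:
    """Deterministic neocortical slab shared by all subjects (group space)."""
    gx, gy, gz = truth.grid_shape
    mask = np.zeros(truth.grid_shape, dtype=bool)
    mask[2 : gx - 2, 1:4, 2 : gz - 2] = True
    return mask


def pick_network_voxels(truth: SimulationTruth) -> np.ndarray:
    """Flat indices of the planted AM-network voxels within the neocortex."""
    rng = _rng(truth, _STREAM_NETWORK)
    flat = np.flatnonzero(neocortex_mask(truth))
    if len(flat) < truth.n_network_voxels:
        raise ValueError("neocortex slab smaller than the requested network size")
    return np.sort(rng.choice(flat, size=truth.n_network_voxels, replace=False))


# ---------------------------------------------------------------------------
# voxel-level BOLD synthesis
# ---------------------------------------------------------------------------

def synthesize_bold(
    truth: SimulationTruth,
    schedule: TrialSchedule,
    labels: LabelVolume,
    subject_id: int,
) -> tuple[BoldRun, MotionTrace]:
    """Render a full 4D run realizing the planted ground truth.

    The voxel model is ``baseline * (1 + s_v(t) / 100) + drift + noise``
    where ``s_v(t)`` sums HRF-convolved condition responses.  Response
    amplitudes combine the planted ``effect_map`` means with between-subject
    variability of SD ``subject_sd_pct`` per condition: hippocampal cells
    draw one amplitude per (subfield, portion, condition) shared across
    hemispheres, neocortical voxels draw independent per-voxel amplitudes.
    The seed subfield cell and the planted network voxels realize their
    subject variability through a per-elaboration-window latent scalar
    whose amplitude ``subject_sd_pct * sqrt(n_trials)`` is calibrated
    analytically so that (i) the subject-level amplitude SD matches
    ``subject_sd_pct`` and (ii) the across-subject seed-network correlation
    approaches ``seed_network_r_am`` (AM) / ``seed_network_r_ma`` (MA) when
    extraction noise is negligible.
    """
    el_on = schedule.elaboration_onsets
    el_end = schedule.trials["elaboration_end_s"].to_numpy(float)
    order = np.argsort(el_on)
    if np.any(el_on[order][1:] < el_end[order][:-1]):
        raise ValueError("elaboration windows overlap")

    n_vols = int(np.ceil((schedule.end_s + 16.0) / truth.tr_s))
    if n_vols > truth.max_volumes:
        raise ValueError("schedule does not fit within the maximum run duration")

    conds = schedule.conditions
    grid = truth.grid_shape
    n_brain_all = int(np.prod(grid))
    rng = _rng(truth, _STREAM_BOLD, subject_id)
    # subject_sd_pct parameterizes the AM-minus-MA differential; each
    # condition's independent amplitude draw therefore uses SD tau/sqrt(2)
    tau = float(truth.subject_sd_pct) / np.sqrt(2.0)

    partition = partition_long_axis(labels)
    net_flat = pick_network_voxels(truth)
    net_mean = float(truth.effect_map[(truth.seed_subfield, truth.seed_portion)])
    neo_flat = np.flatnonzero(neocortex_mask(truth))

    brain = labels.labels > 0
    brain |= neocortex_mask(truth)
    brain_flat = np.flatnonzero(brain)
    vb = len(brain_flat)

    def cell_mask(sf: str, portion: str) -> np.ndarray:
        m = np.zeros(vb, bool)
        for hemi in ("L", "R"):
            hm = labels.mask(subfield=sf, hemisphere=hemi)
            zsel = np.zeros(grid[labels.long_axis], bool)
            zsel[partition.slices(hemi, portion)] = True
            pos = np.flatnonzero(hm & zsel[np.newaxis, np.newaxis, :])
            m[np.searchsorted(brain_flat, pos)] = True
        return m

    seed_cell = (truth.seed_subfield, truth.seed_portion)
    seed_sel = cell_mask(*seed_cell)
    net_pos = np.searchsorted(brain_flat, net_flat)
    neo_pos = np.searchsorted(brain_flat, neo_flat)

    # condition regressors and per-trial regressors at volume times
    def regressor(onsets):
        return condition_regressor(onsets, truth.elaboration_s, n_vols, truth.tr_s)

    x_cond = {c: regressor(el_on[conds == c]) for c in CONDITIONS}
    trial_x = {c: np.column_stack([regressor([o]) for o in el_on[conds == c]]) for c in CONDITIONS}

    signal = np.zeros((n_vols, vb))
    for cond, r in (("AM", truth.seed_network_r_am), ("MA", truth.seed_network_r_ma)):
        amp = np.zeros(vb)
        # hippocampal cells: planted mean (AM only) + per-cell subject draw
        for sf in SUBFIELDS:
            for portion in PORTIONS:
                eps = rng.normal(0.0, 1.0)
                if (sf, portion) == seed_cell:
                    continue  # handled by the latent channel below
                mean = float(truth.effect_map[(sf, portion)]) if cond == "AM" else 0.0
                amp[cell_mask(sf, portion)] = mean + tau * eps
        # neocortex: independent per-voxel subject amplitudes
        amp[neo_pos] = tau * rng.standard_normal(len(neo_pos))
        amp[seed_sel] = net_mean if cond == "AM" else 0.0
        amp[net_pos] = net_mean if cond == "AM" else 0.0
        signal += np.outer(x_cond[cond], amp)

        # latent channel: per-elaboration-window scalar shared by seed cell
        # and network voxels; amplitude tau * sqrt(n_trials) gives the seed a
        # subject-level SD of tau and the target seed-network correlation
        n_tr = trial_x[cond].shape[1]
        c_amp = float(truth.latent_amp_pct) * tau * np.sqrt(n_tr)
        z = rng.standard_normal(n_tr)
        w = rng.standard_normal((n_tr, len(net_pos)))
        if c_amp > 0:
            seed_amp = c_amp * z  # shared by every seed voxel
            net_amp = c_amp * (r * z[:, None] + np.sqrt(1.0 - r**2) * w)
            signal[:, seed_sel] += np.outer(trial_x[cond] @ seed_amp, np.ones(int(seed_sel.sum())))
            signal[:, net_pos] += trial_x[cond] @ net_amp

    data_flat = truth.baseline * (1.0 + signal / 100.0)

    # low-frequency drift: random low-order cosine shape, per-voxel gain
    if truth.drift_amplitude > 0:
        basis = dct_drift_basis(n_vols, truth.tr_s, highpass_s=192.0)
        n_use = min(3, basis.shape[1])
        if n_use:
            shape_t = basis[:, :n_use] @ rng.standard_normal(n_use)
            shape_t = shape_t / max(np.abs(shape_t).max(), 1e-12)
            gains = rng.uniform(0.5, 1.5, vb)
            data_flat += truth.drift_amplitude * np.outer(shape_t, gains)

    # AR(1) noise, stationary SD = noise_sd, plus a shared global fluctuation
    innov_scale = np.sqrt(1.0 - truth.ar1_coef**2)
    if truth.noise_sd > 0:
        eps = rng.standard_normal((n_vols, vb)) * truth.noise_sd * innov_scale
        data_flat += lfilter([1.0], [1.0, -truth.ar1_coef], eps, axis=0)
    if truth.global_noise_sd > 0:
        g_eps = rng.standard_normal((n_vols, 1)) * truth.global_noise_sd * innov_scale
        data_flat += lfilter([1.0], [1.0, -truth.ar1_coef], g_eps, axis=0)

    if truth.spike_factor != 1.0 and truth.spike_volumes:
        data_flat[list(truth.spike_volumes), :] *= truth.spike_factor

    data = np.zeros(grid + (n_vols,))
    data.reshape(n_brain_all, n_vols)[brain_flat] = data_flat.T

    motion = np.cumsum(
        rng.normal(0.0, [0.02] * 3 + [0.001] * 3, size=(n_vols, 6)), axis=0
    )
    run = BoldRun(
        data=data,
        voxel_size_mm=truth.voxel_size_mm,
        tr_s=truth.tr_s,
        n_discarded_leading_volumes=0,
        run_id=f"sub-{subject_id:02d}",
    )
    return run, MotionTrace(motion)


# ---------------------------------------------------------------------------
# group-level summary simulators
# ---------------------------------------------------------------------------

def simulate_roi_differentials(
    truth: SimulationTruth, replicate: int = 0
) -> pd.DataFrame:
    """Subject-by-ROI AM-minus-MA differentials drawn from the truth.

    Each (subject, subfield, portion) cell is the planted ``effect_map``
    value plus independent between-subject noise of SD ``subject_sd_pct``
    — the distribution the voxelwise pipeline's extracted differentials
    follow when within-subject estimation noise is small.
    """
    rng = _rng(truth, _STREAM_TABLE, replicate)
    rows = []
    for s in range(truth.n_subjects):
        for sf in SUBFIELDS:
            for portion in PORTIONS:
                rows.append(
                    {
                        "subject": s,
                        "subfield": sf,
                        "portion": portion,
                        "value": truth.effect_map[(sf, portion)]
                        + rng.normal(0.0, truth.subject_sd_pct),
                    }
                )
    return pd.DataFrame(rows)


def simulate_group_connectivity(
    truth: SimulationTruth,
    n_voxels: int = 2000,
    replicate: int = 0,
) -> tuple[StackedBrainMatrix, dict[tuple[str, str], np.ndarray]]:
    """Group-space contrast rows plus per-ROI seed values for seed PLS.

    Returns a stacked matrix with one row per subject-condition (subject
    major, AM before MA) over ``n_voxels`` voxels, and a dict mapping each
    (portion, subfield) pair over the three body portions to the seed
    vector aligned with those rows.  Only the planted seed
    (``seed_portion``, ``seed_subfield``) correlates with the first
    ``n_network_voxels`` voxels, at ``seed_network_r_am`` under AM and
    ``seed_network_r_ma`` under MA.
    """
    rng = _rng(truth, _STREAM_GROUP, replicate)
    n, tau = truth.n_subjects, truth.subject_sd_pct
    n_net = truth.n_network_voxels
    if n_net > n_voxels:
        raise ValueError("more network voxels than voxels")

    subjects = np.repeat(np.arange(n), 2)
    conditions = np.array(list(CONDITIONS) * n)

    seeds: dict[tuple[str, str], np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    for portion in BODY_PORTIONS:
        for sf in SUBFIELDS:
            g = rng.standard_normal((n, 2))
            mu = float(truth.effect_map[(sf, portion)])
            vals = np.column_stack([mu + tau * g[:, 0], tau * g[:, 1]])
            seeds[(portion, sf)] = vals.reshape(-1)
            if (portion, sf) == (truth.seed_portion, truth.seed_subfield):
                latent = {"AM": g[:, 0], "MA": g[:, 1]}

    mu_net = float(truth.effect_map[(truth.seed_subfield, truth.seed_portion)])
    X = tau * rng.standard_normal((2 * n, n_voxels))
    r_of = {"AM": truth.seed_network_r_am, "MA": truth.seed_network_r_ma}
    for ci, cond in enumerate(CONDITIONS):
        rows = np.arange(ci, 2 * n, 2)
        r = r_of[cond]
        w = rng.standard_normal((n, n_net))
        X[np.ix_(rows, np.arange(n_net))] = tau * (
            r * latent[cond][:, None] + np.sqrt(1.0 - r**2) * w
        )
        if cond == "AM":
            X[np.ix_(rows, np.arange(n_net))] += mu_net
    return StackedBrainMatrix(X=X, conditions=conditions, subjects=subjects), seeds


def simulate_group_null(
    n_subjects: int, n_voxels: int, rng: np.random.Generator
) -> StackedBrainMatrix:
    """Exchangeable null data: iid standard-normal subject-condition rows."""
    subjects = np.repeat(np.arange(n_subjects), 2)
    conditions = np.array(list(CONDITIONS) * n_subjects)
    X = rng.standard_normal((2 * n_subjects, n_voxels))
    return StackedBrainMatrix(X=X, conditions=conditions, subjects=subjects)
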