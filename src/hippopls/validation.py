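"""Validation experiments that exercise the full analysis stack.

Each function runs a self-contained study on synthetic data with known
ground truth and returns the measured quantities.  They are used by the
test suite and by ``scripts/acceptance.py``; all randomness derives from
the ``seed`` argument.
"""
from __future__ import annotations

import numpy as np

from . import glm, pls, synthgen
from .groupstats import rm_anova_oneway
from .hrf import dct_drift_basis
from .pipeline import RunConfig, run_all
from .types import BODY_PORTIONS, PORTIONS, SUBFIELDS, SimulationTruth, default_effect_map

# the reduced lattice used for voxel-level experiments
DESK_GEOM = dict(
    grid_shape=(20, 12, 30),
    n_trials=12,
    n_slices_mean=21,
    n_slices_sd=1.0,
    n_anterior_mean=5,
    n_anterior_sd=0.5,
    n_network_voxels=80,
)


def svd_oracle_gap(seed: int = 0, n_subjects: int = 24, n_voxels: int = 2000):
    """Mean-centered PLS vs a directly constructed SVD; seed rows vs a loop.

    Returns ``(mean_centered_gap, seed_row_gap)``: the largest absolute
    deviation between the package's decomposition (singular values and
    saliences, sign-aligned) and an independent construction, and between
    the vectorized seed-correlation rows and a naive per-voxel loop.
    """
    rng = np.random.default_rng([seed, 21])
    X = synthgen.simulate_group_null(n_subjects, n_voxels, rng)

    # independent construction of the mean-centered matrix and its SVD
    am = X.X[X.conditions == "AM"]
    ma = X.X[X.conditions == "MA"]
    M_ref = np.stack([am.mean(axis=0), ma.mean(axis=0)])
    M_ref = M_ref - M_ref.mean(axis=0)
    U_ref, S_ref, Vt_ref = np.linalg.svd(M_ref, full_matrices=False)

    M = pls.build_mean_centered(X)
    U, S, V = pls.pls_svd(M)
    gap = float(np.abs(S - S_ref).max())
    for i in range(U.shape[1]):
        sign = np.sign(U_ref[np.argmax(np.abs(U_ref[:, i])), i]) or 1.0
        gap = max(gap, float(np.abs(U[:, i] - sign * U_ref[:, i]).max()))
        gap = max(gap, float(np.abs(V[:, i] - sign * Vt_ref[i]).max()))

    seed_vec = rng.standard_normal(2 * n_subjects)
    R = pls.build_seed_matrix(X, seed_vec)
    seed_gap = 0.0
    for ci, cond in enumerate(X.condition_list):
        idx = X.conditions == cond
        for v in range(0, n_voxels, max(1, n_voxels // 200)):  # dense spot check
            r_ref = np.corrcoef(seed_vec[idx], X.X[idx, v])[0, 1]
            seed_gap = max(seed_gap, abs(float(R[ci, v] - r_ref)))
    return gap, seed_gap


def null_permutation_rate(
    seed: int = 0,
    n_reps: int = 100,
    n_perm: int = 200,
    n_subjects: int = 24,
    n_voxels: int = 2000,
) -> float:
    """Fraction of null replicates with LV1 permutation p < 0.05."""
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep, 11])
        X = synthgen.simulate_group_null(n_subjects, n_voxels, rng)
        if pls.permute_significance(X, n_perm=n_perm, rng=rng)[0] < 0.05:
            hits += 1
    return hits / n_reps


def anova_recovery(seed: int = 0, n_reps: int = 50) -> dict[str, float]:
    """Portion-wise RM-ANOVA on the planted truth, replicate rates.

    Returns the rate at which the anterior-body ANOVA is significant with
    the pre/parasubiculum as the highest level, and the significance rates
    of the (null) posterior-body and tail ANOVAs.
    """
    counts = {"anterior_body_recovered": 0, "posterior_body_sig": 0, "tail_sig": 0}
    for rep in range(n_reps):
        truth = SimulationTruth(rng_seed=seed)
        table = synthgen.simulate_roi_differentials(truth, replicate=rep)
        res = {}
        for portion in BODY_PORTIONS:
            pivot = table[table["portion"] == portion].pivot(
                index="subject", columns="subfield", values="value"
            )[list(SUBFIELDS)]
            res[portion] = rm_anova_oneway(pivot, levels=list(SUBFIELDS), posthoc=False)
        ab = res["anterior_body"]
        if ab.p < 0.05 and ab.best_level == "pre/parasubiculum":
            counts["anterior_body_recovered"] += 1
        counts["posterior_body_sig"] += res["posterior_body"].p < 0.05
        counts["tail_sig"] += res["tail"].p < 0.05
    return {k: v / n_reps for k, v in counts.items()}


def connectivity_recovery(
    seed: int = 0, n_reps: int = 25, n_perm: int = 200, n_boot: int = 100
) -> dict[str, float]:
    """Seed-PLS battery selectivity and BSR rates on the planted network.

    A replicate counts as a joint success when the battery flags only the
    anterior-body omnibus (alpha 0.05) and only the pre/parasubiculum
    follow-up (alpha 0.01).  BSR rates are measured over the planted
    network voxels and the remaining null voxels whenever the planted
    follow-up fires.
    """
    truth = SimulationTruth(rng_seed=seed)
    n_net = truth.n_network_voxels
    joint = 0
    hit_rates, fp_rates = [], []
    for rep in range(n_reps):
        X, seeds = synthgen.simulate_group_connectivity(truth, n_voxels=2000, replicate=rep)
        rng = np.random.default_rng([seed, rep, 7])
        res = pls.run_seed_pls_battery(
            X, seeds, portions=BODY_PORTIONS, subfields=SUBFIELDS,
            n_perm=n_perm, n_boot=n_boot, rng=rng,
        )
        ab, pb, tl = (res[p] for p in BODY_PORTIONS)
        ok = (
            ab.omnibus_p < 0.05
            and pb.omnibus_p >= 0.05
            and tl.omnibus_p >= 0.05
            and ab.followup_p.get(truth.seed_subfield, 1.0) < 0.01
            and all(p >= 0.01 for sf, p in ab.followup_p.items() if sf != truth.seed_subfield)
        )
        joint += ok
        if truth.seed_subfield in ab.bootstrap:
            bsr = ab.bootstrap[truth.seed_subfield].bsr[:, 0]
            hit_rates.append(float(np.mean(np.abs(bsr[:n_net]) > 3)))
            fp_rates.append(float(np.mean(np.abs(bsr[n_net:]) > 3)))
    return {
        "joint_selectivity": joint / n_reps,
        "network_bsr_hit": float(np.mean(hit_rates)) if hit_rates else 0.0,
        "null_bsr_false_positive": float(np.mean(fp_rates)) if fp_rates else 0.0,
    }


def _extract_differentials(truth: SimulationTruth, subject_id: int):
    schedule = synthgen.make_schedule(truth, subject_id)
    labels = synthgen.make_label_volume(truth, subject_id)
    run, motion = synthgen.synthesize_bold(truth, schedule, labels, subject_id)
    run = glm.discard_leading_volumes(run, truth.n_discard)
    motion = motion.drop_leading(truth.n_discard)
    design = glm.build_design(
        schedule, motion, truth.tr_s,
        n_volumes=run.n_volumes, t0_s=truth.n_discard * truth.tr_s,
    )
    fit = glm.fit_glm(run, design, mask=labels.labels > 0)
    psc = {c: glm.percent_signal_change(fit, c) for c in ("AM", "MA")}
    from .roi import extract_roi_signal, partition_long_axis

    return extract_roi_signal(psc, labels, partition_long_axis(labels), subject=subject_id)


def glm_noiseless_max_rel_err(seed: int = 0) -> float:
    """Largest relative recovery error of the planted effect, noiseless."""
    truth = SimulationTruth(
        n_subjects=2, rng_seed=seed, noise_sd=0.0, drift_amplitude=0.0,
        global_noise_sd=0.0, subject_sd_pct=0.0, latent_amp_pct=0.0, **DESK_GEOM,
    )
    table = _extract_differentials(truth, 0)
    diff = table[
        (table["condition"] == "AM_minus_MA") & (table["portion"].isin(PORTIONS))
    ].dropna(subset=["value"])
    worst = 0.0
    for row in diff.itertuples():
        planted = truth.effect_map[(row.subfield, row.portion)]
        worst = max(worst, abs(row.value - planted) / max(abs(planted), 1e-12))
    return worst


def glm_recovery_bias(seed: int = 0, n_subjects: int = 10, effect_pct: float = 0.6) -> float:
    """Relative bias of recovered percent signal change at default noise.

    Every cell carries the same planted effect; between-subject amplitude
    variability and the latent channel are off so the estimate isolates the
    estimation chain (smoothing, design sampling, OLS, extraction).
    """
    truth = SimulationTruth(
        n_subjects=n_subjects, rng_seed=seed,
        effect_map=default_effect_map(effect_pct, effect_pct),
        subject_sd_pct=0.0, latent_amp_pct=0.0, **DESK_GEOM,
    )
    estimates = []
    for s in range(n_subjects):
        table = _extract_differentials(truth, s)
        diff = table[
            (table["condition"] == "AM_minus_MA") & (table["portion"].isin(PORTIONS))
        ].dropna(subset=["value"])
        estimates.extend(diff["value"].tolist())
    return float(np.mean(estimates) - effect_pct) / effect_pct


def inband_drift_residual(seed: int = 0, n_volumes: int = 259, tr_s: float = 3.4) -> float:
    """Residual energy fraction of a 1/128-Hz-band drift after the GLM drift set."""
    B = dct_drift_basis(n_volumes, tr_s, highpass_s=128.0)
    rng = np.random.default_rng([seed, 31])
    drift = B @ rng.standard_normal(B.shape[1])
    X = np.column_stack([np.ones(n_volumes), B])
    resid = drift - X @ np.linalg.lstsq(X, drift, rcond=None)[0]
    return float((resid**2).sum() / (drift**2).sum())


def pipeline_recovery(seed: int = 0) -> dict:
    """One small end-to-end run; did the winning cell match the plant?"""
    truth = SimulationTruth(
        n_subjects=6, rng_seed=seed, effect_map=default_effect_map(0.2, 1.0), **DESK_GEOM
    )
    cfg = RunConfig(truth=truth, n_perm=100, n_boot=20, cluster_min_voxels=10)
    res = run_all(cfg)
    return res.summary
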