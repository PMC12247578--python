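import pytest

import hippopls as hp
from hippopls.types import default_effect_map

# desk-scale geometry shared by most voxel-level tests
SMALL_GEOM = dict(
    grid_shape=(20, 12, 30),
    n_trials=12,
    n_slices_mean=21,
    n_slices_sd=1.0,
    n_anterior_mean=5,
    n_anterior_sd=0.5,
    n_network_voxels=80,
)


@pytest.fixture(scope="session")
def small_truth():
    """A noisy small cohort with a strong planted anterior-body effect."""
    return hp.SimulationTruth(
        n_subjects=6,
        rng_seed=5,
        effect_map=default_effect_map(0.2, 1.0),
        **SMALL_GEOM,
    )


@pytest.fixture(scope="session")
def noiseless_truth():
    """All stochastic signal components off: exact-recovery regime."""
    return hp.SimulationTruth(
        n_subjects=2,
        rng_seed=1,
        noise_sd=0.0,
        drift_amplitude=0.0,
        global_noise_sd=0.0,
        subject_sd_pct=0.0,
        latent_amp_pct=0.0,
        **SMALL_GEOM,
    )


@pytest.fixture(scope="session")
def fixed_labels(noiseless_truth):
    return hp.make_label_volume(noiseless_truth, 0)


def extract_differentials(truth, subject_id):
    """Run one subject through synthesize -> GLM -> ROI extraction."""
    schedule = hp.make_schedule(truth, subject_id)
    labels = hp.make_label_volume(truth, subject_id)
    run, motion = hp.synthesize_bold(truth, schedule, labels, subject_id)
    run = hp.discard_leading_volumes(run, truth.n_discard)
    motion = motion.drop_leading(truth.n_discard)
    design = hp.build_design(
        schedule,
        motion,
        truth.tr_s,
        n_volumes=run.n_volumes,
        t0_s=truth.n_discard * truth.tr_s,
    )
    fit = hp.fit_glm(run, design, mask=labels.labels > 0)
    psc = {c: hp.percent_signal_change(fit, c) for c in ("AM", "MA")}
    partition = hp.partition_long_axis(labels)
    table = hp.extract_roi_signal(psc, labels, partition, subject=subject_id)
    return table


@pytest.fixture(scope="session")
def noiseless_table(noiseless_truth):
    return extract_differentials(noiseless_truth, 0)
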