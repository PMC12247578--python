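"""Mean-centered task PLS and seed PLS with resampling inference.

Mean-centered PLS decomposes the condition-mean brain matrix (after
removing the grand mean across conditions) by SVD into ranked latent
variables (LVs); each LV is a triple of design salience, voxel salience,
and singular value.  Seed PLS replaces the condition means with rows of
per-condition across-subject correlations between a seed ROI's signal and
every voxel, turning the same machinery into a functional-connectivity
analysis.

Inference follows the standard two-resampling scheme: LV significance by
permuting condition labels within subject (add-one permutation p-values),
and voxel reliability by bootstrap resampling of subjects, with each
bootstrap solution aligned to the original by orthogonal Procrustes
rotation before forming bootstrap ratios (BSR = salience / bootstrap SE).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.linalg import orthogonal_procrustes

log = logging.getLogger(__name__)


def _as_rng(rng) -> np.random.Generator:
    if hasattr(rng, "integers") and hasattr(rng, "permutation"):
        return rng  # a Generator (or a test double with the same surface)
    return np.random.default_rng(rng)


@dataclass
class StackedBrainMatrix:
    """Subject-within-condition observations by voxels.

    ``X`` has one row per (subject, condition); ``mask_flat``/``grid_shape``
    optionally map columns back onto a 3D lattice for cluster reporting.
    """

    X: np.ndarray
    conditions: np.ndarray
    subjects: np.ndarray
    mask_flat: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.conditions = np.asarray(self.conditions)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 2 or len(self.conditions) != self.X.shape[0] or len(
            self.subjects
        ) != self.X.shape[0]:
            raise ValueError("conditions/subjects must label each row of X")
        # every subject contributes exactly one row per condition
        conds = self.condition_list
        for s in np.unique(self.subjects):
            row_conds = sorted(self.conditions[self.subjects == s].tolist())
            if row_conds != sorted(conds):
                raise ValueError(f"subject {s!r} does not have one row per condition")

    @property
    def condition_list(self) -> list:
        seen: list = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def subject_list(self) -> list:
        seen: list = []
        for s in self.subjects:
            if s not in seen:
                seen.append(s)
        return seen

    def rows_by_subject(self) -> np.ndarray:
        """(n_subjects, n_conditions) row indices, original labelling."""
        conds = self.condition_list
        subs = self.subject_list
        out = np.empty((len(subs), len(conds)), int)
        for i, s in enumerate(subs):
            for j, c in enumerate(conds):
                out[i, j] = int(
                    np.flatnonzero((self.subjects == s) & (self.conditions == c))[0]
                )
        return out


def stack_contrast_maps(
    maps: dict[tuple, np.ndarray], mask: np.ndarray
) -> StackedBrainMatrix:
    """Stack (subject, condition) 3D maps into a brain matrix over a mask.

    All-zero voxel columns are removed from the mask and recorded in the
    log, per the stacking invariant.
    """
    mask = np.asarray(mask, bool)
    mask_flat = np.flatnonzero(mask.reshape(-1))
    keys = sorted(maps, key=lambda k: (k[0], k[1]))
    rows = np.stack(
        [np.asarray(maps[k], float).reshape(-1)[mask_flat] for k in keys]
    )
    nonzero = ~(rows == 0).all(axis=0)
    if not nonzero.all():
        log.info("masking out %d all-zero voxel columns", int((~nonzero).sum()))
    return StackedBrainMatrix(
        X=rows[:, nonzero],
        conditions=np.array([k[1] for k in keys]),
        subjects=np.array([k[0] for k in keys]),
        mask_flat=mask_flat[nonzero],
        grid_shape=mask.shape,
    )


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def build_mean_centered(X: StackedBrainMatrix) -> np.ndarray:
    """Condition-mean matrix minus the column-wise grand mean (C x V)."""
    conds = X.condition_list
    if len(conds) < 2:
        raise ValueError("mean-centered PLS needs at least two conditions")
    M = np.stack([X.X[X.conditions == c].mean(axis=0) for c in conds])
    return M - M.mean(axis=0, keepdims=True)


def _corr_rows(seed: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``seed`` with every column of ``data``."""
    sc = seed - seed.mean()
    dc = data - data.mean(axis=0, keepdims=True)
    num = sc @ dc
    denom = np.sqrt((sc @ sc) * (dc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    n_bad = int((denom == 0).sum())
    if n_bad:
        log.warning("zero-variance seed or voxel in %d columns; correlations set to 0", n_bad)
    return r


def build_seed_matrix(X: StackedBrainMatrix, seed: np.ndarray) -> np.ndarray:
    """Condition-wise seed-voxel correlation matrix (C x V).

    Row ``c`` is the across-subject Pearson correlation, within condition
    ``c``, between the seed values and each voxel column.  Following the
    correlation reading of seed PLS, the matrix is NOT mean-centered across
    conditions.
    """
    seed = np.asarray(seed, float)
    if seed.shape != (X.X.shape[0],):
        raise ValueError("seed must hold one value per subject-condition row")
    if len(X.subject_list) < 3:
        raise ValueError("seed PLS needs at least three subjects")
    rows = []
    for c in X.condition_list:
        idx = X.conditions == c
        rows.append(_corr_rows(seed[idx], X.X[idx]))
    return np.stack(rows)


def build_multi_seed_matrix(
    X: StackedBrainMatrix, seeds: dict[str, np.ndarray]
) -> np.ndarray:
    """Stack seed-correlation rows over several seeds (omnibus form).

    Rows are ordered seed-major then condition, giving
    ``len(seeds) * n_conditions`` rows.
    """
    return np.vstack([build_seed_matrix(X, seeds[name]) for name in seeds])


def pls_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the PLS matrix: M = U S V', singular values descending.

    Sign convention: each LV is oriented so that its largest-magnitude
    design salience is positive.
    """
    M = np.asarray(M, float)
    if not np.all(np.isfinite(M)):
        raise ValueError("PLS matrix must be finite")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1.0
            V[:, i] *= -1.0
    return U, S, V


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _build(X: StackedBrainMatrix, row_order: np.ndarray | None, seeds) -> np.ndarray:
    """Build the PLS matrix, optionally under a row relabelling.

    ``row_order[s, c]`` gives the row index whose data play the role of
    condition ``c`` for subject ``s`` (identity when None).
    """
    if row_order is None:
        data = X
    else:
        idx = row_order.T.reshape(-1)  # condition-major
        conds = np.repeat(X.condition_list, row_order.shape[0])
        subs = np.tile(X.subject_list, row_order.shape[1])
        data = StackedBrainMatrix(
            X=X.X[idx], conditions=conds, subjects=subs,
            mask_flat=X.mask_flat, grid_shape=X.grid_shape,
        )
        if seeds is not None:
            seeds = (
                {k: v[idx] for k, v in seeds.items()}
                if isinstance(seeds, dict)
                else seeds[idx]
            )
    if seeds is None:
        return build_mean_centered(data)
    if isinstance(seeds, dict):
        return build_multi_seed_matrix(data, seeds)
    return build_seed_matrix(data, seeds)


def _permute_seed_values(
    X: StackedBrainMatrix,
    seed: np.ndarray | dict[str, np.ndarray],
    rng: np.random.Generator,
):
    """Shuffle seed values across subjects within each condition.

    One subject permutation is drawn per condition and applied to every
    seed jointly, so inter-seed structure is preserved while the
    seed-brain pairing is broken (the classic behavior/seed-PLS exchange
    scheme).
    """
    vecs = seed if isinstance(seed, dict) else {None: seed}
    out = {k: np.array(v, float, copy=True) for k, v in vecs.items()}
    for c in X.condition_list:
        idx = np.flatnonzero(X.conditions == c)
        perm = rng.permutation(len(idx))
        for k in out:
            out[k][idx] = out[k][idx][perm]
    return out if isinstance(seed, dict) else out[None]


def permute_significance(
    X: StackedBrainMatrix,
    seed: np.ndarray | dict[str, np.ndarray] | None = None,
    n_perm: int = 500,
    rng=None,
) -> np.ndarray:
    """Permutation p-value per LV.

    Mean-centered PLS permutes condition labels within subject.  Seed PLS
    permutes the seed values across subjects within each condition,
    breaking the seed-brain pairing while leaving both the brain rows and
    the seed's condition means intact (shuffling conditions jointly for
    seed and brain would let shared activation differences contaminate the
    permuted correlations).  Uses the add-one estimator
    ``p_i = (1 + #{s_perm,i >= s_obs,i}) / (1 + n_perm)`` with permuted
    singular values matched to observed LVs by rank.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = _as_rng(rng)
    rows = X.rows_by_subject()
    n_sub, n_cond = rows.shape
    n_distinct = (
        factorial(n_cond) ** n_sub if seed is None else factorial(n_sub) ** n_cond
    )
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct permutations; "
            "sampling with replacement from the permutation group"
        )
    _, s_obs, _ = pls_svd(_build(X, None, seed))
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        if seed is None:
            perm = np.stack([rng.permutation(n_cond) for _ in range(n_sub)])
            order = np.take_along_axis(rows, perm, axis=1)
            _, s_perm, _ = pls_svd(_build(X, order, seed))
        else:
            shuffled = _permute_seed_values(X, seed, rng)
            _, s_perm, _ = pls_svd(_build(X, None, shuffled))
        k = min(len(s_perm), len(s_obs))
        exceed[:k] += s_perm[:k] >= s_obs[:k]
    return (1.0 + exceed) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    bsr: np.ndarray  # voxels x LVs
    boot_sd: np.ndarray
    saliences: np.ndarray  # original voxel saliences, voxels x LVs
    n_boot: int


def compute_bsr(original: np.ndarray, boot_stack: np.ndarray) -> np.ndarray:
    """Bootstrap ratio: original salience / SD over bootstrap saliences.

    Voxels whose bootstrap SE is zero (or indistinguishable from rounding
    error) get NaN (masked) with a log message.
    """
    sd = boot_stack.std(axis=0, ddof=1)
    defined = sd > 1e-10 * (1.0 + np.abs(original))
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(defined, original / sd, np.nan)
    n_bad = int((~defined).sum())
    if n_bad:
        log.warning("zero bootstrap SE at %d voxels; BSR masked", n_bad)
    return bsr


def bootstrap_bsr(
    X: StackedBrainMatrix,
    seed: np.ndarray | dict[str, np.ndarray] | None = None,
    n_boot: int = 100,
    rng=None,
) -> BootstrapResult:
    """Voxel-salience bootstrap ratios by subject resampling.

    Subjects are drawn with replacement (keeping each subject's full
    condition set); each bootstrap solution is aligned to the original by
    an orthogonal Procrustes rotation of its design saliences before the
    voxel saliences enter the SD.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = _as_rng(rng)
    rows = X.rows_by_subject()
    n_sub, n_cond = rows.shape
    U0, S0, V0 = pls_svd(_build(X, None, seed))

    boots = np.empty((n_boot, V0.shape[0], V0.shape[1]))
    for b in range(n_boot):
        pick = rng.integers(0, n_sub, size=n_sub)
        idx = rows[pick].T.reshape(-1)  # condition-major rows
        Xb = StackedBrainMatrix(
            X=X.X[idx],
            conditions=np.repeat(X.condition_list, n_sub),
            subjects=np.tile(np.arange(n_sub), n_cond),
        )
        if seed is None:
            Mb = build_mean_centered(Xb)
        elif isinstance(seed, dict):
            Mb = build_multi_seed_matrix(Xb, {k: v[idx] for k, v in seed.items()})
        else:
            Mb = build_seed_matrix(Xb, seed[idx])
        Ub, Sb, Vb = pls_svd(Mb)
        k = min(U0.shape[1], Ub.shape[1])
        R, _ = orthogonal_procrustes(Ub[:, :k], U0[:, :k])
        boots[b, :, :k] = Vb[:, :k] @ R
    return BootstrapResult(
        bsr=compute_bsr(V0, boots), boot_sd=boots.std(axis=0, ddof=1),
        saliences=V0, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# cluster reporting
# ---------------------------------------------------------------------------

def cluster_bsr(
    bsr_values: np.ndarray,
    mask_flat: np.ndarray,
    grid_shape: tuple[int, int, int],
    threshold: float = 3.0,
    min_size: int = 50,
    lv: int = 1,
) -> pd.DataFrame:
    """Connected supra-threshold clusters of a BSR map (face connectivity).

    Positive and negative BSR voxels are clustered separately; clusters
    smaller than ``min_size`` voxels are dropped.  Returns one row per
    cluster with its sign, voxel count, peak |BSR| and peak coordinate.
    """
    vol = np.zeros(grid_shape)
    vol.reshape(-1)[mask_flat] = np.nan_to_num(np.asarray(bsr_values, float))
    structure = ndimage.generate_binary_structure(3, 1)
    rows = []
    for sign, binary in ((1, vol > threshold), (-1, vol < -threshold)):
        labeled, n = ndimage.label(binary, structure=structure)
        for lab in range(1, n + 1):
            members = labeled == lab
            size = int(members.sum())
            if size < min_size:
                continue
            absvals = np.where(members, np.abs(vol), -np.inf)
            peak = np.unravel_index(int(np.argmax(absvals)), grid_shape)
            rows.append(
                {
                    "lv": lv,
                    "sign": sign,
                    "n_voxels": size,
                    "peak_bsr": float(vol[peak]) ,
                    "peak_x": int(peak[0]),
                    "peak_y": int(peak[1]),
                    "peak_z": int(peak[2]),
                }
            )
    return pd.DataFrame(
        rows, columns=["lv", "sign", "n_voxels", "peak_bsr", "peak_x", "peak_y", "peak_z"]
    )


# ---------------------------------------------------------------------------
# model assembly and the seed-PLS battery
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    method: str  # "mean_centered" or "seed"
    singular_values: np.ndarray
    design_saliences: np.ndarray  # conditions x LVs
    voxel_saliences: np.ndarray  # voxels x LVs
    brain_scores: np.ndarray  # rows x LVs
    perm_p: np.ndarray
    bsr: np.ndarray | None = None
    clusters: pd.DataFrame | None = None
    n_perm: int = 0
    n_boot: int = 0


def fit_pls(
    X: StackedBrainMatrix,
    seed: np.ndarray | dict[str, np.ndarray] | None = None,
    n_perm: int = 500,
    n_boot: int = 100,
    rng=None,
    bsr_threshold: float = 3.0,
    cluster_min: int = 50,
) -> PlsModel:
    """Run a full PLS analysis: SVD, permutation p-values, BSR, clusters."""
    rng = _as_rng(rng)
    M = _build(X, None, seed)
    U, S, V = pls_svd(M)
    perm_p = permute_significance(X, seed, n_perm=n_perm, rng=rng)
    boot = bootstrap_bsr(X, seed, n_boot=n_boot, rng=rng) if n_boot >= 2 else None
    clusters = None
    if boot is not None and X.mask_flat is not None and X.grid_shape is not None:
        tables = [
            cluster_bsr(
                boot.bsr[:, i], X.mask_flat, X.grid_shape,
                threshold=bsr_threshold, min_size=cluster_min, lv=i + 1,
            )
            for i in range(boot.bsr.shape[1])
        ]
        non_empty = [t for t in tables if not t.empty]
        clusters = pd.concat(non_empty, ignore_index=True) if non_empty else tables[0]
    return PlsModel(
        method="mean_centered" if seed is None else "seed",
        singular_values=S,
        design_saliences=U,
        voxel_saliences=V,
        brain_scores=X.X @ V,
        perm_p=perm_p,
        bsr=None if boot is None else boot.bsr,
        clusters=clusters,
        n_perm=n_perm,
        n_boot=0 if boot is None else n_boot,
    )


@dataclass
class PortionBatteryResult:
    portion: str
    omnibus_p: float
    followup_p: dict[str, float] = field(default_factory=dict)
    significant_subfields: list[str] = field(default_factory=list)
    bootstrap: dict[str, BootstrapResult] = field(default_factory=dict)


def run_seed_pls_battery(
    X: StackedBrainMatrix,
    seeds: dict[tuple[str, str], np.ndarray],
    portions: tuple[str, ...],
    subfields: tuple[str, ...],
    n_perm: int = 500,
    n_boot: int = 100,
    alpha_omnibus: float = 0.05,
    alpha_followup: float = 0.01,
    rng=None,
) -> dict[str, PortionBatteryResult]:
    """Portion-wise omnibus seed PLS with per-subfield follow-ups.

    For each long-axis portion the omnibus stacks the seed-correlation rows
    of all subfields (multi-seed row stacking) and tests LV1 at
    ``alpha_omnibus``; where significant, five per-subfield seed PLS
    analyses are judged at the Bonferroni-corrected ``alpha_followup``,
    with bootstrap ratios computed for each surviving subfield.  Missing
    seeds are skipped with a warning.
    """
    rng = _as_rng(rng)
    results: dict[str, PortionBatteryResult] = {}
    for portion in portions:
        avail = {
            sf: seeds[(portion, sf)] for sf in subfields if (portion, sf) in seeds
        }
        missing = [sf for sf in subfields if sf not in avail]
        if missing:
            warnings.warn(f"portion {portion}: missing seeds for {missing}; skipped")
        if not avail:
            continue
        omnibus_p = float(permute_significance(X, avail, n_perm=n_perm, rng=rng)[0])
        res = PortionBatteryResult(portion=portion, omnibus_p=omnibus_p)
        if omnibus_p < alpha_omnibus:
            for sf, vec in avail.items():
                p = float(permute_significance(X, vec, n_perm=n_perm, rng=rng)[0])
                res.followup_p[sf] = p
                if p < alpha_followup:
                    res.significant_subfields.append(sf)
                    res.bootstrap[sf] = bootstrap_bsr(X, vec, n_boot=n_boot, rng=rng)
        results[portion] = res
    return results
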