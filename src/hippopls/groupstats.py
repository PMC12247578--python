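"""Group-level univariate statistics on ROI signal tables.

One-sample/paired t-tests with Bonferroni correction, and a one-way
repeated-measures ANOVA whose follow-ups (Tukey HSD, Dunnett) use the
within-subject error term — the "univariate" repeated-measures approach:

    F = MS_levels / MS_(levels x subjects),
    df = (k - 1), (k - 1)(n - 1).

No sphericity correction is applied by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    mean_diff: float
    p_adj: float
    procedure: str


@dataclass
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    level_means: dict[str, float]
    ms_error: float
    n_subjects: int
    pairwise: list[PairwiseComparison]

    @property
    def best_level(self) -> str:
        return max(self.level_means, key=self.level_means.get)


def paired_t(diffs: np.ndarray) -> tuple[float, int, float]:
    """One-sample t on per-subject differences; two-sided p."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("need at least two subjects")
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance in differences")
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), d.size - 1, float(p)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p * m)``; ``m`` defaults to len(pvals)."""
    p = np.atleast_1d(np.asarray(pvals, float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def _dunnett_p(t_obs: float, n_comparisons: int, df: int, tol_maxpts: int = 200_000) -> float:
    """Two-sided Dunnett-adjusted p via multivariate-t box probability.

    Under the balanced design all comparison statistics share correlation
    1/2, so ``p = 1 - P(max_j |T_j| <= |t|)`` with T multivariate t.
    """
    m = n_comparisons
    if m == 1:
        return float(2 * stats.t.sf(abs(t_obs), df))
    shape = np.full((m, m), 0.5)
    np.fill_diagonal(shape, 1.0)
    dist = stats.multivariate_t(loc=np.zeros(m), shape=shape, df=df)
    a = abs(t_obs)
    prob = dist.cdf(
        np.full(m, a),
        lower_limit=np.full(m, -a),
        random_state=np.random.default_rng(0),
        maxpts=tol_maxpts,
    )
    return float(np.clip(1.0 - prob, 0.0, 1.0))


def rm_anova_oneway(
    values: np.ndarray | pd.DataFrame,
    levels: list[str] | None = None,
    control: str | None = None,
    posthoc: bool = True,
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels table.

    Tukey HSD follow-ups on all level pairs use the RM error term; if
    ``control`` names a level, Dunnett comparisons of every other level
    against it are appended.  ``posthoc=False`` skips the pairwise stage
    (useful in simulation loops).  Subjects with any missing cell are
    dropped listwise with a log message.
    """
    if isinstance(values, pd.DataFrame):
        levels = [str(c) for c in values.columns] if levels is None else levels
        X = values.to_numpy(float)
    else:
        X = np.asarray(values, float)
        if levels is None:
            levels = [f"level_{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D table with at least two levels")
    complete = np.isfinite(X).all(axis=1)
    if not complete.all():
        log.warning("dropping %d subjects with missing cells", int((~complete).sum()))
        X = X[complete]
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least two complete subjects")

    grand = X.mean()
    level_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_levels = n * ((level_means - grand) ** 2).sum()
    resid = X - level_means[None, :] - subj_means[:, None] + grand
    ss_error = (resid**2).sum()
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error == 0:
        raise ValueError("zero within-subject error variance; F undefined")
    F = (ss_levels / df_effect) / ms_error
    p = float(stats.f.sf(F, df_effect, df_error))

    pairwise: list[PairwiseComparison] = []
    se_tukey = np.sqrt(ms_error / n)
    for i, j in combinations(range(k), 2) if posthoc else ():
        diff = level_means[i] - level_means[j]
        q = abs(diff) / se_tukey
        p_adj = float(stats.studentized_range.sf(q, k, df_error))
        pairwise.append(
            PairwiseComparison(levels[i], levels[j], float(diff), min(1.0, p_adj), "tukey")
        )
    if control is not None and posthoc:
        if control not in levels:
            raise ValueError(f"control level {control!r} not among levels")
        ci = levels.index(control)
        others = [i for i in range(k) if i != ci]
        se_d = np.sqrt(2.0 * ms_error / n)
        for i in others:
            t_obs = (level_means[i] - level_means[ci]) / se_d
            pairwise.append(
                PairwiseComparison(
                    levels[i],
                    control,
                    float(level_means[i] - level_means[ci]),
                    _dunnett_p(t_obs, len(others), df_error),
                    "dunnett",
                )
            )
    return RmAnovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        level_means={lv: float(m) for lv, m in zip(levels, level_means)},
        ms_error=float(ms_error),
        n_subjects=n,
        pairwise=pairwise,
    )
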