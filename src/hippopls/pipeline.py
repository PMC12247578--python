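"""End-to-end orchestration: simulate -> QC -> GLM -> ROI -> stats -> PLS.

``run_all`` executes the full analysis on a synthetic cohort and returns a
results bundle whose summary compares the recovered effects with the
planted ground truth.  All randomness derives from the configuration's
``rng_seed``; running the same configuration twice yields byte-identical
summaries.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, pls, roi, synthgen
from .groupstats import RmAnovaResult, bonferroni, paired_t, rm_anova_oneway
from .types import BODY_PORTIONS, SUBFIELDS, SimulationTruth

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    fwhm_native_mm: float = 1.0
    fwhm_group_mm: float = 6.0
    highpass_s: float = 128.0
    alpha: float = 0.05
    alpha_followup: float = 0.01
    n_perm: int = 500
    n_boot: int = 100
    bsr_threshold: float = 3.0
    cluster_min_voxels: int = 50
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for a in (self.alpha, self.alpha_followup):
            if not 0 < a < 1:
                raise ValueError("alpha thresholds must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"]["effect_map"] = {
            f"{sf}|{p}": v for (sf, p), v in self.truth.effect_map.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        t = dict(d.pop("truth", {}))
        if "effect_map" in t:
            t["effect_map"] = {tuple(k.split("|")): float(v) for k, v in t["effect_map"].items()}
        for key in ("grid_shape", "voxel_size_mm", "isi_range_s", "spike_volumes"):
            if key in t:
                t[key] = tuple(t[key])
        return cls(truth=SimulationTruth(**t), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResults:
    config: RunConfig | None = None
    qc: list[dict] = field(default_factory=list)
    roi_table: pd.DataFrame | None = None
    laterality: roi.LateralityTest | None = None
    subfield_t: pd.DataFrame | None = None
    anovas: dict[str, RmAnovaResult] = field(default_factory=dict)
    mean_centered: pls.PlsModel | None = None
    seed_battery: dict[str, pls.PortionBatteryResult] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _differential_pivot(table: pd.DataFrame, portion: str) -> pd.DataFrame:
    """Subjects x subfields table of bilateral AM-minus-MA values."""
    sel = table[
        (table["portion"] == portion)
        & (table["condition"] == "AM_minus_MA")
        & (table["hemisphere"] == "bilateral")
    ]
    return sel.pivot(index="subject", columns="subfield", values="value")[list(SUBFIELDS)]


def run_all(config: RunConfig) -> PipelineResults:
    """Execute every stage on a synthetic cohort defined by the config."""
    truth = config.truth
    results = PipelineResults(config=config)
    t_start = time.time()

    tables = []
    group_maps: dict[tuple[int, str], np.ndarray] = {}
    brain_mask = None
    for s in range(truth.n_subjects):
        stage = f"subject {s}"
        try:
            schedule = synthgen.make_schedule(truth, s)
            labels = synthgen.make_label_volume(truth, s)
            run, motion = synthgen.synthesize_bold(truth, schedule, labels, s)
            run = glm.discard_leading_volumes(run, truth.n_discard)
            motion_r = motion.drop_leading(truth.n_discard)
            qc = glm.detect_motion_outliers(run, motion_r)
            results.qc.append(
                {
                    "subject": s,
                    "outlier_fraction": qc.outlier_fraction,
                    "n_outliers": int(len(qc.outlier_volumes)),
                    "excluded": bool(qc.excluded),
                }
            )
            if qc.excluded:
                log.warning("subject %d excluded by motion QC", s)
                continue

            native = glm.smooth_gaussian(run, config.fwhm_native_mm)
            design = glm.build_design(
                schedule,
                motion_r,
                truth.tr_s,
                n_volumes=native.n_volumes,
                t0_s=truth.n_discard * truth.tr_s,
                highpass_s=config.highpass_s,
            )
            mask = (labels.labels > 0) | synthgen.neocortex_mask(truth)
            if brain_mask is None:
                brain_mask = synthgen.neocortex_mask(truth)
            fit = glm.fit_glm(native, design, mask=mask)
            psc = {c: glm.percent_signal_change(fit, c) for c in ("AM", "MA")}

            partition = roi.partition_long_axis(labels)
            tables.append(roi.extract_roi_signal(psc, labels, partition, subject=s))

            smoothed = {
                c: glm.smooth_gaussian(
                    glm.BoldRun(
                        data=m[..., np.newaxis],
                        voxel_size_mm=truth.voxel_size_mm,
                        tr_s=truth.tr_s,
                    ),
                    config.fwhm_group_mm,
                ).data[..., 0]
                for c, m in psc.items()
            }
            for c, m in smoothed.items():
                group_maps[(s, c)] = m
            brain_mask |= labels.labels > 0
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"pipeline stage failed at {stage}: {exc}") from exc

    if not tables:
        raise RuntimeError("pipeline stage failed at group level: no usable subjects")
    table = pd.concat(tables, ignore_index=True)
    table, results.laterality = roi.collapse_laterality(table, alpha=config.alpha)
    if not results.laterality.collapsed:  # keep bilateral rows available downstream
        log.warning("laterality detected; bilateral collapse forced for group stage")
        table = roi.bilateral_collapse(table)
    results.roi_table = table

    # whole-hippocampus per-subfield paired t (AM vs MA), Bonferroni over 5
    rows = []
    whole = _differential_pivot(table, "whole")
    for sf in SUBFIELDS:
        t, df, p = paired_t(whole[sf].dropna().to_numpy())
        rows.append({"subfield": sf, "t": t, "df": df, "p": p})
    tdf = pd.DataFrame(rows)
    tdf["p_bonferroni"] = bonferroni(tdf["p"].to_numpy(), m=len(SUBFIELDS))
    results.subfield_t = tdf

    # RM-ANOVA with Tukey follow-ups: whole plus each body portion
    for portion in ("whole",) + BODY_PORTIONS:
        pivot = _differential_pivot(table, portion).dropna()
        results.anovas[portion] = rm_anova_oneway(pivot, levels=list(SUBFIELDS))

    # group PLS
    rng = np.random.default_rng([truth.rng_seed, 909])
    X = pls.stack_contrast_maps(group_maps, brain_mask)
    results.mean_centered = pls.fit_pls(
        X,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        rng=rng,
        bsr_threshold=config.bsr_threshold,
        cluster_min=config.cluster_min_voxels,
    )

    # seed analyses target hippocampal-neocortical connectivity, so their
    # brain matrix is restricted to neocortex (otherwise each seed trivially
    # correlates with its own ROI voxels)
    X_neo = pls.stack_contrast_maps(group_maps, synthgen.neocortex_mask(truth))
    seeds = _seed_vectors(table, X_neo)
    results.seed_battery = pls.run_seed_pls_battery(
        X_neo,
        seeds,
        portions=BODY_PORTIONS,
        subfields=SUBFIELDS,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        alpha_omnibus=config.alpha,
        alpha_followup=config.alpha_followup,
        rng=rng,
    )

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    results.summary = _summarize(results)
    if config.out_dir:
        _write_outputs(results, Path(config.out_dir))
    return results


def _seed_vectors(table: pd.DataFrame, X: pls.StackedBrainMatrix):
    """Per-(portion, subfield) seed values aligned to the stacked rows."""
    seeds = {}
    for portion in BODY_PORTIONS:
        for sf in SUBFIELDS:
            sel = table[
                (table["portion"] == portion)
                & (table["subfield"] == sf)
                & (table["hemisphere"] == "bilateral")
                & table["condition"].isin(["AM", "MA"])
            ]
            lookup = {
                (int(r.subject), str(r.condition)): float(r.value)
                for r in sel.itertuples()
            }
            try:
                vec = np.array(
                    [
                        lookup[(int(s), str(c))]
                        for s, c in zip(X.subjects, X.conditions)
                    ]
                )
            except KeyError:
                log.warning("missing seed values for %s %s", portion, sf)
                continue
            if np.all(np.isfinite(vec)):
                seeds[(portion, sf)] = vec
    return seeds


def _summarize(results: PipelineResults) -> dict:
    truth = results.config.truth
    planted = max(truth.effect_map, key=truth.effect_map.get)
    anova_summary = {
        portion: {
            "F": round(res.F, 6),
            "df_effect": res.df_effect,
            "df_error": res.df_error,
            "p": round(res.p, 8),
            "significant": bool(res.p < results.config.alpha),
            "best_subfield": res.best_level,
        }
        for portion, res in results.anovas.items()
    }
    winning = None
    for portion in BODY_PORTIONS:
        res = results.anovas.get(portion)
        if res is not None and res.p < results.config.alpha:
            if winning is None or res.p < results.anovas[winning[1]].p:
                winning = (res.best_level, portion)
    battery = {
        portion: {
            "omnibus_p": round(r.omnibus_p, 8),
            "significant": bool(r.omnibus_p < results.config.alpha),
            "followup_p": {sf: round(p, 8) for sf, p in r.followup_p.items()},
            "significant_subfields": r.significant_subfields,
        }
        for portion, r in results.seed_battery.items()
    }
    mc = results.mean_centered
    return {
        "config_hash": results.config.config_hash(),
        "n_subjects_used": int(len({q["subject"] for q in results.qc if not q["excluded"]})),
        "laterality": {
            "t": round(results.laterality.t, 6),
            "p": round(results.laterality.p, 8),
            "collapsed": results.laterality.collapsed,
        },
        "subfield_t": {
            r["subfield"]: {
                "t": round(r["t"], 6),
                "df": int(r["df"]),
                "p_bonferroni": round(r["p_bonferroni"], 8),
            }
            for r in results.subfield_t.to_dict("records")
        },
        "rm_anova": anova_summary,
        "mean_centered_pls": {
            "lv1_p": round(float(mc.perm_p[0]), 8),
            "singular_values": [round(float(v), 6) for v in mc.singular_values],
            "n_clusters_lv1": int(
                0 if mc.clusters is None else (mc.clusters["lv"] == 1).sum()
            ),
        },
        "seed_battery": battery,
        "truth": {
            "planted_cell": {"subfield": planted[0], "portion": planted[1]},
            "planted_effect_pct": truth.effect_map[planted],
        },
        "recovered": {
            "winning_cell": None
            if winning is None
            else {"subfield": winning[0], "portion": winning[1]},
            "matches_truth": bool(
                winning is not None and (winning[0], winning[1]) == planted
            ),
        },
    }


def report(results: PipelineResults) -> tuple[str, dict]:
    """Human-readable markdown plus a machine summary for a results bundle.

    Missing stages are marked absent rather than failing, so a partially
    filled bundle still renders.
    """
    lines = ["# Pipeline report", ""]
    if results.config is not None:
        lines += [f"Config hash: `{results.config.config_hash()}`", ""]
    lines.append("## Motion QC")
    if results.qc:
        excluded = [q["subject"] for q in results.qc if q["excluded"]]
        lines.append(f"- {len(results.qc)} subjects screened; excluded: {excluded or 'none'}")
    else:
        lines.append("- absent")
    lines += ["", "## Repeated-measures ANOVA (AM minus MA, by portion)"]
    if results.anovas:
        for portion, res in results.anovas.items():
            lines.append(
                f"- {portion}: F({res.df_effect}, {res.df_error}) = {res.F:.3f}, "
                f"p = {res.p:.4g}, best subfield: {res.best_level}"
            )
    else:
        lines.append("- absent")
    lines += ["", "## Mean-centered PLS"]
    if results.mean_centered is not None:
        mc = results.mean_centered
        lines.append(f"- LV1 permutation p = {mc.perm_p[0]:.4g}")
        if mc.clusters is not None:
            lines.append(f"- {len(mc.clusters)} BSR clusters")
    else:
        lines.append("- absent")
    lines += ["", "## Seed PLS battery"]
    if results.seed_battery:
        for portion, r in results.seed_battery.items():
            mark = "significant" if r.significant_subfields else "n.s."
            lines.append(
                f"- {portion}: omnibus p = {r.omnibus_p:.4g} ({mark}); "
                f"subfields surviving follow-up: {r.significant_subfields or 'none'}"
            )
    else:
        lines.append("- absent")
    summary = results.summary or {}
    return "\n".join(lines) + "\n", summary


def _write_outputs(results: PipelineResults, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(results.config.to_dict(), sort_keys=True)
    )
    results.roi_table.to_csv(out_dir / "roi_signal_table.tsv", sep="\t", index=False)
    pd.DataFrame(results.qc).to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    if results.mean_centered is not None and results.mean_centered.clusters is not None:
        results.mean_centered.clusters.to_csv(
            out_dir / "mean_centered_clusters.tsv", sep="\t", index=False
        )
    md, summary = report(results)
    (out_dir / "report.md").write_text(md)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
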