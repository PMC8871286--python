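"""End-to-end orchestration: simulate → quantify → map → volumetrics → stats.

The central artefact is the long-format cohort result table, one row per
subject-timepoint with MRS-PDFF, MRI-PDFF over the colocalized VOI and over
the whole liver, and LV% at each declared threshold. Every statistic in the
report is computed from that table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .fatmap import fat_fraction_map, mean_pdff, place_voi, separate_two_point
from .grid import PDFFMap, VOISpec, VolumeGrid
from .mrs import AcquisitionConstants, MRSMeasurement, mrs_pdff
from .stats import (
    STEATOSIS_CUTOFF,
    bland_altman,
    rm_anova_two_way,
    roc_youden,
    spearman_rho,
    steatosis_label,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .synthetic import (
    BASELINE,
    WEEK8,
    GeneratorConfig,
    PhantomSubject,
    generate_cohort,
    write_cohort,
)
from .volumetrics import lv_percent_above, paired_changes

__all__ = [
    "PipelineConfig",
    "StudyResult",
    "lv_column",
    "measure_subject",
    "build_result_table",
    "analyze_cohort",
    "summarize",
    "run_study",
]

PDFF_MEASURES = ("mrs_pdff", "mri_pdff_voi", "mri_pdff_wl")


def lv_column(th: float) -> str:
    return f"lv_pct_{th:g}"


@dataclass
class PipelineConfig:
    """Serializable configuration of the whole synthetic study."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    acq: AcquisitionConstants = field(default_factory=AcquisitionConstants)
    thresholds: tuple[float, ...] = (5.56, 7.97, 8.8)
    #: count voxels exactly at the threshold as steatotic (>= instead of >)
    inclusive_threshold: bool = False
    #: derive water/fat from the in/opposed-phase composites instead of
    #: using the rendered water/fat channels directly
    from_inphase_opposed: bool = False

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if any(not 0 < t < 100 for t in self.thresholds):
            raise ValueError("each threshold must lie in (0, 100)")

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "acq": asdict(self.acq),
            "thresholds": list(self.thresholds),
            "inclusive_threshold": self.inclusive_threshold,
            "from_inphase_opposed": self.from_inphase_opposed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            generator=GeneratorConfig.from_dict(d.get("generator", {})),
            acq=AcquisitionConstants(**d.get("acq", {})),
            thresholds=tuple(d.get("thresholds", (5.56, 7.97, 8.8))),
            inclusive_threshold=bool(d.get("inclusive_threshold", False)),
            from_inphase_opposed=bool(d.get("from_inphase_opposed", False)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def measure_subject_timepoint(
    dixon,
    mask: VolumeGrid,
    voi: VOISpec,
    mrs: MRSMeasurement,
    thresholds: tuple[float, ...],
    inclusive: bool = False,
    from_inphase_opposed: bool = False,
) -> dict[str, float]:
    """All per-timepoint measures from images + raw MRS amplitudes."""
    if from_inphase_opposed:
        water, fat, _ = separate_two_point(dixon.in_phase, dixon.opposed_phase)
    else:
        water, fat = dixon.water, dixon.fat
    pdff, _ = fat_fraction_map(water, fat, mask)
    voi_mask = place_voi(pdff, voi)
    row: dict[str, float] = {
        "mrs_pdff": mrs_pdff(mrs),
        "mri_pdff_voi": mean_pdff(pdff, voi_mask),
        "mri_pdff_wl": mean_pdff(pdff),
    }
    for th in thresholds:
        row[lv_column(th)] = lv_percent_above(pdff, th, inclusive)
    return row


def measure_subject(subject: PhantomSubject, config: PipelineConfig) -> list[dict[str, Any]]:
    rows = []
    for tp, data in subject.timepoints.items():
        row = {
            "subject_id": subject.subject_id,
            "arm": subject.arm,
            "timepoint": tp,
        }
        row.update(
            measure_subject_timepoint(
                data.dixon,
                subject.mask,
                subject.voi,
                data.mrs,
                config.thresholds,
                config.inclusive_threshold,
                config.from_inphase_opposed,
            )
        )
        row["true_mean_pdff"] = data.true_mean
        for th, lv in data.true_lv.items():
            row[f"true_{lv_column(th)}"] = lv
        rows.append(row)
    return rows


def build_result_table(subjects: list[PhantomSubject], config: PipelineConfig) -> pd.DataFrame:
    rows: list[dict[str, Any]] = []
    for s in subjects:
        rows.extend(measure_subject(s, config))
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Arm × timepoint mean ± sample SD for every measure column."""
    if table.empty:
        raise ValueError("empty result table")
    measures = [
        c for c in table.columns if c not in ("subject_id", "arm", "timepoint")
    ]
    return (
        table.groupby(["arm", "timepoint"])[measures]
        .agg(["mean", lambda v: v.std(ddof=1)])
        .rename(columns={"<lambda_0>": "sd"}, level=1)
    )


def _result_to_dict(res) -> dict:
    d = asdict(res)
    d.pop("extra", None)
    if hasattr(res, "extra"):
        d.update(res.extra)
    return d


def analyze_cohort(table: pd.DataFrame, config: PipelineConfig) -> dict[str, Any]:
    """The full statistical report on a cohort result table.

    Sections: method agreement (Spearman + Bland–Altman, pooled over
    timepoints), ROC/Youden threshold derivation against MRS labels,
    within-arm paired tests, between-arm rank-sum comparisons of changes and
    percent changes, and the mixed two-way ANOVA per PDFF measure.
    """
    report: dict[str, Any] = {"alpha": 0.05}

    # --- agreement, pooled over timepoint and arm
    mrs = table["mrs_pdff"].to_numpy()
    agreement = {}
    for meas in ("mri_pdff_voi", "mri_pdff_wl"):
        mri = table[meas].to_numpy()
        agreement[meas] = {
            "spearman": _result_to_dict(spearman_rho(mri, mrs, name=f"spearman_{meas}")),
            "bland_altman": asdict(bland_altman(mri, mrs)),
        }
    agreement["voi_vs_wl"] = {
        "spearman": _result_to_dict(
            spearman_rho(table["mri_pdff_voi"], table["mri_pdff_wl"], name="spearman_voi_wl")
        ),
        "bland_altman": asdict(
            bland_altman(table["mri_pdff_voi"].to_numpy(), table["mri_pdff_wl"].to_numpy())
        ),
    }
    report["agreement"] = agreement

    # --- ROC threshold derivation with MRS-based labels
    labels = np.array([steatosis_label(v) for v in mrs])
    roc = {}
    if labels.any() and not labels.all():
        for meas in ("mri_pdff_voi", "mri_pdff_wl"):
            r = roc_youden(table[meas].to_numpy(), labels)
            roc[meas] = {
                "auc": r.auc,
                "youden_threshold": r.youden_threshold,
                "youden_j": r.youden_j,
            }
    report["roc"] = roc

    # --- per-measure change analyses
    lv_cols = [c for c in table.columns if c.startswith("lv_pct_")]
    arms = sorted(table["arm"].unique())
    changes: dict[str, Any] = {}
    for meas in list(PDFF_MEASURES) + lv_cols:
        ch = paired_changes(table, meas)
        entry: dict[str, Any] = {"per_arm": {}}
        for arm in arms:
            sub = ch[ch["arm"] == arm]
            entry["per_arm"][arm] = {
                "n": int(len(sub)),
                "baseline_mean": float(sub["baseline"].mean()),
                "baseline_sd": float(sub["baseline"].std(ddof=1)),
                "week8_mean": float(sub["week8"].mean()),
                "week8_sd": float(sub["week8"].std(ddof=1)),
                "change_mean": float(sub["change"].mean()),
                "change_sd": float(sub["change"].std(ddof=1)),
                "percent_change_mean": float(sub["percent_change"].mean()),
                "percent_change_sd": float(sub["percent_change"].std(ddof=1)),
            }
            diffs = sub["change"].to_numpy()
            if np.any(diffs != 0):
                entry["per_arm"][arm]["wilcoxon_signed_rank"] = _result_to_dict(
                    wilcoxon_signed_rank(diffs, name=f"signed_rank_{meas}_{arm}")
                )
        if len(arms) == 2:
            a, b = arms
            ch_a = ch[ch["arm"] == a]
            ch_b = ch[ch["arm"] == b]
            entry["rank_sum_change"] = _result_to_dict(
                wilcoxon_rank_sum(
                    ch_a["change"], ch_b["change"], name=f"rank_sum_change_{meas}"
                )
            )
            pa = ch_a["percent_change"].dropna()
            pb = ch_b["percent_change"].dropna()
            if len(pa) >= 2 and len(pb) >= 2:
                entry["rank_sum_percent_change"] = _result_to_dict(
                    wilcoxon_rank_sum(pa, pb, name=f"rank_sum_pct_change_{meas}")
                )
        changes[meas] = entry
    report["changes"] = changes

    # --- mixed two-way ANOVA on the PDFF measures
    anova: dict[str, Any] = {}
    if len(arms) == 2:
        for meas in PDFF_MEASURES:
            sub = table[["subject_id", "arm", "timepoint", meas]].rename(
                columns={meas: "value"}
            )
            try:
                res = rm_anova_two_way(sub)
            except ValueError:
                continue
            anova[meas] = {k: _result_to_dict(v) for k, v in res.items()}
    report["anova"] = anova
    return report


@dataclass
class StudyResult:
    table: pd.DataFrame
    report: dict[str, Any]
    provenance: dict[str, Any]
    subjects: list[PhantomSubject]


def run_study(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    write_images: bool = False,
) -> StudyResult:
    """Simulate a cohort, run every analysis stage, optionally write outputs.

    ``seed`` overrides ``config.generator.seed``. With ``out_dir`` set, the
    result table (2-decimal CSV plus full-precision JSON sidecar), the stats
    report, a Markdown summary and a provenance record are written; with
    ``write_images`` also the per-subject NIfTI volumes and manifest.
    """
    config = config or PipelineConfig()
    if seed is not None:
        gd = config.generator.to_dict()
        gd["seed"] = int(seed)
        config = PipelineConfig.from_dict({**config.to_dict(), "generator": gd})
    subjects = generate_cohort(config.generator, acq=config.acq)
    table = build_result_table(subjects, config)
    report = analyze_cohort(table, config)
    provenance = {
        "package": "dixonvol",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.generator.seed,
        "n_subjects": len(subjects),
        "config": config.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.round(2).to_csv(out / "cohort_results.csv", index=False)
        table.to_json(out / "cohort_results_full.json", orient="records", indent=2)
        (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (out / "report.md").write_text(render_markdown_report(report, provenance))
        if write_images:
            write_cohort(subjects, out / "images", config.generator)
    return StudyResult(table=table, report=report, provenance=provenance, subjects=subjects)


def render_markdown_report(report: dict[str, Any], provenance: dict[str, Any]) -> str:
    """Human-readable Markdown rendering of the stats report."""
    lines = [
        "# Synthetic liver-fat study report",
        "",
        f"Package dixonvol {provenance.get('version', '?')}, "
        f"seed {provenance.get('seed')}, config {provenance.get('config_hash')}, "
        f"{provenance.get('n_subjects')} subjects.",
        "",
        "## Method agreement (pooled over arms and timepoints)",
        "",
    ]
    for meas, d in report.get("agreement", {}).items():
        sp = d["spearman"]
        ba = d["bland_altman"]
        lines.append(
            f"- **{meas}**: Spearman rho = {sp['statistic']:.2f} (p = {sp['p_value']:.2g}); "
            f"Bland–Altman MD = {ba['mean_difference']:.2f} "
            f"[{ba['loa_lower']:.2f}, {ba['loa_upper']:.2f}] %-points"
        )
    if report.get("roc"):
        lines += ["", "## ROC thresholds (MRS label: PDFF > 5.56%)", ""]
        for meas, d in report["roc"].items():
            lines.append(
                f"- **{meas}**: AUC = {d['auc']:.2f}, "
                f"Youden-optimal cutoff = {d['youden_threshold']:.2f}% (J = {d['youden_j']:.2f})"
            )
    lines += ["", "## Changes after 8 weeks", ""]
    for meas, d in report.get("changes", {}).items():
        lines.append(f"### {meas}")
        for arm, a in d["per_arm"].items():
            wsr = a.get("wilcoxon_signed_rank")
            ptxt = f", signed-rank p = {wsr['p_value']:.3g}" if wsr else ""
            lines.append(
                f"- {arm} (n={a['n']}): {a['baseline_mean']:.2f} ± {a['baseline_sd']:.2f} → "
                f"{a['week8_mean']:.2f} ± {a['week8_sd']:.2f}, "
                f"change {a['change_mean']:.2f} ± {a['change_sd']:.2f}{ptxt}"
            )
        if "rank_sum_change" in d:
            rs = d["rank_sum_change"]
            lines.append(f"- between-arm rank-sum on changes: p = {rs['p_value']:.3g}")
        if "rank_sum_percent_change" in d:
            rs = d["rank_sum_percent_change"]
            lines.append(f"- between-arm rank-sum on percent changes: p = {rs['p_value']:.3g}")
        lines.append("")
    if report.get("anova"):
        lines += ["## Two-way repeated-measures ANOVA", ""]
        for meas, d in report["anova"].items():
            parts = ", ".join(
                f"{k}: F = {v['statistic']:.2f}, p = {v['p_value']:.3g}" for k, v in d.items()
            )
            lines.append(f"- **{meas}**: {parts}")
    return "\n".join(lines) + "\n"
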