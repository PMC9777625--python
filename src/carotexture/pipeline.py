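"""End-to-end run orchestration: simulate -> preprocess -> extract ->
screen -> classify -> report, with a manifest for byte-identical reruns."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import TASKS, LooResult, ModelConfig, TaskSpec, accuracy_table, loo_evaluate
from .features import TextureParams, feature_table
from .io import load_roi_json, rasterize_roi, read_image
from .stats import COMPARISONS, count_significant, feature_significance, results_frame, significance_report
from .synthetic import CohortDataset, GroupTextureParams, SyntheticConfig, generate_cohort

log = logging.getLogger("carotexture")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort_dir: str | None = None  # use an existing cohort instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    texture: TextureParams = field(default_factory=TextureParams)
    alpha: float = 0.05
    per_patient_stats: bool = False
    subsets: tuple[str, ...] = ("clinical", "clinical_imt", "texture", "aldo")
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    write_cohort: bool = False
    plots: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["texture_params"] = {
            g: asdict(tp) for g, tp in self.synthetic.texture_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            s = dict(d["synthetic"])
            if "texture_params" in s:
                s["texture_params"] = {
                    g: GroupTextureParams(**{**tp, "wall_thickness_px": tuple(tp["wall_thickness_px"])})
                    for g, tp in s["texture_params"].items()}
            for key in ("image_size",):
                if key in s:
                    s[key] = tuple(s[key])
            d["synthetic"] = SyntheticConfig(**s)
        if "texture" in d:
            t = dict(d["texture"])
            for key in ("distances", "thetas"):
                if key in t:
                    t[key] = tuple(t[key])
            d["texture"] = TextureParams(**t)
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        if "subsets" in d:
            d["subsets"] = tuple(d["subsets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage and write all artifacts under ``outdir``.

    Re-running with the written manifest reproduces byte-identical CSV
    outputs.  Any stage failure aborts with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])
            return out
        return deco

    if config.cohort_dir:
        cohort = stage("load_cohort")(lambda: CohortDataset.load(config.cohort_dir))
    else:
        cohort = stage("simulate")(lambda: generate_cohort(config.synthetic))
        if config.write_cohort:
            stage("write_cohort")(lambda: cohort.save(outdir / "cohort"))

    table = stage("extract")(lambda: feature_table(cohort, config.texture))
    table.to_csv(outdir / "features.csv", index=False)
    clinical = cohort.clinical_frame()
    clinical.to_csv(outdir / "clinical.csv", index=False)

    def _stats():
        frames, reports, counts = [], [], {}
        clin_cols = [c for c in clinical.columns if c not in ("patient_id", "group_label")]
        for comp in COMPARISONS:
            tex = feature_significance(table, comp, config.alpha,
                                       per_patient=config.per_patient_stats)
            clin_cols_comp = ([c for c in clin_cols if c not in ("aldosterone", "renin", "arr")]
                              if comp == "HTN_vs_C" else clin_cols)
            clin = feature_significance(clinical, comp, config.alpha,
                                        feature_cols=clin_cols_comp)
            frames.append(results_frame(tex + clin))
            reports.append(significance_report(tex, clin, config.alpha))
            counts[comp] = count_significant(tex, config.alpha)
        pd.concat(frames).to_csv(outdir / "stats.csv", index=False)
        for comp, rep in zip(COMPARISONS, reports):
            rep.to_csv(outdir / f"stats_report_{comp}.csv", index=False)
        return counts

    sig_counts = stage("stats")(_stats)

    def _classify():
        results: dict[tuple[str, str], LooResult] = {}
        for task in TASKS:
            for subset in config.subsets:
                if subset == "aldo" and task == "HTN_vs_C":
                    continue
                spec = TaskSpec(task=task, feature_subset=subset)
                res = loo_evaluate(table, clinical, spec, config.model, seed=config.seed)
                results[(task, subset)] = res
                res.per_patient.to_csv(outdir / f"loo_{task}_{subset}.csv", index=False)
                pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
                    outdir / f"roc_{task}_{subset}.csv", index=False)
        return results

    results = stage("classify")(_classify)
    acc = accuracy_table(results)
    acc.to_csv(outdir / "accuracy.csv", index=False)

    if config.plots:
        stage("plots")(lambda: _plot_rocs(results, outdir))

    stage("report")(lambda: _write_report(outdir, config, sig_counts, acc, results))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "timings_s": timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def rerun_from_manifest(manifest_path: str | Path, outdir: str | Path) -> Path:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(RunConfig.from_dict(manifest["config"]), outdir)


def _plot_rocs(results: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for task in TASKS:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for (t, subset), res in results.items():
            if t != task:
                continue
            ax.plot(res.fpr, res.tpr, label=f"{subset} (AUC={res.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(task.replace("_", " "))
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"roc_{task}.png", dpi=120)
        plt.close(fig)


def _write_report(outdir: Path, config: RunConfig, sig_counts: dict,
                  acc: pd.DataFrame, results: dict) -> None:
    lines = ["# Pipeline run report", ""]
    lines.append(f"Seed {config.seed}; alpha {config.alpha}; "
                 f"model hash {config.model.hash()}.")
    lines.append("")
    lines.append("## Feature screening")
    for comp, n in sig_counts.items():
        lines.append(f"- {comp}: {n} of 152 texture features significant "
                     f"by all three tests at alpha={config.alpha}")
    lines.append("")
    lines.append("## Per-patient leave-one-out accuracy")
    lines.append("")
    lines.append(acc.to_markdown(index=False))
    lines.append("")
    lines.append("## AUC")
    for (task, subset), res in sorted(results.items()):
        lines.append(f"- {task} / {subset}: AUC = {res.auc:.3f}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


def validate_inputs(cohort_dir: str | Path) -> list[str]:
    """Check a cohort directory for structural problems; report-only.

    Verifies every image has an ROI, every ROI rasterizes to a non-empty
    mask, and the clinical table covers all patients.
    """
    cohort_dir = Path(cohort_dir)
    violations: list[str] = []
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        return [f"missing manifest.json in {cohort_dir}"]
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    clinical = pd.read_csv(cohort_dir / "clinical.csv")
    known_patients = set(clinical["patient_id"])
    for entry in manifest.get("images", []):
        name, pid = entry["image"], entry["patient_id"]
        stem = Path(name).stem
        img_path = cohort_dir / "images" / name
        roi_path = cohort_dir / "rois" / f"{stem}.json"
        if not img_path.exists():
            violations.append(f"missing image file: {name}")
            continue
        if not roi_path.exists():
            violations.append(f"missing ROI for image: {name}")
            continue
        img = read_image(img_path)
        poly = load_roi_json(roi_path)
        if len(poly) < 3:
            violations.append(f"degenerate ROI polygon (<3 vertices): {name}")
            continue
        try:
            rasterize_roi(poly, img.shape)
        except ValueError as exc:
            violations.append(f"ROI does not rasterize for {name}: {exc}")
        if pid not in known_patients:
            violations.append(f"patient {pid} of image {name} missing from clinical.csv")
    return violations
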