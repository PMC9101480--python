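"""End-to-end orchestration: (simulate | ingest) -> clean -> features ->
ANOVA + classification -> reports and figures.

Every stage output is a pure function of (inputs, config, seed); re-running
with an identical config reproduces identical numeric outputs.  The fully
resolved configuration is echoed into the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anova as anova_mod
from . import classify as classify_mod
from . import simulate as simulate_mod
from .features import FEATURE_SETS, ViewingGeometry, extract_table
from .preprocess import CleaningConfig, clean_cohort, cleaning_summary
from .records import ConfigError
from .report_io import (
    assemble_trials,
    read_fixation_report,
    read_saccade_report,
    read_trial_meta,
    write_feature_table,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "stroopgaze_out"
    seed: int = 0
    n_subjects: int = 64
    input_dir: str | None = None  # None -> simulate; else read reports from here
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    contrasts: tuple[str, ...] = anova_mod.CLASSIFICATION_CONTRASTS
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
    classifiers: tuple[str, ...] = classify_mod.CLASSIFIER_NAMES
    folds: int = 5
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
        raw = dict(raw)
        if isinstance(raw.get("cleaning"), dict):
            raw["cleaning"] = CleaningConfig(**raw["cleaning"])
        if isinstance(raw.get("geometry"), dict):
            raw["geometry"] = ViewingGeometry(**raw["geometry"])
        for key in ("contrasts", "feature_sets", "classifiers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("contrasts", "feature_sets", "classifiers"):
            d[key] = list(d[key])
        return d


def load_trials(config: PipelineConfig):
    if config.input_dir is None:
        sim = simulate_mod.calibrate_defaults()
        sim = dataclasses.replace(sim, n_subjects=config.n_subjects)
        log.info("simulating %d subjects (seed %d)", config.n_subjects, config.seed)
        fixations, saccades, meta = simulate_mod.simulate_cohort(sim, config.seed,
                                                                 config.geometry)
    else:
        d = Path(config.input_dir)
        log.info("reading reports from %s", d)
        fixations = read_fixation_report(d / "fixation_report.tsv")
        saccades = read_saccade_report(d / "saccade_report.tsv")
        meta = read_trial_meta(d / "meta.tsv")
    return assemble_trials(fixations, saccades, meta)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts to the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("stroopgaze")
    root.addHandler(fh)
    old_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        with open(out / "config_resolved.yaml", "w") as f:
            yaml.safe_dump(config.to_dict(), f, sort_keys=True)

        trials = load_trials(config)
        grid = trials[0].canvas if trials else None
        aoi = simulate_mod.AoiGrid(margin=config.cleaning.aoi_margin_px)
        cleaned = clean_cohort(trials, aoi, config.cleaning)
        summary = pd.DataFrame([cleaning_summary(b, a) for b, a in zip(trials, cleaned)])
        summary.to_csv(out / "cleaning_summary.csv", index=False)
        for row in summary.itertuples(index=False):
            log.info("cleaned %s/%s: fixations %d -> %d, saccades %d -> %d",
                     row.subject, row.condition, row.fixations_in, row.fixations_out,
                     row.saccades_in, row.saccades_out)

        table = extract_table(cleaned, aoi, config.geometry)
        write_feature_table(table, out / "features.csv")

        results = anova_mod.run_all_contrasts(table)
        report = anova_mod.anova_report(results)
        report.to_csv(out / "anova_pvalues.csv")
        (out / "anova_report.txt").write_text(anova_mod.format_report(report) + "\n")

        cv = classify_mod.run_grid(table, seed=config.seed,
                                   contrasts=config.contrasts,
                                   feature_sets=config.feature_sets,
                                   classifiers=config.classifiers,
                                   folds=config.folds)
        classify_mod.results_frame(cv).to_csv(out / "classification_folds.csv", index=False)
        summary_cv = classify_mod.summary_frame(cv)
        summary_cv.to_csv(out / "classification_summary.csv", index=False)

        if config.make_figures:
            plot_grid(summary_cv, out)
        return out
    finally:
        root.setLevel(old_level)
        root.removeHandler(fh)
        fh.close()


def plot_grid(summary: pd.DataFrame, out_dir: Path) -> None:
    """Grouped bar charts of mean Accuracy and F1 per contrast, with the
    0.5 chance baseline; the plotted values are also emitted as CSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric in ("accuracy", "f1"):
        contrasts = list(dict.fromkeys(summary["contrast"]))
        fig, axes = plt.subplots(1, len(contrasts), figsize=(5 * len(contrasts), 4),
                                 squeeze=False)
        plotted = []
        for ax, contrast in zip(axes[0], contrasts):
            sub = summary[summary["contrast"] == contrast]
            classifiers = list(dict.fromkeys(sub["classifier"]))
            feature_sets = list(dict.fromkeys(sub["feature_set"]))
            width = 0.8 / len(feature_sets)
            for j, fs in enumerate(feature_sets):
                vals = [sub[(sub["classifier"] == c) & (sub["feature_set"] == fs)]
                        [f"mean_{metric}"].iloc[0] for c in classifiers]
                errs = [sub[(sub["classifier"] == c) & (sub["feature_set"] == fs)]
                        [f"sd_{metric}"].iloc[0] for c in classifiers]
                xs = [i + j * width for i in range(len(classifiers))]
                ax.bar(xs, vals, width=width, yerr=errs, capsize=2, label=fs)
                plotted.extend(
                    {"contrast": contrast, "classifier": c, "feature_set": fs,
                     "metric": metric, "mean": v, "sd": e}
                    for c, v, e in zip(classifiers, vals, errs))
            ax.axhline(0.5, color="red", linestyle="--", linewidth=1)
            ax.set_xticks([i + 0.4 - width / 2 for i in range(len(classifiers))])
            ax.set_xticklabels(classifiers)
            ax.set_ylim(0, 1.05)
            ax.set_title(contrast)
            ax.set_ylabel(metric)
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"classification_{metric}.png", dpi=120)
        plt.close(fig)
        pd.DataFrame(plotted).to_csv(out_dir / f"classification_{metric}_plotted.csv",
                                     index=False)
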