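"""End-to-end orchestration: angles -> dimorphism -> selection -> classification.

The stage order mirrors the analysis protocol: compute (or load, or
simulate) the 36-angle table; test every angle for sexual dimorphism; keep
the significant angles as the initial feature set; run the repeated CFS
selection scheme on that restricted table to get attribute importances;
evaluate every classifier on every AI-thresholded subset (plus the full
significant set) under one shared repeated stratified 5-fold plan; and
collect everything into a serializable report.

Re-running with the same config and seed reproduces the report
bit-for-bit; the config is embedded in the report as provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (EvalSettings, EvaluationResult, evaluate, majority_baseline,
                       make_fold_plan)
from .dimorphism import DimorphismReport, DimorphismSettings, dimorphism_report
from .geometry import AngleTable, compute_angle_table
from .landmarks import read_landmarks_csv
from .selection import DEFAULT_THRESHOLDS, AttributeImportance, repeated_selection
from .synthetic import SyntheticConfig, generate_angle_table, generate_landmark_sets


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    # input: exactly one of the three
    landmarks_csv: str | None = None
    angles_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    synthetic_level: str = "angles"          # "angles" | "landmarks"

    alpha: float = 0.05
    dimorphism: DimorphismSettings = field(default_factory=DimorphismSettings)
    folds: int = 5
    repeats: int = 10
    cv_seed: int = 0
    selection_seed: int = 0
    thresholds: tuple[str, ...] = DEFAULT_THRESHOLDS
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    output_dir: str | None = None

    def validate(self) -> None:
        sources = [self.landmarks_csv, self.angles_csv, self.synthetic]
        if sum(s is not None for s in sources) != 1:
            raise PipelineError("config: exactly one input source must be set")
        if self.synthetic_level not in ("angles", "landmarks"):
            raise PipelineError("config: synthetic_level must be 'angles' or 'landmarks'")
        if not 0 < self.alpha < 1:
            raise PipelineError("config: alpha must be in (0, 1)")


@dataclass
class RunReport:
    config: RunConfig
    n_specimens: int
    majority_accuracy: float
    dimorphism: DimorphismReport
    significant_angles: list[str]
    importance: AttributeImportance | None
    evaluations: dict[str, EvaluationResult]
    cn2_rules: str
    provenance: dict

    def to_dict(self) -> dict:
        evals = {}
        for label, res in self.evaluations.items():
            evals[label] = {
                "overall": res.overall,
                "per_class": res.per_class,
                "svm_params": res.svm_params,
                "n_folds": int(len(res.fold_frame)) if len(res.fold_frame) else 0,
            }
        return {
            "provenance": self.provenance,
            "n_specimens": self.n_specimens,
            "majority_accuracy": self.majority_accuracy,
            "alpha": self.dimorphism.alpha,
            "significant_angles": self.significant_angles,
            "dimorphism": [
                {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                 for k, v in dataclasses.asdict(row).items()}
                for row in self.dimorphism.rows
            ],
            "attribute_importance": (
                None if self.importance is None else {
                    "frequencies": self.importance.frequencies.to_dict(),
                    "total_runs": self.importance.total_runs,
                    "subsets": self.importance.subsets,
                }),
            "evaluations": evals,
            "cn2_rules": self.cn2_rules,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _config_provenance(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return {"package_version": __version__, "config": clean(config)}


def load_angle_table(config: RunConfig) -> AngleTable:
    if config.angles_csv is not None:
        path = Path(config.angles_csv)
        if not path.exists():
            raise PipelineError(f"input: angle table not found: {path}")
        return AngleTable.from_csv(path)
    if config.landmarks_csv is not None:
        path = Path(config.landmarks_csv)
        if not path.exists():
            raise PipelineError(f"input: landmark file not found: {path}")
        return compute_angle_table(read_landmarks_csv(path))
    assert config.synthetic is not None
    if config.synthetic_level == "landmarks":
        return compute_angle_table(generate_landmark_sets(config.synthetic))
    return generate_angle_table(config=config.synthetic)


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    try:
        table = load_angle_table(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
        raise PipelineError(f"angles: {exc}") from exc

    labeled = table.sex.isin(["male", "female"]).to_numpy()
    frame = table.frame.loc[labeled]
    sex = table.sex[labeled]
    if frame.empty:
        raise PipelineError("input: no specimens with sex labels")

    try:
        report = dimorphism_report(AngleTable(frame, sex), config.dimorphism)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"dimorphism: {exc}") from exc
    significant = report.significant_codes()

    majority = majority_baseline(sex)
    importance: AttributeImportance | None = None
    evaluations: dict[str, EvaluationResult] = {}
    cn2_rules = ""

    if significant:
        restricted = frame[significant]
        try:
            importance = repeated_selection(
                restricted, sex, folds=config.folds, repeats=config.repeats,
                seed=config.selection_seed, thresholds=config.thresholds)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"selection: {exc}") from exc

        plan = make_fold_plan(sex, config.folds, config.repeats, config.cv_seed)
        subsets: dict[str, list[str]] = {"all_significant": significant}
        for label, attrs in importance.subsets.items():
            if attrs:
                subsets[label] = attrs
        try:
            for label, attrs in subsets.items():
                evaluations[label] = evaluate(frame[attrs], sex, plan, config.evaluation)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"classification: {exc}") from exc

        # render rules induced on the full labeled data, on the subset where
        # CN2 scored best (mirrors reporting the final interpretable model)
        if "cn2" in config.evaluation.classifiers:
            from .rules import cn2_induce
            best_label = max(evaluations, key=lambda k: evaluations[k].overall["cn2"])
            rl = cn2_induce(frame[subsets[best_label]].copy(), sex,
                            beam_width=config.evaluation.cn2_beam_width,
                            min_coverage=config.evaluation.cn2_min_coverage,
                            variant=config.evaluation.cn2_variant)
            cn2_rules = f"# subset: {best_label}\n" + rl.render()

    out = RunReport(
        config=config,
        n_specimens=int(len(frame)),
        majority_accuracy=majority,
        dimorphism=report,
        significant_angles=significant,
        importance=importance,
        evaluations=evaluations,
        cn2_rules=cn2_rules,
        provenance=_config_provenance(config),
    )
    if config.output_dir:
        write_report(out, Path(config.output_dir))
    return out


def write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
    report.dimorphism.to_frame().to_csv(out_dir / "dimorphism.csv")
    if report.importance is not None:
        report.importance.to_frame().to_csv(out_dir / "attribute_importance.csv")
    if report.evaluations:
        rows = []
        for label, res in report.evaluations.items():
            for name, acc in res.overall.items():
                row = {"subset": label, "classifier": name, "overall": acc}
                row.update({f"acc_{cls}": v for cls, v in res.per_class[name].items()})
                rows.append(row)
        import pandas as pd
        pd.DataFrame(rows).to_csv(out_dir / "accuracy.csv", index=False)
    if report.cn2_rules:
        (out_dir / "cn2_rules.txt").write_text(report.cn2_rules + "\n", encoding="utf-8")
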