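"""End-to-end orchestration: simulate → extract → detect → classify → compare.

``run_full`` realizes the whole two-step protocol over a cohort of synthetic
subjects: per subject it extracts feature tables for every configured window,
runs the balanced binary detection step for every algorithm × window,
computes learning curves at the 10 ms window, runs the three-class step at
10 ms, and finally compares windows (Nemenyi) and algorithms
(Bergmann–Hommel by default) across subjects with Friedman tests.  Every
artifact is stamped with the config hash and the derived seeds; a fixed
master seed makes the metric outputs byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import ADASYNConfig, crossval_classify
from .detection import (ALGORITHM_FAMILIES, balance_binary, crossval_detect,
                        learning_curve, split_tuning_holdout, tune)
from .errors import ConfigurationError
from .features import WINDOW_CHOICES_MS, WindowSpec, extract_features
from .io import EVENT_LABELS, write_annotations, write_feature_table, write_recording
from .stats import compare_conditions
from .synth import GeneratorConfig, generate_recording, subject_configs

log = logging.getLogger("hfopipe")

#: step-2 needs, per class: the 30% tuning split (>=3 for its internal 3-fold
#: CV) and 2 per development fold.
_MIN_CLASS_ROWS = 10


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = GeneratorConfig()
    n_subjects: int = 3
    windows: tuple[int, ...] = (10, 50, 100)
    algorithms: tuple[str, ...] = ALGORITHM_FAMILIES
    seed: int = 0
    learning_curve_sizes: tuple[int, ...] = (720, 1440, 2520, 3240)
    adasyn_k: int = 5
    adasyn_beta: float = 1.0
    save_features: bool = True
    save_recordings: bool = False
    posthoc_windows: str = "nemenyi"
    posthoc_algorithms: str = "bergmann_hommel"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.windows:
            raise ConfigurationError("windows must be a non-empty subset of "
                                     f"{WINDOW_CHOICES_MS}")
        for w in self.windows:
            if w not in WINDOW_CHOICES_MS:
                raise ConfigurationError(
                    f"window {w} ms not allowed; choose from {WINDOW_CHOICES_MS}")
        for a in self.algorithms:
            if a not in ALGORITHM_FAMILIES:
                raise ConfigurationError(
                    f"algorithm {a!r} not allowed; choose from {ALGORITHM_FAMILIES}")
        if not self.algorithms:
            raise ConfigurationError("algorithms must be non-empty")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_GEN_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig; unknown keys are errors."""
    data = dict(data or {})
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}")
    gen_data = dict(data.pop("generator", {}) or {})
    unknown = set(gen_data) - _GEN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown generator keys {sorted(unknown)}; allowed: {sorted(_GEN_KEYS)}")
    for key in ("class_mix", "ripple_duration_ms", "ripple_duration_bounds_ms",
                "fr_duration_ms", "fr_duration_bounds_ms", "ripple_freq_range",
                "fr_freq_range"):
        if key in gen_data:
            gen_data[key] = tuple(gen_data[key])
    for key in ("windows", "algorithms", "learning_curve_sizes"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(generator=GeneratorConfig(**gen_data), **data)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + strictly validate a YAML pipeline config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        return config_from_dict(data)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def _stage_seed(master: int, *parts: int) -> int:
    return int(np.random.SeedSequence([master, *parts]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class RunReport:
    out_dir: Path
    step1_metrics: pd.DataFrame
    step2_metrics: pd.DataFrame | None
    learning_curves: pd.DataFrame | None
    comparisons: dict
    manifest: dict = field(default_factory=dict)


def run_full(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Run the whole pipeline; see module docstring.  Raises on any stage
    error after persisting partial outputs; infeasible optional stages
    (single window, scarce step-2 classes, oversized learning-curve sizes)
    are skipped with a logged notice instead."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    chosen_params: dict[str, dict] = {}
    master = config.seed
    algo_index = {a: i for i, a in enumerate(ALGORITHM_FAMILIES)}

    step1_rows, step2_rows, lc_rows = [], [], []
    subjects = []
    try:
        for si, gen_cfg in enumerate(subject_configs(config.generator,
                                                     config.n_subjects, master)):
            subject = f"s{si + 1:02d}"
            subjects.append(subject)
            log.info("subject %s: generating (seed %d)", subject, gen_cfg.seed)
            recording, annotations = generate_recording(gen_cfg, subject_id=subject)
            if config.save_recordings:
                write_recording(recording, out / f"{subject}_recording.npy")
            write_annotations(annotations, out / f"{subject}_annotations.csv")

            tables = {}
            for w in config.windows:
                table = extract_features(recording, annotations, WindowSpec(w))
                tables[w] = table
                if config.save_features:
                    write_feature_table(table, out / f"{subject}_features_{w}ms.csv")

            for w in config.windows:
                for algo in config.algorithms:
                    seed = _stage_seed(master, si, w, algo_index[algo])
                    balanced = balance_binary(tables[w], seed=seed)
                    tuning, dev = split_tuning_holdout(balanced, seed=seed)
                    params, tune_auc = tune(algo, tuning, seed=seed)
                    chosen_params[f"{subject}/{algo}/{w}ms"] = params
                    metrics = crossval_detect(dev, algo, params, folds=5, seed=seed)
                    for fold in range(len(metrics.auc)):
                        step1_rows.append({
                            "subject": subject, "algorithm": algo,
                            "window_ms": w, "fold": fold,
                            "auc": metrics.auc[fold],
                            "sensitivity": metrics.sensitivity[fold],
                            "specificity": metrics.specificity[fold]})
                    if w == min(config.windows):
                        sizes = tuple(s for s in config.learning_curve_sizes
                                      if s <= len(dev))
                        skipped = set(config.learning_curve_sizes) - set(sizes)
                        if skipped:
                            notices.append(
                                f"{subject}/{algo}: learning-curve sizes "
                                f"{sorted(skipped)} exceed the {len(dev)}-row "
                                "development set; skipped")
                        if sizes:
                            lc = learning_curve(dev, algo, params, sizes=sizes,
                                                folds=10, seed=seed)
                            lc.insert(0, "algorithm", algo)
                            lc.insert(0, "subject", subject)
                            lc_rows.append(lc)

            # step 2 at the 10 ms window
            if 10 not in config.windows:
                notices.append(f"{subject}: no 10 ms window configured; "
                               "three-class step skipped")
                continue
            hfo = tables[10][tables[10]["label"] != "noHFO"]
            counts = hfo["label"].value_counts()
            if (set(counts.index) != set(EVENT_LABELS)
                    or (counts < _MIN_CLASS_ROWS).any()):
                notices.append(
                    f"{subject}: step-2 class counts {counts.to_dict()} below "
                    f"the minimum {_MIN_CLASS_ROWS}/class; three-class step skipped")
                continue
            for algo in config.algorithms:
                seed = _stage_seed(master, si, 997, algo_index[algo])
                mm = crossval_classify(
                    hfo, algo, folds=3, seed=seed,
                    adasyn=ADASYNConfig(config.adasyn_k, config.adasyn_beta, seed))
                for fold in range(len(mm.sensitivity["R"])):
                    for cls in mm.classes:
                        step2_rows.append({
                            "subject": subject, "algorithm": algo,
                            "class": cls, "fold": fold,
                            "sensitivity": mm.sensitivity[cls][fold],
                            "specificity": mm.specificity[cls][fold]})
    finally:
        step1 = pd.DataFrame(step1_rows)
        if not step1.empty:
            step1.to_csv(out / "step1_metrics.csv", index=False,
                         float_format="%.12g")
        step2 = pd.DataFrame(step2_rows) if step2_rows else None
        if step2 is not None:
            step2.to_csv(out / "step2_metrics.csv", index=False,
                         float_format="%.12g")
        curves = pd.concat(lc_rows, ignore_index=True) if lc_rows else None
        if curves is not None:
            curves.to_csv(out / "learning_curves.csv", index=False,
                          float_format="%.12g")

    comparisons = _compare_stage(config, step1, step2, notices)
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=1))

    manifest = {
        "hfopipe_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "master_seed": master,
        "subject_seeds": [c.seed for c in
                          subject_configs(config.generator, config.n_subjects,
                                          master)],
        "chosen_hyperparameters": chosen_params,
        "notices": notices,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=list))
    _write_summary(out, config, step1, step2, comparisons, notices)
    return RunReport(out_dir=out, step1_metrics=step1, step2_metrics=step2,
                     learning_curves=curves, comparisons=comparisons,
                     manifest=manifest)


def _pivot(df: pd.DataFrame, metric: str, condition: str) -> pd.DataFrame:
    per_subject = (df.groupby(["subject", condition], sort=True)[metric]
                   .mean().reset_index())
    return per_subject.pivot(index="subject", columns=condition, values=metric)


def _compare_stage(config: PipelineConfig, step1: pd.DataFrame,
                   step2: pd.DataFrame | None, notices: list[str]) -> dict:
    comparisons: dict = {}
    n_subj = step1["subject"].nunique() if not step1.empty else 0
    if len(config.windows) >= 2 and n_subj >= 2:
        window_effect = {}
        for algo in config.algorithms:
            M = _pivot(step1[step1["algorithm"] == algo], "auc", "window_ms")
            res = compare_conditions(M, posthoc=config.posthoc_windows,
                                     alpha=config.alpha)
            window_effect[algo] = res.to_dict()
        comparisons["window_effect_auc"] = window_effect
    else:
        notices.append("window-effect Friedman test skipped "
                       f"(windows={list(config.windows)}, subjects={n_subj})")
    if len(config.algorithms) >= 2 and n_subj >= 2:
        w0 = min(config.windows)
        M = _pivot(step1[step1["window_ms"] == w0], "auc", "algorithm")
        comparisons[f"algorithm_effect_auc_{w0}ms"] = compare_conditions(
            M, posthoc=config.posthoc_algorithms, alpha=config.alpha).to_dict()
    if (step2 is not None and len(config.algorithms) >= 2
            and step2["subject"].nunique() >= 2):
        per_class = {}
        for cls in EVENT_LABELS:
            sub = step2[step2["class"] == cls]
            complete = (sub.groupby("subject")["algorithm"].nunique()
                        == len(config.algorithms))
            sub = sub[sub["subject"].isin(complete[complete].index)]
            if sub["subject"].nunique() < 2:
                continue
            M = _pivot(sub, "sensitivity", "algorithm")
            per_class[cls] = compare_conditions(
                M, posthoc=config.posthoc_algorithms, alpha=config.alpha).to_dict()
        if per_class:
            comparisons["step2_sensitivity_by_algorithm"] = per_class
    return comparisons


def _write_summary(out: Path, config: PipelineConfig, step1: pd.DataFrame,
                   step2: pd.DataFrame | None, comparisons: dict,
                   notices: list[str]) -> None:
    lines = [f"hfopipe full-run (config {config.content_hash()}, "
             f"master seed {config.seed})", ""]
    if not step1.empty:
        lines.append("Step 1 (binary HFO detection), mean over folds and subjects:")
        agg = (step1.groupby(["algorithm", "window_ms"])
               [["auc", "sensitivity", "specificity"]].mean())
        lines.append(agg.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
    if step2 is not None:
        lines.append("Step 2 (three-class, 10 ms), mean over folds and subjects:")
        agg2 = (step2.groupby(["algorithm", "class"])
                [["sensitivity", "specificity"]].mean())
        lines.append(agg2.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
    for key, block in comparisons.items():
        lines.append(f"[{key}]")
        if "friedman" in block:
            block = {"": block}
        for sub, res in block.items():
            fr = res["friedman"]
            lines.append(
                f"  {sub or 'overall'}: Friedman chi2={fr['chi2']:.3f}, "
                f"df={fr['df']}, p={fr['p_value']:.2e}; "
                f"not-significant pairs: {res['not_significant_edges']}")
        lines.append("")
    if notices:
        lines.append("Notices:")
        lines.extend(f"  - {n}" for n in notices)
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
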