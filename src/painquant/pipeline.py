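"""End-to-end pipeline: simulate -> preprocess/features -> fit -> evaluate.

A run writes everything under one run directory: the resolved config, a
text log, per-combination feature tables, a metrics table with one row per
pulse-sensor combination (combination, n_recordings, n_windows, r, RMSE,
ICC(3,1), permutation p), cross-validated predictions and a Bland-Altman
summary for each combination, optional per-subject individual-model
results, and a provenance file with SHA-256 hashes of inputs and outputs.
Reruns with the same config and seed reproduce identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core_io, evaluation, features, modeling, synthetic_data
from .modeling import ModelSpec

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending recording."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_root: str = "runs"
    run_name: str = ""                    # empty -> timestamped
    manifest: str = ""                    # existing cohort; empty -> simulate
    simulate: bool = True
    seed: int = 0
    combinations: list[tuple[str, ...]] = field(
        default_factory=modeling.enumerate_sensor_combinations
    )
    # synthesis (used when simulate=True)
    n_subjects: int = 12
    recordings_per_subject: int = 15
    duration_s: float = 600.0
    artifact_fraction: float = 0.10
    coupling: dict[str, float] | None = None
    # modeling
    n_trees: int = 500
    max_depth: int | None = None
    n_selected: int = 5
    # evaluation
    n_perm: int = 0
    individual_models: bool = True
    recording_means: bool = False
    include_temp_sd: bool = False
    plots: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        if "combinations" in data:
            data["combinations"] = [tuple(c) for c in data["combinations"]]
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["combinations"] = [list(c) for c in self.combinations]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _synth_config(cfg: PipelineConfig) -> synthetic_data.SynthConfig:
    kwargs = dict(
        n_subjects=cfg.n_subjects,
        recordings_per_subject=cfg.recordings_per_subject,
        duration_s=cfg.duration_s,
        artifact_fraction=cfg.artifact_fraction,
        seed=cfg.seed,
    )
    if cfg.coupling is not None:
        kwargs["coupling"] = dict(cfg.coupling)
    return synthetic_data.SynthConfig(**kwargs)


def _load_recordings(manifest: core_io.CohortManifest) -> list[core_io.RawRecording]:
    recs = []
    for _, rid, path in manifest.entries:
        try:
            recs.append(core_io.read_recording(path))
        except Exception as exc:
            raise PipelineError(f"stage load: recording {rid}: {exc}") from exc
    return recs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every configured stage; returns the run directory."""
    run_dir = Path(cfg.out_root) / (cfg.run_name or time.strftime("run-%Y%m%d-%H%M%S"))
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("painquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    provenance: dict[str, dict[str, str]] = {"inputs": {}, "outputs": {}}
    try:
        (run_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))

        if cfg.simulate and not cfg.manifest:
            logger.info("stage simulate: %d subjects x %d recordings",
                        cfg.n_subjects, cfg.recordings_per_subject)
            manifest, _ = synthetic_data.generate_cohort(_synth_config(cfg), run_dir / "cohort")
        else:
            manifest = core_io.read_manifest(cfg.manifest)
        for _, _, p in manifest.entries:
            provenance["inputs"][str(p)] = _sha256(Path(p))
        recordings = _load_recordings(manifest)
        logger.info("loaded %d recordings", len(recordings))

        metric_rows = []
        for combo in cfg.combinations:
            combo_name = "+".join(combo)
            logger.info("stage features/evaluate: combination %s", combo_name)
            table = features.extract_cohort_features(
                recordings, combo, include_temp_sd=cfg.include_temp_sd
            )
            _write_tsv(table, run_dir / f"features_{combo_name}.tsv")
            if len(table) == 0 or table["recording_id"].nunique() < 2:
                logger.warning("combination %s: %d usable windows; skipping evaluation",
                               combo_name, len(table))
                metric_rows.append({"combination": combo_name, "n_recordings": 0,
                                    "n_windows": len(table), "r": np.nan, "rmse": np.nan,
                                    "icc31": np.nan, "perm_p": np.nan})
                continue
            spec = ModelSpec(level="population", sensors=combo, n_trees=cfg.n_trees,
                             max_depth=cfg.max_depth, seed=cfg.seed)
            report = evaluation.evaluate(
                table, spec, n_perm=cfg.n_perm, perm_seed=cfg.seed,
                recording_means=cfg.recording_means,
            )
            _write_tsv(report.predictions, run_dir / f"predictions_{combo_name}.tsv")
            metric_rows.append({
                "combination": combo_name,
                "n_recordings": report.n_recordings,
                "n_windows": report.n_windows,
                "r": report.r,
                "rmse": report.rmse,
                "icc31": report.icc31,
                "perm_p": report.perm_p if report.perm_p is not None else np.nan,
            })
            ba = evaluation.bland_altman(report.predictions["pred"],
                                         report.predictions["label"])
            _write_tsv(pd.DataFrame([{"combination": combo_name, "bias": ba.bias,
                                      "lower": ba.lower, "upper": ba.upper}]),
                       run_dir / f"bland_altman_{combo_name}.tsv")
        metrics = pd.DataFrame(metric_rows)
        _write_tsv(metrics, run_dir / "metrics.tsv")

        if cfg.individual_models:
            indiv = individual_model_sweep(
                recordings, cfg.combinations,
                n_selected=cfg.n_selected, include_temp_sd=cfg.include_temp_sd,
            )
            _write_tsv(indiv, run_dir / "individual.tsv")

        for p in sorted(run_dir.glob("*.tsv")):
            provenance["outputs"][p.name] = _sha256(p)
        (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


def individual_model_sweep(
    recordings: Sequence[core_io.RawRecording],
    combinations: Sequence[tuple[str, ...]],
    *,
    n_selected: int = 5,
    include_temp_sd: bool = False,
) -> pd.DataFrame:
    """Per-subject RFE+linear models over every sensor combination.

    For each subject, every combination is LORO-cross-validated and the
    one with the best cross-validated r is flagged (``best=True``).  Note
    that selecting the combination on cross-validated performance is
    optimistic; the flagged rows are combination-selected results, not an
    independent assessment.
    """
    by_subject: dict[str, list[core_io.RawRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    rows = []
    for subject_id in sorted(by_subject):
        recs = by_subject[subject_id]
        results = []
        for combo in combinations:
            table = features.extract_cohort_features(
                recs, combo, include_temp_sd=include_temp_sd
            )
            if len(table) == 0 or table["recording_id"].nunique() < 2:
                continue
            if table["label"].nunique() < 2:
                continue
            spec = ModelSpec(level="individual", sensors=combo, n_selected=n_selected)
            try:
                preds = evaluation.loro_cv(table, spec)
                r = evaluation.pearson_r(preds["pred"], preds["label"])
            except ValueError as exc:
                logger.info("subject %s combination %s: skipped (%s)",
                            subject_id, "+".join(combo), exc)
                continue
            results.append({
                "subject_id": subject_id,
                "combination": "+".join(combo),
                "n_recordings": table["recording_id"].nunique(),
                "n_windows": len(table),
                "r": r,
                "rmse": evaluation.rmse(preds["pred"], preds["label"]),
            })
        if not results:
            continue
        best_i = int(np.argmax([res["r"] for res in results]))
        for i, res in enumerate(results):
            res["best"] = i == best_i
            rows.append(res)
    return pd.DataFrame(
        rows, columns=["subject_id", "combination", "n_recordings", "n_windows",
                       "r", "rmse", "best"]
    )


def report(run_dir: str | Path, *, plots: bool = False) -> str:
    """Render a human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    missing = [name for name in ("metrics.tsv", "config.json") if not (run_dir / name).exists()]
    if missing:
        raise PipelineError(f"incomplete run {run_dir}: missing {', '.join(missing)}")
    metrics = pd.read_csv(run_dir / "metrics.tsv", sep="\t")
    lines = [f"run: {run_dir}", "", "population-level models (one row per sensor combination):"]
    lines.append(metrics.to_string(index=False))
    indiv_path = run_dir / "individual.tsv"
    if indiv_path.exists():
        indiv = pd.read_csv(indiv_path, sep="\t")
        if len(indiv):
            best = indiv[indiv["best"]]
            lines += ["", "individual models (best combination per subject):",
                      best.to_string(index=False)]
    usable = metrics[metrics["n_windows"] > 0]
    if len(usable) == 0:
        lines += ["", "no usable windows in any combination (0 windows)"]
    if plots:
        lines += ["", f"plots: {', '.join(p.name for p in _make_plots(run_dir, metrics))}"]
    return "\n".join(lines)


def _make_plots(run_dir: Path, metrics: pd.DataFrame) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    for _, row in metrics.iterrows():
        combo = row["combination"]
        pred_path = run_dir / f"predictions_{combo}.tsv"
        if not pred_path.exists():
            continue
        preds = pd.read_csv(pred_path, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        d = preds["pred"] - preds["label"]
        axes[0].scatter(preds["label"], d, s=4, alpha=0.4)
        axes[0].axhline(d.mean(), color="k")
        sd = d.std(ddof=1)
        for lim in (d.mean() - 1.96 * sd, d.mean() + 1.96 * sd):
            axes[0].axhline(lim, color="k", linestyle="--")
        axes[0].set_xlabel("reported pain score")
        axes[0].set_ylabel("predicted - reported")
        axes[0].set_title(f"Bland-Altman ({combo})")
        scores = sorted(preds["label"].unique())
        axes[1].violinplot([preds.loc[preds["label"] == s, "pred"] for s in scores],
                           positions=scores, widths=0.8)
        axes[1].plot(scores, scores, color="k", linewidth=1)
        axes[1].set_xlabel("reported pain score")
        axes[1].set_ylabel("predicted pain score")
        axes[1].set_title(f"predictions ({combo})")
        fig.tight_layout()
        path = run_dir / f"plot_{combo}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        out.append(path)
    return out
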