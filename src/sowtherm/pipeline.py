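"""End-to-end pipeline: simulate → extract ROI temperature → fit/tune →
predict → evaluate, with every artifact stamped by the config hash.

The stages mirror the monitoring workflow: acquire observations (here the
synthetic generator stands in for the farm acquisition system), map the
vulva mask onto the IR temperature matrix and reduce it to one statistic,
train the temperature-inversion regressor (fixed hyperparameters or the
adaptive-GA search), predict rectal temperatures on the held-out test set,
and score them.  Reruns with an identical config reproduce the model file
and metrics byte for byte; wall-clock timing appears only in the run
report, never inside a model or metrics artifact.
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

from . import aga, forest, metrics, synthetic, thermal
from .errors import ConfigurationError, SowthermError

__all__ = [
    "Normalizer",
    "PipelineConfig",
    "run_pipeline",
    "save_model_file",
    "load_model_file",
    "predict_records",
]

log = logging.getLogger("sowtherm")


@dataclass(frozen=True)
class Normalizer:
    """Per-feature min-max scaling fitted on training data only.

    Constant features map to 0.5 (the midpoint) rather than dividing by a
    zero span.  Tree ensembles are scale-invariant, so this exists for
    interface stability (other regressors can be swapped in) and is stored
    with the model so prediction-time inputs are scaled identically.
    """

    mins: tuple
    maxs: tuple

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        return cls(mins=tuple(X.min(axis=0).tolist()),
                   maxs=tuple(X.max(axis=0).tolist()))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mins = np.array(self.mins)
        span = np.array(self.maxs) - mins
        out = np.empty_like(X)
        const = span == 0
        out[:, ~const] = (X[:, ~const] - mins[~const]) / span[~const]
        out[:, const] = 0.5
        return out

    def to_dict(self) -> dict:
        return {"mins": list(self.mins), "maxs": list(self.maxs)}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(mins=tuple(d["mins"]), maxs=tuple(d["maxs"]))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    outdir: str
    generator: synthetic.GeneratorConfig
    ratios: tuple = (8, 1, 1)
    roi_stat: str = "max"
    thermal_enabled: bool = True
    thermal_height: int = 48
    thermal_width: int = 64
    thermal_noise_sd_c: float = 0.2
    mode: str = "tune"  # "tune" (AGA search) or "fit" (fixed genome)
    hyperparams: forest.ForestHyperparams = field(
        default_factory=forest.ForestHyperparams)
    search_space: str = "compact"  # "compact" or "default"
    aga: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ConfigurationError(
                "config must set an explicit top-level 'seed'")
        gen_raw = dict(raw.get("generator", {}))
        gen_raw.setdefault("seed", int(raw["seed"]))
        for key in ("rectal_range_c", "at_range_c", "rh_range_pct",
                    "ai_range_lux"):
            if key in gen_raw:
                gen_raw[key] = tuple(gen_raw[key])
        thermal_raw = dict(raw.get("thermal", {}))
        model_raw = dict(raw.get("model", {}))
        hp = forest.ForestHyperparams(**model_raw.get("hyperparams", {}))
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=str(raw.get("outdir", "sowtherm_run")),
            generator=synthetic.GeneratorConfig(**gen_raw),
            ratios=tuple(raw.get("split", {}).get("ratios", (8, 1, 1))),
            roi_stat=str(raw.get("roi_stat", "max")),
            thermal_enabled=bool(thermal_raw.get("enabled", True)),
            thermal_height=int(thermal_raw.get("height", 48)),
            thermal_width=int(thermal_raw.get("width", 64)),
            thermal_noise_sd_c=float(thermal_raw.get("noise_sd_c", 0.2)),
            mode=str(model_raw.get("mode", "tune")),
            hyperparams=hp,
            search_space=str(model_raw.get("search_space", "compact")),
            aga=dict(model_raw.get("aga", {})),
            log_level=str(raw.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        self.generator.validate()
        if self.generator.n < 10:
            raise ConfigurationError(
                f"generator.n must be >= 10 for a pipeline run, "
                f"got {self.generator.n}")
        if self.mode not in ("tune", "fit"):
            raise ConfigurationError(
                f"model.mode must be 'tune' or 'fit', got {self.mode!r}")
        if self.search_space not in ("compact", "default"):
            raise ConfigurationError(
                f"model.search_space must be 'compact' or 'default', "
                f"got {self.search_space!r}")
        self.hyperparams.validate()

    def to_canonical_dict(self) -> dict:
        return {
            "seed": self.seed,
            "generator": self.generator.to_dict(),
            "ratios": list(self.ratios),
            "roi_stat": self.roi_stat,
            "thermal": {"enabled": self.thermal_enabled,
                        "height": self.thermal_height,
                        "width": self.thermal_width,
                        "noise_sd_c": self.thermal_noise_sd_c},
            "model": {"mode": self.mode,
                      "hyperparams": self.hyperparams.to_dict(),
                      "search_space": self.search_space,
                      "aga": dict(sorted(self.aga.items()))},
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model file I/O


def save_model_file(model: forest.ForestModel, normalizer: Normalizer,
                    path, config_hash: str = "") -> None:
    payload = {"format": "sowtherm-model-v1",
               "config_hash": config_hash,
               "normalizer": normalizer.to_dict(),
               "forest": model.to_dict()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model_file(path) -> tuple[forest.ForestModel, Normalizer]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "sowtherm-model-v1":
        raise ConfigurationError(f"{path}: not a sowtherm model file")
    return (forest.ForestModel.from_dict(payload["forest"]),
            Normalizer.from_dict(payload["normalizer"]))


def _features(frame: pd.DataFrame) -> np.ndarray:
    missing = [c for c in synthetic.FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"records are missing feature columns {missing}; "
            f"expected {list(synthetic.FEATURE_COLUMNS)}")
    return frame.loc[:, list(synthetic.FEATURE_COLUMNS)].to_numpy(dtype=float)


def predict_records(model_path, records_csv, out_path=None) -> pd.DataFrame:
    """Apply a saved model to a records CSV; returns (and optionally writes)
    a predictions table with one ``t_rectal_pred_c`` per input row."""
    model, normalizer = load_model_file(model_path)
    frame = pd.read_csv(records_csv, comment="#")
    if len(frame) == 0:
        out = frame.assign(t_rectal_pred_c=pd.Series(dtype=float))
    else:
        X = normalizer.transform(_features(frame))
        out = frame.assign(t_rectal_pred_c=model.predict(X))
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out


# ---------------------------------------------------------------------------
# the pipeline


def _extract_stage(records, config: PipelineConfig, outdir: Path,
                   config_hash: str):
    """Re-derive each record's vulva temperature through a thermal scene.

    Each record gets a synthetic IR scene whose ROI plateau is the record's
    surface temperature; the mask statistic then replaces ``t_vulva_c``,
    exercising the same mask→matrix mapping used on real exports.
    """
    h, w = config.thermal_height, config.thermal_width
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    axes = (max(1.0, w / 6.0), max(1.0, h / 6.0))
    rng = np.random.default_rng(config.seed + 104729)
    extracted = []
    example_written = False
    for rec in records:
        background = min(rec.at_c, rec.t_vulva_c - 2.0)
        matrix, mask = synthetic.generate_thermal_scene(
            h, w, center, axes, background_c=background, roi_c=rec.t_vulva_c,
            noise_sd_c=config.thermal_noise_sd_c,
            seed=int(rng.integers(0, 2**31 - 1)))
        stat = thermal.extract_region_temperature(matrix, mask,
                                                  stat=config.roi_stat)
        extracted.append(dataclasses.replace(rec, t_vulva_c=stat.value_c))
        if not example_written:
            thermal.write_temperature_matrix(
                matrix, outdir / "scene_example.csv",
                header=f"config_hash={config_hash}")
            thermal.write_mask(mask, outdir / "scene_example_mask.csv")
            example_written = True
    return extracted


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    Any stage failure raises :class:`SowthermError` with a stage-labelled
    message; partial outputs are kept next to a ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    stage = "configure"
    try:
        stage = "simulate"
        log.info("[simulate] generating %d records", config.generator.n)
        records = synthetic.generate_samples(config.generator)
        synthetic.write_records_csv(records, outdir / "samples.csv",
                                    config=config.generator,
                                    extra_comments=[f"config_hash={chash}"])

        stage = "extract-temp"
        if config.thermal_enabled:
            log.info("[extract-temp] ROI statistic %s over %dx%d scenes",
                     config.roi_stat, config.thermal_height,
                     config.thermal_width)
            records = _extract_stage(records, config, outdir, chash)
            synthetic.write_records_csv(
                records, outdir / "extracted.csv",
                extra_comments=[f"config_hash={chash}",
                                f"roi_stat={config.roi_stat}"])

        stage = "split"
        train, val, test = synthetic.split_dataset(records, config.ratios,
                                                   seed=config.seed)
        for name, part in (("train", train), ("val", val), ("test", test)):
            synthetic.write_records_csv(
                part, outdir / f"{name}.csv",
                extra_comments=[f"config_hash={chash}"])

        stage = "fit" if config.mode == "fit" else "tune"
        train_frame = synthetic.records_to_frame(train)
        X_train = _features(train_frame)
        y_train = train_frame[synthetic.TARGET_COLUMN].to_numpy(float)
        normalizer = Normalizer.fit(X_train)
        Xn = normalizer.transform(X_train)
        if config.mode == "fit":
            log.info("[fit] fixed hyperparameters %s",
                     config.hyperparams.to_dict())
            model = forest.fit_forest(
                Xn, y_train, config.hyperparams, seed=config.seed,
                feature_names=synthetic.FEATURE_COLUMNS)
            report_model = {"mode": "fit",
                            "hyperparams": config.hyperparams.to_dict()}
        else:
            space = (aga.compact_search_space()
                     if config.search_space == "compact"
                     else aga.default_search_space())
            aga_config = aga.AGAConfig(seed=config.seed, **config.aga)
            log.info("[tune] AGA over %d genomes, population %d, "
                     "%d generations", space.size(),
                     aga_config.population_size, aga_config.generations)
            model, tune_report = aga.fit_aga_rf(
                Xn, y_train, space, aga_config,
                feature_names=synthetic.FEATURE_COLUMNS)
            report_model = {"mode": "tune", **tune_report}
            with open(outdir / "tune_report.json", "w", encoding="utf-8") as fh:
                json.dump({"config_hash": chash, **tune_report}, fh, indent=2)
        save_model_file(model, normalizer, outdir / "model.json",
                        config_hash=chash)

        stage = "predict"
        test_frame = synthetic.records_to_frame(test)
        preds = predict_records(outdir / "model.json", outdir / "test.csv",
                                out_path=outdir / "predictions.csv")

        stage = "evaluate"
        truth = test_frame[synthetic.TARGET_COLUMN].to_numpy(float)
        scores = metrics.regression_report(truth,
                                           preds["t_rectal_pred_c"].to_numpy())
        with open(outdir / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump({"config_hash": chash, **scores}, fh, indent=2)
            fh.write("\n")

        stage = "report"
        report = {
            "config_hash": chash,
            "config": config.to_canonical_dict(),
            "n_records": len(records),
            "split_sizes": {"train": len(train), "val": len(val),
                            "test": len(test)},
            "model": report_model,
            "metrics": scores,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        return report
    except SowthermError as err:
        (outdir / "FAILED").write_text(f"stage={stage}: {err}\n",
                                       encoding="utf-8")
        raise SowthermError(f"[{stage}] {err}") from err
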